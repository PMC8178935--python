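"""Synthetic cohorts with planted methylation, clinical and batch structure.

The generator emulates the statistical shape of an early-stage OSCC
methylation study: a clinical table with ten scoring features drawn from
realistic marginals, a binary 5-year disease-specific vital status from a
logistic model over configurable feature odds ratios, a bimodal beta-value
matrix (logit-normal noise per probe) with differential methylation
planted at a chosen set of signature CpGs, batch structure optionally
correlated with outcome, a detection-p matrix with failing entries and bad
probes, and negative-binomial-like expression counts with signed
correlation to signature-CpG methylation.  Everything is reproducible from
a single seed, and the planted truth is recorded alongside the data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .containers import MethylationDataset, validate_manifest
from . import io as rsio

#: Default signature gene symbols (a 12-gene panel; 13 CpGs, one gene with two).
DEFAULT_SIGNATURE_GENES = (
    "ABCA2",
    "CACNA1H",
    "CCNJL",
    "GPR133",
    "HGFAC",
    "HORMAD2",
    "MCPH1",
    "MYLK",
    "RNF216",
    "SOX8",
    "TRPA1",
    "WDR86",
)

#: Default signed expression-methylation correlation targets for six
#: signature genes (positive: expression rises with methylation).
DEFAULT_EXPR_CORR = {
    "ABCA2": 0.46,
    "GPR133": 0.42,
    "MCPH1": 0.31,
    "RNF216": -0.38,
    "TRPA1": -0.60,
    "WDR86": 0.36,
}

#: Marginal prevalences of the clinical features (early-stage oral-cavity
#: TCGA-like cohort).  Categorical features list (level, probability).
CLINICAL_MARGINALS = {
    "sex": (("male", 0.60), ("female", 0.40)),
    "race": (("white", 0.93), ("nonwhite", 0.07)),
    "ethnicity": (("hispanic", 0.036), ("non-hispanic", 0.964)),
    "tobacco": (("yes", 0.68), ("no", 0.32)),
    "alcohol": (("yes", 0.61), ("no", 0.39)),
    "site": (
        ("tongue", 0.57),
        ("floor_of_mouth", 0.15),
        ("buccal", 0.10),
        ("alveolar", 0.05),
        ("other", 0.13),
    ),
    "grade": (("well", 0.19), ("moderate", 0.61), ("poor", 0.20)),
    "stage": (("I", 0.31), ("II", 0.69)),
    "pni": (("yes", 0.35), ("no", 0.65)),
    "lvi": (("yes", 0.069), ("no", 0.931)),
    "margin": (("positive_close", 0.21), ("negative", 0.79)),
}

AGE_MEAN, AGE_SD, AGE_RANGE = 64.0, 11.0, (30.0, 92.0)

#: Which level of each feature counts as "risk positive" in the planted
#: logistic outcome model (age uses the >= 65 convention).
RISK_LEVELS = {
    "age": None,  # handled as age >= AGE_RISK_CUT
    "sex": "male",
    "race": "nonwhite",
    "ethnicity": "hispanic",
    "tobacco": "yes",
    "alcohol": "yes",
    "site": "floor_of_mouth",
    "grade": ("moderate", "poor"),
    "stage": "II",
    "pni": "yes",
    "lvi": "yes",
    "margin": "positive_close",
}

AGE_RISK_CUT = 65.0

#: Pre-compensation for the lognormal-Poisson attenuation of the target
#: expression-methylation correlation (product of the analytic exp-link and
#: Poisson shot-noise attenuation factors at the default count scale).
LATENT_CORR_COMPENSATION = 0.95


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic bundle.

    Defaults mirror a TCGA-like early-stage oral-cavity cohort: 58
    patients, a 14% 5-year disease-specific death rate, a 12-gene /
    13-CpG planted signature shifted by 0.25 beta units in decedents, two
    strong clinical risk factors (age >= 65, OR 3; PNI, OR 4), two batches
    weakly correlated with outcome, and six expression-methylation
    correlation targets.  Use ``event_rate=0.37`` for an internal-cohort
    style death rate.
    """

    n_patients: int = 58
    n_probes: int = 5000
    n_signature_genes: int = 12
    n_signature_cpgs: int = 13
    event_rate: float = 0.14
    delta_beta: float = 0.25
    clinical_effects: dict = field(default_factory=lambda: {"age": 3.0, "pni": 4.0})
    n_batches: int = 2
    batch_outcome_corr: float = 0.10
    expr_corr: dict = field(default_factory=lambda: dict(DEFAULT_EXPR_CORR))
    seed: int = 0
    # probe-annotation fractions
    xy_fraction: float = 0.03
    snp_fraction: float = 0.04
    unmapped_fraction: float = 0.20
    cross_reactive_fraction: float = 0.04
    constant_fraction: float = 0.02
    # noise / nuisance structure
    noise_sd: float = 0.5  # logit-scale per-sample noise
    batch_effect_sd: float = 0.4  # logit-scale per-batch shift spread
    detection_fail_rate: float = 0.005
    bad_probe_fraction: float = 0.01
    # expression
    n_expr_background_genes: int = 200
    expr_base_mean: float = 300.0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ConfigurationError("n_patients must be positive")
        if not 0.0 < self.event_rate < 1.0:
            raise ConfigurationError(f"event_rate {self.event_rate} outside (0, 1)")
        if self.event_rate * self.n_patients < 2:
            raise ConfigurationError("expected events below 2; enlarge cohort or event rate")
        if self.n_signature_cpgs < self.n_signature_genes:
            raise ConfigurationError("n_signature_cpgs must be >= n_signature_genes")
        if self.n_probes < self.n_signature_cpgs:
            raise ConfigurationError("n_probes smaller than the signature")
        allowed = set(self.signature_genes())
        for gene, r in self.expr_corr.items():
            if gene not in allowed:
                raise ConfigurationError(f"expr_corr gene {gene!r} is not a signature gene")
            if not abs(r) < 1.0:
                raise ConfigurationError(f"|expr_corr[{gene!r}]| must be < 1")
        for feat in self.clinical_effects:
            if feat not in RISK_LEVELS:
                raise ConfigurationError(f"unknown clinical feature {feat!r}")
        if not 0.0 <= self.batch_outcome_corr < 1.0:
            raise ConfigurationError("batch_outcome_corr must lie in [0, 1)")
        if self.n_batches < 1:
            raise ConfigurationError("n_batches must be >= 1")

    def signature_genes(self) -> list[str]:
        if self.n_signature_genes <= len(DEFAULT_SIGNATURE_GENES):
            return list(DEFAULT_SIGNATURE_GENES[: self.n_signature_genes])
        extra = [f"SIG{i:02d}" for i in range(len(DEFAULT_SIGNATURE_GENES), self.n_signature_genes)]
        return list(DEFAULT_SIGNATURE_GENES) + extra


@dataclass
class SyntheticBundle:
    """One generated study: all inputs plus the planted truth."""

    manifest: pd.DataFrame
    methylation: MethylationDataset
    clinical: pd.DataFrame
    expression: pd.DataFrame
    truth: dict

    def __post_init__(self) -> None:
        samples = list(self.methylation.sample_ids)
        if list(self.clinical.index) != samples:
            raise ValueError("clinical sample ids disagree with methylation")
        if list(self.expression.columns) != samples:
            raise ValueError("expression sample ids disagree with methylation")
        missing = set(self.truth["planted_cpgs"]) - set(self.methylation.probe_ids)
        if missing:
            raise ValueError(f"truth lists unknown probes: {sorted(missing)[:5]}")


def _risk_indicator(clinical: pd.DataFrame, feature: str) -> np.ndarray:
    if feature == "age":
        return (clinical["age"].to_numpy(dtype=float) >= AGE_RISK_CUT).astype(float)
    level = RISK_LEVELS[feature]
    levels = level if isinstance(level, tuple) else (level,)
    return clinical[feature].isin(levels).to_numpy(dtype=float)


def generate_cohort(config: SimulationConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw a clinical table and its binary 5-year vital status.

    Features are sampled independently from the marginal prevalences; the
    outcome follows a logistic model whose log odds ratios come from
    ``config.clinical_effects``, with the intercept solved so the expected
    event rate matches ``config.event_rate`` on the drawn covariates.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_patients
    data: dict[str, np.ndarray] = {}
    data["age"] = np.clip(np.round(rng.normal(AGE_MEAN, AGE_SD, n)), *AGE_RANGE)
    for feat, pairs in CLINICAL_MARGINALS.items():
        levels = [lv for lv, _ in pairs]
        probs = np.array([p for _, p in pairs])
        data[feat] = rng.choice(levels, size=n, p=probs / probs.sum())
    clinical = pd.DataFrame(data, index=pd.Index([f"P{i:04d}" for i in range(n)], name="patient_id"))

    eta = np.zeros(n)
    for feat, oratio in config.clinical_effects.items():
        if oratio <= 0:
            raise ConfigurationError(f"odds multiplier for {feat!r} must be positive")
        eta += np.log(oratio) * _risk_indicator(clinical, feat)

    def mean_rate(intercept: float) -> float:
        return float(expit(intercept + eta).mean()) - config.event_rate

    intercept = brentq(mean_rate, -30.0, 30.0)
    p = expit(intercept + eta)
    clinical["vital_status_5yr"] = rng.binomial(1, p)
    return clinical[list(rsio.CLINICAL_COLUMNS)]


def _assign_batches(
    config: SimulationConfig, outcome: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Batch labels with corr(1{batch 0}, outcome) targeting batch_outcome_corr.

    The membership probability of batch 0 is tilted by outcome so the
    phi coefficient between batch-0 membership and death matches the
    target; remaining batches are uniform.
    """
    n = outcome.size
    if config.n_batches == 1:
        return np.zeros(n, dtype=int)
    p0 = 1.0 / config.n_batches
    e = outcome.mean()
    if 0 < e < 1 and config.batch_outcome_corr > 0:
        delta = config.batch_outcome_corr * np.sqrt(p0 * (1 - p0) / (e * (1 - e)))
    else:
        delta = 0.0
    p_dead = np.clip(p0 + delta * (1 - e), 0.0, 1.0)
    p_alive = np.clip(p0 - delta * e, 0.0, 1.0)
    in0 = rng.random(n) < np.where(outcome == 1, p_dead, p_alive)
    batches = np.where(in0, 0, rng.integers(1, config.n_batches, n))
    return batches.astype(int)


def generate_methylation(
    config: SimulationConfig,
    cohort: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, MethylationDataset, dict]:
    """Manifest, beta/detection matrices and planted truth for a cohort.

    Probe baselines are a two-component logit-normal mixture; signature
    CpGs sit in the dynamic mid-range and are shifted by +-``delta_beta``
    (beta scale, clipped) in patients who died, one direction per gene.
    Batch shifts act additively on the logit scale.
    """
    if cohort.empty:
        raise ConfigurationError("cohort is empty")
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    n_probes, n = config.n_probes, cohort.shape[0]
    samples = pd.Index(cohort.index.to_list())  # unnamed: matrix files carry no axis label
    outcome = cohort["vital_status_5yr"].to_numpy(dtype=int)

    probe_ids = np.array([f"cg{i:08d}" for i in range(n_probes)])
    chrom = rng.choice([str(c) for c in range(1, 23)], size=n_probes)
    pos = rng.integers(1, 2**27, size=n_probes)
    snp_flag = np.zeros(n_probes, dtype=bool)
    cross_flag = np.zeros(n_probes, dtype=bool)
    gene_idx = rng.integers(0, max(1, n_probes // 3), n_probes)
    gene = np.array([f"G{i:05d}" for i in gene_idx], dtype=object)

    # annotation categories drawn up front; signature probes are kept clean
    order = rng.permutation(n_probes)
    counts = {
        "xy": int(round(config.xy_fraction * n_probes)),
        "snp": int(round(config.snp_fraction * n_probes)),
        "unmapped": int(round(config.unmapped_fraction * n_probes)),
        "cross": int(round(config.cross_reactive_fraction * n_probes)),
        "constant": int(round(config.constant_fraction * n_probes)),
        "bad": int(round(config.bad_probe_fraction * n_probes)),
    }
    stop = 0
    slices = {}
    for name, cnt in counts.items():
        slices[name] = order[stop : stop + cnt]
        stop += cnt
    if stop + config.n_signature_cpgs > n_probes:
        raise ConfigurationError("annotation fractions leave no room for the signature")
    sig_idx = order[stop : stop + config.n_signature_cpgs]

    xy = slices["xy"]
    chrom[xy] = rng.choice(["X", "Y"], size=xy.size)
    snp_flag[slices["snp"]] = True
    gene[slices["unmapped"]] = ""
    cross_flag[slices["cross"]] = True

    genes = config.signature_genes()
    # assign CpGs to genes round-robin so every gene gets >= 1 CpG
    sig_gene = [genes[i % len(genes)] for i in range(config.n_signature_cpgs)]
    gene[sig_idx] = sig_gene
    directions = {g: ("hyper" if rng.random() < 0.5 else "hypo") for g in genes}

    # baseline: two-component logit-normal mixture
    high = rng.random(n_probes) < 0.5
    mu = np.where(
        high,
        rng.normal(logit(0.8), 0.6, n_probes),
        rng.normal(logit(0.2), 0.6, n_probes),
    )
    const = slices["constant"]
    mu[const] = np.where(rng.random(const.size) < 0.5, logit(0.03), logit(0.97))
    # signature probes live mid-range so a delta_beta shift can cross a state cut
    mu[sig_idx] = logit(rng.uniform(0.30, 0.55, sig_idx.size))

    # lognormal per-probe spread keeps the variance prior non-degenerate
    sd = config.noise_sd * np.exp(rng.normal(0.0, 0.3, n_probes))
    sd[const] = 0.05

    batches = _assign_batches(config, outcome, rng)
    batch_shift = rng.normal(0.0, config.batch_effect_sd, config.n_batches)

    z = mu[:, None] + rng.normal(0.0, 1.0, (n_probes, n)) * sd[:, None]
    z += batch_shift[batches][None, :]
    beta = expit(z)

    # planted differential methylation on the beta scale, clipped
    for row, g in zip(sig_idx, sig_gene):
        shift = config.delta_beta if directions[g] == "hyper" else -config.delta_beta
        beta[row, outcome == 1] += shift
    beta = np.clip(beta, 1e-6, 1.0 - 1e-6)

    fail = rng.random((n_probes, n)) < config.detection_fail_rate
    fail[slices["bad"], :] = rng.random((slices["bad"].size, n)) < 0.8
    fail[sig_idx, :] = False
    detp = np.where(fail, rng.uniform(0.011, 1.0, (n_probes, n)), rng.uniform(0.0, 0.009, (n_probes, n)))

    manifest = validate_manifest(
        pd.DataFrame(
            {
                "probe_id": probe_ids,
                "chrom": chrom,
                "pos": pos,
                "gene": gene,
                "snp_flag": snp_flag,
                "cross_reactive_flag": cross_flag,
            }
        )
    )
    dataset = MethylationDataset(
        beta=pd.DataFrame(beta, index=probe_ids, columns=samples),
        detection_p=pd.DataFrame(detp, index=probe_ids, columns=samples),
        outcome=cohort["vital_status_5yr"],
    )
    truth = {
        "note": "synthetic stand-in cohort; joint distributions are generator choices",
        "planted_cpgs": {
            str(probe_ids[row]): {"gene": g, "direction": directions[g]}
            for row, g in zip(sig_idx, sig_gene)
        },
        "gene_directions": directions,
        "clinical_effects": dict(config.clinical_effects),
        "batches": {str(s): int(b) for s, b in zip(samples, batches)},
        "batch_shift_logit": [float(x) for x in batch_shift],
    }
    return manifest, dataset, truth


def generate_expression(
    config: SimulationConfig,
    methylation: MethylationDataset,
    truth: dict,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Count matrix with signed expression-methylation correlation targets.

    For each configured signature gene, counts are Poisson with a log-scale
    latent partially correlated with the gene's planted-CpG beta; the
    latent correlation is pre-compensated for the exp-link and shot-noise
    attenuation so the realized count-beta Pearson r lands near the target.
    Background genes are independent negative-binomial-like counts.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    sig_genes = config.signature_genes()
    unknown = set(config.expr_corr) - set(sig_genes)
    if unknown:
        raise ConfigurationError(f"expr_corr genes not in the signature: {sorted(unknown)}")
    gene_cpg = {}
    for cpg, info in truth["planted_cpgs"].items():
        gene_cpg.setdefault(info["gene"], cpg)
    n = methylation.n_samples
    rows, names = [], []
    for g in sig_genes:
        target = config.expr_corr.get(g)
        if target is None or g not in gene_cpg:
            lam = np.exp(np.log(config.expr_base_mean) + 0.4 * rng.normal(0, 1, n))
        else:
            b = methylation.beta.loc[gene_cpg[g]].to_numpy(dtype=float)
            zb = (b - b.mean()) / max(b.std(), 1e-12)
            rho = np.clip(target / LATENT_CORR_COMPENSATION, -0.995, 0.995)
            latent = rho * zb + np.sqrt(1 - rho**2) * rng.normal(0, 1, n)
            lam = np.exp(np.log(config.expr_base_mean) + 0.4 * latent)
        rows.append(rng.poisson(lam))
        names.append(g)
    for i in range(config.n_expr_background_genes):
        mean = np.exp(rng.normal(np.log(150.0), 0.7))
        lam = mean * rng.gamma(10.0, 0.1, n)
        rows.append(rng.poisson(lam))
        names.append(f"BG{i:04d}")
    return pd.DataFrame(
        np.vstack(rows), index=pd.Index(names, name="gene_id"), columns=methylation.sample_ids
    )


def generate_bundle(config: SimulationConfig) -> SyntheticBundle:
    """Generate a full bundle (cohort, methylation, expression, truth) from one seed."""
    root = np.random.default_rng(config.seed)
    # independent child streams so stages stay reproducible in isolation
    seeds = root.integers(0, 2**31 - 1, 3)
    cohort = generate_cohort(config, np.random.default_rng(seeds[0]))
    manifest, dataset, truth = generate_methylation(config, cohort, np.random.default_rng(seeds[1]))
    expression = generate_expression(config, dataset, truth, np.random.default_rng(seeds[2]))
    return SyntheticBundle(
        manifest=manifest,
        methylation=dataset,
        clinical=cohort,
        expression=expression,
        truth=truth,
    )


def write_bundle(bundle: SyntheticBundle, directory: str | Path) -> dict[str, Path]:
    """Write all bundle components as delimited text plus a truth JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "beta": directory / "beta.tsv",
        "detection_p": directory / "detection_p.tsv",
        "manifest": directory / "manifest.tsv",
        "clinical": directory / "clinical.tsv",
        "counts": directory / "counts.tsv",
        "truth": directory / "truth.json",
    }
    rsio.write_matrix(bundle.methylation.beta, paths["beta"])
    rsio.write_matrix(bundle.methylation.detection_p, paths["detection_p"])
    rsio.write_manifest(bundle.manifest, paths["manifest"])
    rsio.write_clinical(bundle.clinical, paths["clinical"])
    rsio.write_matrix(bundle.expression, paths["counts"])
    paths["truth"].write_text(json.dumps(bundle.truth, indent=2, sort_keys=True) + "\n")
    return paths


def make_cascade_fixture(
    n_total: int = 485_512,
    n_xy: int = 11_648,
    n_snp: int = 17_351,
    n_unmapped: int = 111_977,
    n_detection_fail: int = 5_000,
    n_cross_reactive: int = 15_071,
    n_uninformative: int = 7_449,
    n_samples: int = 4,
) -> tuple[pd.DataFrame, MethylationDataset]:
    """Manifest + dataset engineered so each filter removes an exact count.

    Defaults size the fixture to a full 450K array with the published
    workflow's removal counts at the stages whose totals are printed
    (485,512 -> 473,864 -> 344,536 -> ... -> 317,016 -> 95,104); the
    detection / cross-reactive split is not printed and is arbitrary here.
    Category memberships are disjoint so the bookkeeping is exact.
    """
    sizes = [n_xy, n_snp, n_unmapped, n_detection_fail, n_cross_reactive, n_uninformative]
    n_normal = n_total - sum(sizes)
    if n_normal < 0:
        raise ValueError("category counts exceed the total probe count")
    probe_ids = pd.Index([f"p{i:07d}" for i in range(n_total)])
    chrom = np.full(n_total, "1", dtype=object)
    gene = np.full(n_total, "G1", dtype=object)
    snp = np.zeros(n_total, dtype=bool)
    cross = np.zeros(n_total, dtype=bool)
    beta = np.full((n_total, n_samples), 0.5)
    detp = np.full((n_total, n_samples), 0.001)

    bounds = np.cumsum([0] + sizes + [n_normal])
    seg = {
        name: slice(bounds[i], bounds[i + 1])
        for i, name in enumerate(
            ["xy", "snp", "unmapped", "det", "cross", "uninf", "normal"]
        )
    }
    chrom[seg["xy"]] = "X"
    snp[seg["snp"]] = True
    gene[seg["unmapped"]] = ""
    detp[seg["det"]] = 0.5
    cross[seg["cross"]] = True
    beta[seg["uninf"]] = 0.05
    # distinct variances for the survivors of the earlier stages
    spread = np.linspace(0.01, 0.34, n_normal)
    half = n_samples // 2
    beta[seg["normal"], :half] = (0.5 - spread)[:, None]
    beta[seg["normal"], half:] = (0.5 + spread)[:, None]

    manifest = validate_manifest(
        pd.DataFrame(
            {
                "probe_id": probe_ids,
                "chrom": chrom,
                "pos": np.arange(1, n_total + 1),
                "gene": gene,
                "snp_flag": snp,
                "cross_reactive_flag": cross,
            }
        )
    )
    samples = [f"S{i}" for i in range(n_samples)]
    outcome = pd.Series([i % 2 for i in range(n_samples)], index=samples)
    dataset = MethylationDataset(
        beta=pd.DataFrame(beta, index=probe_ids, columns=samples),
        detection_p=pd.DataFrame(detp, index=probe_ids, columns=samples),
        outcome=outcome,
    )
    return manifest, dataset
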