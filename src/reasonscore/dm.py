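"""Moderated-t differential methylation between deceased and surviving patients.

Each probe's M-value (logit2 of beta) is fit by ordinary least squares on
[intercept, outcome, retained surrogate variables].  Per-probe residual
variances are then shrunk toward a common prior by empirical Bayes: the
prior degrees of freedom d0 and prior variance s0^2 are estimated by the
method of moments on log residual variances (closed forms of the standard
hierarchical model), giving

    s2_post = (d0 * s0^2 + df * s2) / (d0 + df)
    t_mod   = effect / sqrt(s2_post * v),   df_total = d0 + df

where v is the design leverage of the outcome coefficient.  Probes with an
adjusted p-value below the selection threshold form the molecular
signature; the per-gene risk direction is the sign of the effect at the
gene's most significant CpG (positive = hypermethylation in decedents).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .containers import MethylationDataset

logger = logging.getLogger(__name__)


def beta_to_m(beta: np.ndarray | pd.DataFrame, eps: float = 1e-6):
    """logit2 transform: M = log2(beta / (1 - beta)), beta clipped to [eps, 1-eps]."""
    clipped = np.clip(beta, eps, 1.0 - eps)
    return np.log2(clipped / (1.0 - clipped))


@dataclass
class ProbeFits:
    """Per-probe OLS summaries for the outcome contrast."""

    probe_ids: pd.Index
    effect: np.ndarray  # outcome coefficient per probe (M-value difference)
    sigma2: np.ndarray  # residual variance per probe
    df_resid: int
    v_outcome: float  # leverage [ (X'X)^-1 ]_{outcome,outcome}

    def __post_init__(self) -> None:
        if np.any(self.sigma2 < 0):
            raise ValueError("negative residual variance")


def _collinear_columns(x: np.ndarray, names: list[str]) -> list[str]:
    bad = []
    for j in range(1, x.shape[1]):
        sub = x[:, :j]
        resid = x[:, j] - sub @ np.linalg.lstsq(sub, x[:, j], rcond=None)[0]
        if np.linalg.norm(resid) < 1e-10 * max(1.0, np.linalg.norm(x[:, j])):
            bad.append(names[j])
    return bad


def fit_probe_models(
    m_values: np.ndarray,
    outcome: np.ndarray,
    covariates: np.ndarray | pd.DataFrame | None = None,
    probe_ids: pd.Index | None = None,
) -> ProbeFits:
    """OLS fit of every probe's M-values on [1, outcome, covariates].

    Raises
    ------
    ValueError
        If the design matrix is rank deficient (the collinear columns are
        named) or has no residual degrees of freedom.
    """
    m_values = np.asarray(m_values, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    n = outcome.shape[0]
    if m_values.shape[1] != n:
        raise ValueError(f"M matrix has {m_values.shape[1]} samples, outcome has {n}")
    cols = [np.ones(n), outcome]
    names = ["intercept", "outcome"]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] != n:
            raise ValueError("covariate rows do not match samples")
        for j in range(cov.shape[1]):
            cols.append(cov[:, j])
            name = (
                covariates.columns[j]
                if isinstance(covariates, pd.DataFrame)
                else f"covariate{j + 1}"
            )
            names.append(str(name))
    x = np.column_stack(cols)
    p = x.shape[1]
    if np.linalg.matrix_rank(x) < p:
        raise ValueError(f"design matrix rank deficient; collinear columns: {_collinear_columns(x, names)}")
    if n <= p:
        raise ValueError(f"no residual degrees of freedom: n={n}, design columns={p}")
    xtx_inv = np.linalg.inv(x.T @ x)
    hat = xtx_inv @ x.T  # p x n
    coef = m_values @ hat.T  # probes x p
    resid = m_values - coef @ x.T
    df = n - p
    sigma2 = (resid**2).sum(axis=1) / df
    if probe_ids is None:
        probe_ids = pd.RangeIndex(m_values.shape[0])
    return ProbeFits(
        probe_ids=pd.Index(probe_ids),
        effect=coef[:, 1],
        sigma2=sigma2,
        df_resid=df,
        v_outcome=float(xtx_inv[1, 1]),
    )


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise ValueError("trigamma inverse requires a positive argument")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(100):
        tri = special.polygamma(1, y)
        step = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += step
        if abs(step) < 1e-10 * y:
            break
    return float(y)


def estimate_prior(sigma2: np.ndarray, df_resid: int) -> tuple[float, float]:
    """Method-of-moments estimate of the variance prior (d0, s0^2).

    Works on z = log(s2) of probes with positive residual variance:
    E[z] and Var[z] have closed forms in digamma/trigamma, from which d0
    follows by trigamma inversion and s0^2 by back-transformation.  If the
    observed spread of log variances is no larger than expected from the
    residual chi-square alone, d0 is infinite (full shrinkage to s0^2).
    """
    s2 = np.asarray(sigma2, dtype=float)
    s2 = s2[s2 > 0]
    if s2.size < 2:
        raise ValueError("prior estimation needs >= 2 probes with positive variance")
    half_df = df_resid / 2.0
    e = np.log(s2) - special.digamma(half_df) + np.log(half_df)
    mean_e = float(e.mean())
    var_e = float(e.var(ddof=1))
    excess = var_e - float(special.polygamma(1, half_df))
    if excess <= 0:
        d0 = np.inf
        s0_sq = float(np.exp(mean_e))
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_sq = float(np.exp(mean_e + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


@dataclass
class DMResults:
    """Moderated per-probe statistics plus the shared prior hyperparameters."""

    table: pd.DataFrame  # index probe_id; logFC_M, t_mod, p, p_adj, ...
    d0: float
    s0_sq: float
    df_resid: int

    def __post_init__(self) -> None:
        if np.any(self.table["p_adj"].to_numpy() + 1e-12 < self.table["p"].to_numpy()):
            raise ValueError("adjusted p-values below raw p-values")


def empirical_bayes_moderate(fits: ProbeFits) -> DMResults:
    """Shrink per-probe variances and return moderated statistics.

    Probes with zero residual variance (constant M across samples) receive
    the fully shrunk posterior variance and are flagged in the table.
    """
    d0, s0_sq = estimate_prior(fits.sigma2, fits.df_resid)
    df = fits.df_resid
    if np.isinf(d0):
        s2_post = np.full_like(fits.sigma2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df * fits.sigma2) / (d0 + df)
        df_total = d0 + df
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = fits.effect / np.sqrt(s2_post * fits.v_outcome)
    t_mod = np.where(np.isfinite(t_mod), t_mod, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    table = pd.DataFrame(
        {
            "logFC_M": fits.effect,
            "t_mod": t_mod,
            "df_total": df_total,
            "p": p,
            "p_adj": adjust_bh(p),
            "zero_variance": fits.sigma2 == 0,
        },
        index=fits.probe_ids,
    )
    return DMResults(table=table, d0=float(d0), s0_sq=float(s0_sq), df_resid=df)


def adjust_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ordinary_t(fits: ProbeFits) -> tuple[np.ndarray, np.ndarray]:
    """Unmoderated per-probe t statistics and two-sided p-values (d0 -> 0 limit)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fits.effect / np.sqrt(fits.sigma2 * fits.v_outcome)
    t = np.where(np.isfinite(t), t, 0.0)
    return t, 2.0 * stats.t.sf(np.abs(t), fits.df_resid)


@dataclass
class Signature:
    """Selected signature: CpGs, their genes, and per-gene risk directions."""

    cpgs: list[str]
    genes: list[str]
    cpg_to_gene: dict[str, str]
    directions: dict[str, str] = field(default_factory=dict)  # gene -> hyper|hypo

    def __post_init__(self) -> None:
        for d in self.directions.values():
            if d not in ("hyper", "hypo"):
                raise ValueError(f"direction must be hyper/hypo, got {d!r}")

    @property
    def n_cpgs(self) -> int:
        return len(self.cpgs)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def gene_cpgs(self, gene: str) -> list[str]:
        return [c for c, g in self.cpg_to_gene.items() if g == gene]

    def to_dict(self) -> dict:
        return {
            "cpgs": self.cpgs,
            "genes": self.genes,
            "cpg_to_gene": self.cpg_to_gene,
            "directions": self.directions,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Signature":
        return cls(
            cpgs=list(d["cpgs"]),
            genes=list(d["genes"]),
            cpg_to_gene=dict(d["cpg_to_gene"]),
            directions=dict(d["directions"]),
        )


def select_signature(
    results: DMResults, alpha: float = 0.1, max_cpgs: int | None = None
) -> Signature:
    """Select signature CpGs at adjusted p < alpha and derive gene directions.

    The gene list is the deduplicated set of genes of selected CpGs (first
    symbol when a probe maps to several).  Each gene's risk direction is
    the sign of the effect at its most significant CpG: positive effect =
    hypermethylated in patients who died.
    """
    tab = results.table
    if "gene" not in tab.columns:
        raise ValueError("results table lacks a 'gene' column; pass a manifest when fitting")
    hits = tab[tab["p_adj"] < alpha].sort_values(["p_adj", "p"], kind="mergesort")
    if max_cpgs is not None:
        hits = hits.iloc[:max_cpgs]
    if hits.empty:
        logger.warning("empty signature: no CpG reached adjusted p < %.3g", alpha)
    cpgs = hits.index.tolist()
    cpg_to_gene = {
        c: str(g).split(";")[0] for c, g in hits["gene"].items() if str(g)
    }
    genes: list[str] = []
    directions: dict[str, str] = {}
    for cpg in cpgs:  # hits are p-ordered, so the first CpG per gene is the best
        gene = cpg_to_gene.get(cpg)
        if gene and gene not in directions:
            genes.append(gene)
            directions[gene] = "hyper" if hits.loc[cpg, "logFC_M"] > 0 else "hypo"
    return Signature(cpgs=cpgs, genes=genes, cpg_to_gene=cpg_to_gene, directions=directions)


def run_differential_methylation(
    dataset: MethylationDataset,
    covariates: pd.DataFrame | None = None,
    manifest: pd.DataFrame | None = None,
    eps: float = 1e-6,
) -> DMResults:
    """Full stage: M-transform, per-probe OLS, empirical-Bayes moderation.

    Adds a ``gene`` column (from the manifest) and ``delta_beta_mean``, the
    raw mean beta difference (deceased - survived), as a companion effect
    scale to the M-value logFC.
    """
    if covariates is not None and len(covariates.columns) == 0:
        covariates = None
    if covariates is not None:
        covariates = covariates.loc[dataset.sample_ids]
    m = beta_to_m(dataset.beta.to_numpy(), eps=eps)
    y = dataset.outcome_array()
    fits = fit_probe_models(m, y, covariates, probe_ids=dataset.probe_ids)
    results = empirical_bayes_moderate(fits)
    b = dataset.beta.to_numpy()
    dead = y == 1
    if dead.any() and (~dead).any():
        results.table["delta_beta_mean"] = b[:, dead].mean(axis=1) - b[:, ~dead].mean(axis=1)
    else:
        results.table["delta_beta_mean"] = np.nan
    if manifest is not None:
        results.table["gene"] = manifest.loc[dataset.probe_ids, "gene"].to_numpy()
    return results
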