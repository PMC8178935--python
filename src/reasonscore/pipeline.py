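"""End-to-end orchestration: filter -> sva -> dm -> states -> clinico -> evaluate -> downstream.

Every stage persists its outputs as TSV/JSON before the next runs, so any
stage can be re-run from intermediates; a run manifest with content hashes
makes determinism checkable.  The first failing stage aborts with its name
while earlier outputs are retained.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import io as rsio
from .clinico import TreeParams, derive_clinico_score
from .dm import run_differential_methylation, select_signature
from .downstream import correlate_expression_methylation, filter_expressed, ora
from .evaluate import combine_scores, evaluate_panels
from .filtering import FilterParams, run_cascade
from .states import StateThresholds, molecular_scores
from .sva import estimate_surrogates, select_covariates

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Inputs, outputs and per-stage parameters of a full run."""

    beta: str = "beta.tsv"
    detection_p: str = "detection_p.tsv"
    manifest: str = "manifest.tsv"
    clinical: str = "clinical.tsv"
    counts: str | None = None
    gmt: str | None = None
    out_dir: str = "results"
    seed: int = 0
    n_sv: int | str = "auto"
    dm_alpha: float = 0.1
    max_signature_cpgs: int | None = None
    n_bootstrap: int = 2000
    filter_params: FilterParams = field(default_factory=FilterParams)
    state_thresholds: StateThresholds = field(default_factory=StateThresholds)
    tree_params: TreeParams = field(default_factory=TreeParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        for key, sub in (
            ("filter_params", FilterParams),
            ("state_thresholds", StateThresholds),
            ("tree_params", TreeParams),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                subknown = {f.name for f in fields(sub)}
                bad = set(kwargs[key]) - subknown
                if bad:
                    raise ValueError(f"unknown {key} keys: {sorted(bad)}")
                kwargs[key] = sub(**kwargs[key])
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the whole analysis; returns the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    produced: list[Path] = []

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - stage name is the contract
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrap

    dataset = stage("read")(
        lambda: rsio.read_dataset(config.beta, config.detection_p, config.clinical)
    )
    manifest = stage("read")(lambda: rsio.read_manifest(config.manifest))
    clinical = stage("read")(lambda: rsio.read_clinical(config.clinical))

    def do_filter():
        ds, report = run_cascade(dataset, manifest, config.filter_params)
        report.write(out / "filter_report.tsv")
        rsio.write_matrix(ds.beta, out / "filtered_beta.tsv")
        produced.extend([out / "filter_report.tsv", out / "filtered_beta.tsv"])
        return ds

    filtered = stage("filter")(do_filter)

    def do_sva():
        svs = estimate_surrogates(filtered, n_sv=config.n_sv, random_state=config.seed)
        cov = select_covariates(svs)
        cov.to_csv(out / "sv.tsv", sep="\t", index_label="sample_id")
        svs.report().to_csv(out / "sv_report.tsv", sep="\t", index_label="sv")
        produced.extend([out / "sv.tsv", out / "sv_report.tsv"])
        return cov

    covariates = stage("sva")(do_sva)

    def do_dm():
        results = run_differential_methylation(filtered, covariates, manifest)
        results.table.to_csv(out / "dm_results.tsv", sep="\t", index_label="probe_id")
        sig = select_signature(results, alpha=config.dm_alpha, max_cpgs=config.max_signature_cpgs)
        rsio.write_json(sig.to_dict(), out / "signature.json")
        produced.extend([out / "dm_results.tsv", out / "signature.json"])
        return results, sig

    dm_results, signature = stage("dm")(do_dm)

    def do_states():
        scores, calls = molecular_scores(dataset, signature, config.state_thresholds)
        calls.to_csv(out / "state_calls.tsv", sep="\t", index=False)
        scores.to_frame().to_csv(out / "molecular_scores.tsv", sep="\t", index_label="patient_id")
        produced.extend([out / "state_calls.tsv", out / "molecular_scores.tsv"])
        return scores

    mol_scores = stage("states")(do_states)

    def do_clinico():
        model, scores, _tree = derive_clinico_score(clinical, params=config.tree_params)
        model.write(out / "clinico_model.json")
        scores.to_frame().to_csv(out / "clinico_scores.tsv", sep="\t", index_label="patient_id")
        produced.extend([out / "clinico_model.json", out / "clinico_scores.tsv"])
        return scores

    clin_scores = stage("clinico")(do_clinico)

    def do_evaluate():
        composite = combine_scores(clin_scores, mol_scores)
        composite.to_csv(out / "reason_scores.tsv", sep="\t")
        outcome = clinical["vital_status_5yr"]
        panels = {
            "clinico": composite["clinico_points"],
            "molecular": composite["molecular_points"],
            "reason": composite["total"],
        }
        table = evaluate_panels(outcome, panels, n_bootstrap=config.n_bootstrap, seed=config.seed)
        rsio.write_json(table.reset_index().to_dict(orient="records"), out / "evaluation.json")
        produced.extend([out / "reason_scores.tsv", out / "evaluation.json"])
        return table

    stage("evaluate")(do_evaluate)

    if config.counts:
        def do_downstream():
            counts = rsio.read_matrix(config.counts, "counts")
            expressed = filter_expressed(counts)
            corr = correlate_expression_methylation(expressed, dataset.beta, signature)
            corr.to_csv(out / "correlations.tsv", sep="\t", index=False)
            produced.append(out / "correlations.tsv")
            if config.gmt:
                sets = rsio.read_gmt(config.gmt)
                universe = sorted(
                    {
                        str(g).split(";")[0]
                        for g in dm_results.table.get("gene", pd.Series(dtype=str))
                        if str(g)
                    }
                )
                query = [g for g in signature.genes if g in universe]
                enr = ora(query, universe, sets)
                enr.to_csv(out / "ora_results.tsv", sep="\t", index=False)
                produced.append(out / "ora_results.tsv")

        stage("downstream")(do_downstream)

    hashes = {p.name: _sha256(p) for p in produced}
    rsio.write_json(hashes, out / "run_manifest.json")
    logger.info("pipeline complete: %d artifacts in %s", len(produced), out)
    return out
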