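"""Probe-filter cascade for 450K beta-value matrices.

The cascade removes, in a fixed order: sex-chromosome probes, SNP-related
probes, probes not mapping to any gene region, probes failing detection,
cross-reactive/multi-mapping probes, probes uninformative across all
samples, and finally keeps only the top fraction of probes by beta-value
variance.  Every stage appends an auditable (stage, n_in, n_removed, n_out)
entry so the bookkeeping can be checked against published workflow counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .containers import MethylationDataset

logger = logging.getLogger(__name__)


class FilterStage(NamedTuple):
    stage: str
    n_in: int
    n_removed: int
    n_out: int


@dataclass
class FilterCascadeReport:
    """Ordered per-stage probe counts with a chaining invariant."""

    stages: list[FilterStage] = field(default_factory=list)

    def append(self, stage: str, n_in: int, n_out: int) -> None:
        entry = FilterStage(stage, n_in, n_in - n_out, n_out)
        if self.stages and self.stages[-1].n_out != n_in:
            raise ValueError(
                f"stage {stage!r} received {n_in} probes but previous stage "
                f"left {self.stages[-1].n_out}"
            )
        self.stages.append(entry)
        logger.info("filter %-20s in=%d removed=%d out=%d", stage, *entry[1:])

    def validate(self) -> None:
        for k, s in enumerate(self.stages):
            if s.n_out != s.n_in - s.n_removed:
                raise ValueError(f"stage {s.stage!r} count mismatch")
            if k and self.stages[k - 1].n_out != s.n_in:
                raise ValueError(f"stage {s.stage!r} breaks the chain")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "n_in", "n_removed", "n_out"])

    def write(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class FilterParams:
    """Cascade thresholds.

    Defaults follow the standard 450K workflow: detection p < 0.01 in at
    least half the samples, uninformative band outside [0.1, 0.9], top 30%
    of probes by variance retained.
    """

    detection_p_threshold: float = 0.01
    detection_sample_fraction: float = 0.5
    beta_low: float = 0.1
    beta_high: float = 0.9
    variance_fraction: float = 0.30


def _check_manifest_cover(dataset: MethylationDataset, manifest: pd.DataFrame) -> None:
    missing = dataset.probe_ids.difference(manifest.index)
    if len(missing):
        raise KeyError(f"probes absent from manifest: {missing.tolist()[:5]}")


def filter_sex_chromosomes(
    dataset: MethylationDataset, manifest: pd.DataFrame, report: FilterCascadeReport | None = None
) -> tuple[MethylationDataset, FilterCascadeReport]:
    """Drop probes hybridizing to the X or Y chromosome."""
    report = report if report is not None else FilterCascadeReport()
    _check_manifest_cover(dataset, manifest)
    chrom = manifest.loc[dataset.probe_ids, "chrom"]
    keep = dataset.probe_ids[~chrom.isin(["X", "Y"])]
    out = dataset.subset_probes(keep)
    report.append("sex_chromosomes", dataset.n_probes, out.n_probes)
    return out, report


def filter_snp_and_unmapped(
    dataset: MethylationDataset, manifest: pd.DataFrame, report: FilterCascadeReport | None = None
) -> tuple[MethylationDataset, FilterCascadeReport]:
    """Drop SNP-related probes, then probes mapping to no gene region.

    A probe carrying both annotations is counted in the SNP stage only,
    since the stages are applied sequentially.
    """
    report = report if report is not None else FilterCascadeReport()
    _check_manifest_cover(dataset, manifest)
    snp = manifest.loc[dataset.probe_ids, "snp_flag"]
    keep = dataset.probe_ids[~snp.to_numpy()]
    mid = dataset.subset_probes(keep)
    report.append("snp", dataset.n_probes, mid.n_probes)

    gene = manifest.loc[mid.probe_ids, "gene"]
    keep = mid.probe_ids[gene.str.len().to_numpy() > 0]
    out = mid.subset_probes(keep)
    report.append("unmapped", mid.n_probes, out.n_probes)
    return out, report


def filter_detection(
    dataset: MethylationDataset,
    p_threshold: float = 0.01,
    sample_fraction: float = 0.5,
    report: FilterCascadeReport | None = None,
) -> tuple[MethylationDataset, FilterCascadeReport]:
    """Keep probes detected (p < threshold) in at least ``sample_fraction`` of samples.

    The boundary is inclusive: a probe passing in exactly half the samples
    is retained with the default fraction of 0.5.
    """
    report = report if report is not None else FilterCascadeReport()
    if dataset.n_samples == 0:
        if dataset.n_probes:
            raise ValueError("detection filter requires at least one sample")
        report.append("detection", 0, 0)
        return dataset, report
    frac_pass = (dataset.detection_p.to_numpy() < p_threshold).mean(axis=1)
    keep = dataset.probe_ids[frac_pass >= sample_fraction]
    out = dataset.subset_probes(keep)
    report.append("detection", dataset.n_probes, out.n_probes)
    return out, report


def filter_cross_reactive(
    dataset: MethylationDataset, manifest: pd.DataFrame, report: FilterCascadeReport | None = None
) -> tuple[MethylationDataset, FilterCascadeReport]:
    """Drop probes flagged cross-reactive or multi-mapping."""
    report = report if report is not None else FilterCascadeReport()
    _check_manifest_cover(dataset, manifest)
    flag = manifest.loc[dataset.probe_ids, "cross_reactive_flag"]
    out = dataset.subset_probes(dataset.probe_ids[~flag.to_numpy()])
    report.append("cross_reactive", dataset.n_probes, out.n_probes)
    return out, report


def filter_uninformative_beta(
    dataset: MethylationDataset,
    low: float = 0.1,
    high: float = 0.9,
    report: FilterCascadeReport | None = None,
) -> tuple[MethylationDataset, FilterCascadeReport]:
    """Drop probes with beta < low across ALL samples or > high across ALL samples."""
    report = report if report is not None else FilterCascadeReport()
    b = dataset.beta.to_numpy()
    all_low = (b < low).all(axis=1)
    all_high = (b > high).all(axis=1)
    out = dataset.subset_probes(dataset.probe_ids[~(all_low | all_high)])
    report.append("uninformative_beta", dataset.n_probes, out.n_probes)
    return out, report


def filter_top_variance(
    dataset: MethylationDataset,
    fraction: float = 0.30,
    report: FilterCascadeReport | None = None,
) -> tuple[MethylationDataset, FilterCascadeReport]:
    """Retain the top ``floor(fraction * n)`` probes by beta-value sample variance.

    Variance is the unbiased sample variance; ties at the cut are broken by
    probe id so the retained set is invariant to input row order.
    """
    report = report if report is not None else FilterCascadeReport()
    n_in = dataset.n_probes
    n_keep = math.floor(fraction * n_in)
    if n_in == 0:
        report.append("top_variance", 0, 0)
        return dataset, report
    if dataset.n_samples < 2:
        raise ValueError("variance filter requires at least two samples")
    var = dataset.beta.var(axis=1, ddof=1)
    # stable sort after a lexicographic pre-sort: ties at the cut break by probe id
    order = (
        pd.DataFrame({"var": var})
        .sort_index()
        .sort_values(by="var", ascending=False, kind="mergesort")
    )
    keep = order.index[:n_keep]
    # preserve original probe order in the output matrix
    keep = dataset.probe_ids[dataset.probe_ids.isin(keep)]
    out = dataset.subset_probes(keep)
    report.append("top_variance", n_in, out.n_probes)
    return out, report


def run_cascade(
    dataset: MethylationDataset,
    manifest: pd.DataFrame,
    params: FilterParams = FilterParams(),
) -> tuple[MethylationDataset, FilterCascadeReport]:
    """Run the full filter cascade in its fixed order.

    Order: sex chromosomes -> SNP -> unmapped -> detection -> cross-reactive
    -> uninformative beta -> top variance.  The returned report satisfies
    the chaining invariant and the final dataset is the differential-
    methylation input.
    """
    report = FilterCascadeReport()
    ds, _ = filter_sex_chromosomes(dataset, manifest, report)
    ds, _ = filter_snp_and_unmapped(ds, manifest, report)
    ds, _ = filter_detection(
        ds, params.detection_p_threshold, params.detection_sample_fraction, report
    )
    ds, _ = filter_cross_reactive(ds, manifest, report)
    ds, _ = filter_uninformative_beta(ds, params.beta_low, params.beta_high, report)
    ds, _ = filter_top_variance(ds, params.variance_fraction, report)
    report.validate()
    return ds, report
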