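"""Core in-memory containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Valid chromosome names for array probes (no contigs, no "chr" prefix).
CHROMOSOMES = tuple(str(i) for i in range(1, 23)) + ("X", "Y")

#: Required columns of a probe manifest.
MANIFEST_COLUMNS = ("probe_id", "chrom", "pos", "gene", "snp_flag", "cross_reactive_flag")


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    """Validate a probe manifest and return it indexed by probe id.

    The ``gene`` column holds ';'-separated symbols, empty string meaning the
    probe maps to no gene region.  Flags are 0/1 integers or booleans.
    """
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns and c != "probe_id"]
    if "probe_id" not in manifest.columns and manifest.index.name != "probe_id":
        raise ValueError("manifest lacks a probe_id column")
    if missing:
        raise ValueError(f"manifest lacks required columns: {missing}")
    if "probe_id" in manifest.columns:
        manifest = manifest.set_index("probe_id")
    if manifest.index.duplicated().any():
        dups = manifest.index[manifest.index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicated probe ids in manifest: {dups}")
    bad = set(manifest["chrom"].astype(str)) - set(CHROMOSOMES)
    if bad:
        raise ValueError(f"unknown chromosome names in manifest: {sorted(bad)[:5]}")
    manifest = manifest.copy()
    manifest["chrom"] = manifest["chrom"].astype(str)
    manifest["gene"] = manifest["gene"].fillna("").astype(str)
    manifest["snp_flag"] = manifest["snp_flag"].astype(bool)
    manifest["cross_reactive_flag"] = manifest["cross_reactive_flag"].astype(bool)
    return manifest


@dataclass
class MethylationDataset:
    """Aligned beta matrix, detection-p matrix and per-sample outcome.

    Parameters
    ----------
    beta
        Probes x samples DataFrame of methylation beta values in [0, 1].
    detection_p
        Probes x samples DataFrame of detection p-values in [0, 1], with
        identical axis labels to ``beta``.
    outcome
        Per-sample binary 5-year disease-specific vital status indexed by
        sample id (1 = died of disease within 5 years).
    """

    beta: pd.DataFrame
    detection_p: pd.DataFrame
    outcome: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if self.beta.shape != self.detection_p.shape:
            raise ValueError(
                f"beta {self.beta.shape} and detection_p {self.detection_p.shape} "
                "shapes differ"
            )
        if not self.beta.index.equals(self.detection_p.index) or not self.beta.columns.equals(
            self.detection_p.columns
        ):
            raise ValueError("beta and detection_p axis labels differ")
        if self.beta.index.duplicated().any():
            raise ValueError("duplicated probe ids in beta matrix")
        self.outcome = self.outcome.reindex(self.beta.columns)
        if self.outcome.isna().any():
            missing = self.outcome.index[self.outcome.isna()].tolist()[:5]
            raise ValueError(f"samples without outcome: {missing}")
        vals = set(pd.unique(self.outcome))
        if not vals <= {0, 1}:
            raise ValueError(f"outcome must be binary 0/1, got values {sorted(vals)[:5]}")
        self.outcome = self.outcome.astype(int)

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.columns

    @property
    def n_probes(self) -> int:
        return self.beta.shape[0]

    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]

    def subset_probes(self, probe_ids) -> "MethylationDataset":
        """Return a dataset restricted to ``probe_ids`` (order preserved)."""
        return MethylationDataset(
            beta=self.beta.loc[probe_ids],
            detection_p=self.detection_p.loc[probe_ids],
            outcome=self.outcome,
        )

    def outcome_array(self) -> np.ndarray:
        return self.outcome.to_numpy(dtype=float)
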