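"""Methylation state-transition scoring.

Beta values are discretized into three ordered states — unmethylated,
hemi-methylated, fully methylated — with cuts at 0.33 and 0.75 (published
thresholds name < 0.3 as unmethylated and 0.33-0.75 as hemi-methylated;
the unassigned [0.30, 0.33) sliver is merged into the unmethylated state
so the map is a total partition).  A signature gene scores a risk point
for a patient when at least one of its CpGs has moved to a different state
relative to a reference — the state of the survivor-group median beta — in
the gene's risk-associated direction.  A beta change without a state
change never scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd

from .containers import MethylationDataset
from .dm import Signature

logger = logging.getLogger(__name__)


class MethState(IntEnum):
    """Ordered methylation states; the order defines transition direction."""

    UNMETH = 0
    HEMI = 1
    FULL = 2


@dataclass(frozen=True)
class StateThresholds:
    """Beta cuts for the state map.

    ``unmeth_below`` is the nominal unmethylated cut (0.3); classification
    uses ``hemi_low`` as the single lower boundary (gap-merge convention),
    with HEMI closed on both ends: UNMETH < 0.33 <= HEMI <= 0.75 < FULL.
    """

    unmeth_below: float = 0.30
    hemi_low: float = 0.33
    hemi_high: float = 0.75

    def __post_init__(self) -> None:
        if not (0.0 < self.unmeth_below <= self.hemi_low < self.hemi_high < 1.0):
            raise ValueError(
                "thresholds must satisfy 0 < unmeth_below <= hemi_low < hemi_high < 1"
            )


def assign_state(beta: float, thresholds: StateThresholds = StateThresholds()) -> MethState:
    """Map a single beta value to its methylation state."""
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta value {beta!r} outside [0, 1]")
    if beta < thresholds.hemi_low:
        return MethState.UNMETH
    if beta <= thresholds.hemi_high:
        return MethState.HEMI
    return MethState.FULL


def assign_states(
    beta: np.ndarray, thresholds: StateThresholds = StateThresholds()
) -> np.ndarray:
    """Vectorized state map; returns an int array of MethState values."""
    b = np.asarray(beta, dtype=float)
    if np.any((b < 0) | (b > 1)):
        raise ValueError("beta values outside [0, 1]")
    out = np.full(b.shape, int(MethState.HEMI), dtype=np.int8)
    out[b < thresholds.hemi_low] = int(MethState.UNMETH)
    out[b > thresholds.hemi_high] = int(MethState.FULL)
    return out


def _lower_median(values: np.ndarray) -> float:
    """Median that is always an observed value (lower-middle for even counts)."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("median of empty set")
    return float(v[(v.size - 1) // 2])


def reference_states(
    dataset: MethylationDataset,
    signature: Signature,
    thresholds: StateThresholds = StateThresholds(),
) -> pd.Series:
    """Per-CpG reference state: state of the survivor-group median beta.

    Raises
    ------
    ValueError
        If the cohort contains no 5-year survivor, or a signature CpG is
        absent from the dataset.
    """
    survivors = dataset.outcome.index[dataset.outcome == 0]
    if len(survivors) == 0:
        raise ValueError("no event-free patient to anchor reference states")
    missing = [c for c in signature.cpgs if c not in dataset.beta.index]
    if missing:
        raise KeyError(f"signature CpGs absent from dataset: {missing[:5]}")
    refs = {}
    for cpg in signature.cpgs:
        med = _lower_median(dataset.beta.loc[cpg, survivors].to_numpy())
        refs[cpg] = int(assign_state(med, thresholds))
    return pd.Series(refs, name="reference_state", dtype=int)


def call_state_transitions(
    dataset: MethylationDataset,
    signature: Signature,
    thresholds: StateThresholds = StateThresholds(),
    references: pd.Series | None = None,
) -> pd.DataFrame:
    """Long table of per-patient, per-CpG state calls.

    Columns: patient_id, cpg_id, gene, state, reference_state, transition
    (HYPER / HYPO / NONE), risk_flag.  ``risk_flag`` is True iff the
    transition direction matches the gene's risk direction.
    """
    if references is None:
        references = reference_states(dataset, signature, thresholds)
    records = []
    for cpg in signature.cpgs:
        gene = signature.cpg_to_gene.get(cpg, "")
        direction = signature.directions.get(gene)
        ref = int(references[cpg])
        states = assign_states(dataset.beta.loc[cpg].to_numpy(), thresholds)
        for patient, state in zip(dataset.sample_ids, states):
            if state > ref:
                transition = "HYPER"
            elif state < ref:
                transition = "HYPO"
            else:
                transition = "NONE"
            risk = (transition == "HYPER" and direction == "hyper") or (
                transition == "HYPO" and direction == "hypo"
            )
            records.append(
                (patient, cpg, gene, MethState(int(state)).name, MethState(ref).name, transition, risk)
            )
    return pd.DataFrame(
        records,
        columns=[
            "patient_id",
            "cpg_id",
            "gene",
            "state",
            "reference_state",
            "transition",
            "risk_flag",
        ],
    )


def call_gene_risk(calls: pd.DataFrame, signature: Signature) -> pd.DataFrame:
    """Patients x genes boolean risk flags (a gene fires if ANY of its CpGs does).

    Signature genes with no CpG in the call table are scored 0 for every
    patient and logged as missing.
    """
    patients = calls["patient_id"].unique()
    flags = pd.DataFrame(False, index=pd.Index(patients, name="patient_id"), columns=signature.genes)
    grouped = calls[calls["risk_flag"]].groupby(["patient_id", "gene"]).size()
    for (patient, gene), _count in grouped.items():
        if gene in flags.columns:
            flags.loc[patient, gene] = True
    present_genes = set(calls["gene"])
    for gene in signature.genes:
        if gene not in present_genes:
            logger.warning("signature gene %s has no CpG in the dataset; scored 0", gene)
    return flags


def molecular_scores(
    dataset: MethylationDataset,
    signature: Signature,
    thresholds: StateThresholds = StateThresholds(),
    references: pd.Series | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-patient molecular score = count of risk-positive signature genes.

    Returns the integer score series (0..n_genes) and the long call table.
    """
    calls = call_state_transitions(dataset, signature, thresholds, references)
    if calls.empty:
        scores = pd.Series(0, index=dataset.sample_ids, name="molecular_score", dtype=int)
        return scores, calls
    flags = call_gene_risk(calls, signature)
    scores = flags.sum(axis=1).reindex(dataset.sample_ids).fillna(0).astype(int)
    scores.name = "molecular_score"
    return scores, calls
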