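"""Clinicopathologic integer risk score via recursive partitioning.

A binary tree over the ten-feature panel (age, race, sex, tobacco,
alcohol, histologic grade, stage, PNI, LVI, margin status) is grown by
choosing, at each node, the binary split with the smallest Pearson
chi-square p-value against 5-year vital status.  Continuous features are
dichotomized beforehand at the chi-square-maximizing cut over a clinically
sensible candidate grid (multiples of 5 by default).  Each decision node
contributes integer points equal to its death odds ratio rounded to the
nearest integer (banker's rounding, Haldane-Anscombe 0.5 correction for
zero cells); a patient's score is the sum of points over the node rules
they satisfy.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

logger = logging.getLogger(__name__)

#: The ten-feature clinicopathologic panel.
PANEL_FEATURES = (
    "age",
    "race",
    "sex",
    "tobacco",
    "alcohol",
    "grade",
    "stage",
    "pni",
    "lvi",
    "margin",
)

#: Continuous panel members (dichotomized before tree growth).
CONTINUOUS_FEATURES = ("age",)

OUTCOME_COLUMN = "vital_status_5yr"

MAX_MISSING_FRACTION = 0.05  # panel features must be near-complete


def chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) for a 2x2 table.

    Returns (statistic, p).  Degenerate tables (a zero margin) give (0, 1).
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 0.0, 1.0
    stat, p, _, _ = chi2_contingency(table, correction=False)
    return float(stat), float(p)


def default_candidate_cuts(values: np.ndarray, step: int = 5) -> list[float]:
    """Multiples of ``step`` strictly inside the observed range."""
    lo, hi = np.nanmin(values), np.nanmax(values)
    first = math.floor(lo / step) * step + step
    cuts = [float(c) for c in range(int(first), int(math.ceil(hi)), step) if lo < c <= hi]
    return cuts


def dichotomize_continuous(
    cohort: pd.DataFrame,
    feature: str,
    candidate_cuts: Sequence[float] | None = None,
    outcome: str = OUTCOME_COLUMN,
) -> float:
    """Pick the cut maximizing the 2x2 chi-square of (value >= cut) x outcome.

    Ties take the smaller cut.  A constant feature is an error.
    """
    values = cohort[feature].to_numpy(dtype=float)
    y = cohort[outcome].to_numpy(dtype=int)
    ok = ~np.isnan(values)
    values, y = values[ok], y[ok]
    if values.size == 0 or np.nanmin(values) == np.nanmax(values):
        raise ValueError(f"feature {feature!r} is constant; cannot dichotomize")
    if candidate_cuts is None:
        candidate_cuts = default_candidate_cuts(values)
    if not candidate_cuts:
        raise ValueError(f"no candidate cuts inside the range of {feature!r}")
    best_cut, best_stat = None, -1.0
    for cut in sorted(candidate_cuts):
        above = values >= cut
        stat, _ = chi2_2x2(
            int((above & (y == 1)).sum()),
            int((above & (y == 0)).sum()),
            int((~above & (y == 1)).sum()),
            int((~above & (y == 0)).sum()),
        )
        if stat > best_stat + 1e-12:
            best_cut, best_stat = cut, stat
    return float(best_cut)


@dataclass
class TreeNode:
    """A node of the partitioning tree; decision nodes carry their split table."""

    depth: int
    n: int
    n_dead: int
    feature: str | None = None
    levels: tuple | None = None  # split: feature value in levels
    chi2: float = 0.0
    p_value: float = 1.0
    table: tuple | None = None  # (in_dead, in_alive, out_dead, out_alive)
    in_child: "TreeNode | None" = None
    out_child: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def decision_nodes(self) -> list["TreeNode"]:
        if self.is_leaf:
            return []
        out = [self]
        out += self.in_child.decision_nodes()
        out += self.out_child.decision_nodes()
        return out


@dataclass(frozen=True)
class TreeParams:
    min_leaf: int = 20
    max_depth: int = 4
    stop_alpha: float = 0.05


def _candidate_splits(values: pd.Series) -> list[tuple]:
    """One-vs-rest candidate level sets, deduplicated against complements."""
    levels = sorted(values.dropna().unique(), key=str)
    if len(levels) < 2:
        return []
    if len(levels) == 2:
        return [(levels[0],)]
    return [(lv,) for lv in levels]


def build_partition_tree(
    cohort: pd.DataFrame,
    features: Sequence[str],
    outcome: str = OUTCOME_COLUMN,
    params: TreeParams = TreeParams(),
) -> TreeNode:
    """Grow the partitioning tree; a root with no admissible split is a leaf."""
    if cohort.shape[0] < 2 * params.min_leaf:
        raise ValueError(
            f"need at least {2 * params.min_leaf} patients, got {cohort.shape[0]}"
        )
    y_all = cohort[outcome].to_numpy(dtype=int)
    if set(np.unique(y_all)) - {0, 1}:
        raise ValueError("outcome must be binary 0/1")

    def grow(idx: np.ndarray, depth: int) -> TreeNode:
        y = y_all[idx]
        node = TreeNode(depth=depth, n=len(idx), n_dead=int(y.sum()))
        if depth >= params.max_depth or len(idx) < 2 * params.min_leaf or y.min() == y.max():
            return node
        best = None  # (p, feature_order, levels_key, feature, levels, stat, table, mask)
        n_candidates = 0
        for order, feat in enumerate(features):
            col = cohort[feat].iloc[idx]
            for levels in _candidate_splits(col):
                mask = col.isin(levels).to_numpy() & col.notna().to_numpy()
                n_in = int(mask.sum())
                if n_in < params.min_leaf or len(idx) - n_in < params.min_leaf:
                    continue
                n_candidates += 1
                tab = (
                    int(y[mask].sum()),
                    int((1 - y[mask]).sum()),
                    int(y[~mask].sum()),
                    int((1 - y[~mask]).sum()),
                )
                stat, p = chi2_2x2(*tab)
                key = (p, order, tuple(str(lv) for lv in levels))
                if best is None or key < best[0]:
                    best = (key, feat, levels, stat, p, tab, mask)
        # Bonferroni over the candidate splits examined at this node keeps the
        # family-wise split rate at stop_alpha under pure noise
        if best is None or min(1.0, best[4] * n_candidates) >= params.stop_alpha:
            return node
        _, feat, levels, stat, p, tab, mask = best
        node.feature = feat
        node.levels = tuple(levels)
        node.chi2, node.p_value, node.table = stat, p, tab
        node.in_child = grow(idx[mask], depth + 1)
        node.out_child = grow(idx[~mask], depth + 1)
        return node

    return grow(np.arange(len(cohort)), 0)


@dataclass
class Rule:
    feature: str
    levels: tuple  # satisfied when patient's feature value is in levels
    points: int
    odds_ratio: float
    node_path: str = ""


@dataclass
class ClinicoScoreModel:
    """Integer scoring rules derived from the partitioning tree."""

    rules: list[Rule]
    cuts: dict[str, float] = field(default_factory=dict)
    known_levels: dict[str, list] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "rules": [
                {
                    "feature": r.feature,
                    "levels": list(r.levels),
                    "points": r.points,
                    "odds_ratio": r.odds_ratio,
                    "node_path": r.node_path,
                }
                for r in self.rules
            ],
            "cuts": self.cuts,
            "known_levels": {k: list(v) for k, v in self.known_levels.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClinicoScoreModel":
        return cls(
            rules=[
                Rule(
                    feature=r["feature"],
                    levels=tuple(r["levels"]),
                    points=int(r["points"]),
                    odds_ratio=float(r["odds_ratio"]),
                    node_path=r.get("node_path", ""),
                )
                for r in d["rules"]
            ],
            cuts=dict(d.get("cuts", {})),
            known_levels={k: list(v) for k, v in d.get("known_levels", {}).items()},
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "ClinicoScoreModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def node_odds_ratio(table: tuple, risk_in: bool) -> float:
    """Death odds ratio of the risk side vs the other, 0.5-corrected for zeros."""
    in_dead, in_alive, out_dead, out_alive = map(float, table)
    if not risk_in:
        in_dead, in_alive, out_dead, out_alive = out_dead, out_alive, in_dead, in_alive
    if min(in_dead, in_alive, out_dead, out_alive) == 0:
        in_dead, in_alive, out_dead, out_alive = (
            in_dead + 0.5,
            in_alive + 0.5,
            out_dead + 0.5,
            out_alive + 0.5,
        )
    return (in_dead * out_alive) / (in_alive * out_dead)


def tree_to_score(tree: TreeNode, cohort: pd.DataFrame, features: Sequence[str]) -> ClinicoScoreModel:
    """Turn every decision node into an integer-point rule.

    The risk side of a node is the branch with the higher death rate; its
    odds ratio against the other branch, rounded half-to-even, is the rule's
    points.  Rules are evaluated independently of tree paths when scoring.
    """
    rules: list[Rule] = []

    def walk(node: TreeNode, path: str) -> None:
        if node.is_leaf:
            return
        in_dead, in_alive, out_dead, out_alive = node.table
        rate_in = in_dead / max(in_dead + in_alive, 1)
        rate_out = out_dead / max(out_dead + out_alive, 1)
        risk_in = rate_in >= rate_out
        or_ = node_odds_ratio(node.table, risk_in)
        points = int(round(or_))  # Python round: banker's rounding on halves
        levels = node.levels
        if not risk_in:
            # complement within the levels observed at this node
            observed = sorted(cohort[node.feature].dropna().unique(), key=str)
            levels = tuple(lv for lv in observed if lv not in node.levels)
        rules.append(
            Rule(
                feature=node.feature,
                levels=levels,
                points=points,
                odds_ratio=float(or_),
                node_path=path or "root",
            )
        )
        walk(node.in_child, path + "I")
        walk(node.out_child, path + "O")

    walk(tree, "")
    known = {
        f: sorted(cohort[f].dropna().unique(), key=str)
        for f in {r.feature for r in rules}
    }
    return ClinicoScoreModel(rules=rules, known_levels=known)


def score_patients(model: ClinicoScoreModel, cohort: pd.DataFrame) -> pd.Series:
    """Sum rule points over satisfied rules for every patient.

    A missing value in a rule's feature skips that rule for that patient
    (logged); an unseen category level is an error naming it.
    """
    scores = pd.Series(0, index=cohort.index, dtype=int, name="clinico_score")
    for feat in {r.feature for r in model.rules}:
        if feat not in cohort.columns:
            raise KeyError(f"cohort lacks model feature {feat!r}")
        unknown = set(cohort[feat].dropna().unique()) - set(model.known_levels.get(feat, []))
        if unknown:
            raise ValueError(f"unknown category level(s) {sorted(unknown, key=str)} for feature {feat!r}")
        n_missing = int(cohort[feat].isna().sum())
        if n_missing:
            logger.warning("feature %s missing for %d patients; their rules are skipped", feat, n_missing)
    for rule in model.rules:
        satisfied = cohort[rule.feature].isin(rule.levels) & cohort[rule.feature].notna()
        scores[satisfied.to_numpy()] += rule.points
    return scores


def prepare_features(
    cohort: pd.DataFrame,
    features: Sequence[str] = PANEL_FEATURES,
    continuous: Sequence[str] = CONTINUOUS_FEATURES,
    outcome: str = OUTCOME_COLUMN,
    cuts: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, list[str], dict[str, float]]:
    """Dichotomize continuous panel features and drop incomplete ones.

    Returns (augmented cohort, usable feature names, derived cuts).  A
    feature with >= 5% missing values is excluded from the candidate list
    (scores are built only from near-complete features, no imputation).
    """
    cohort = cohort.copy()
    derived_cuts = dict(cuts or {})
    usable: list[str] = []
    for feat in features:
        if feat not in cohort.columns:
            raise KeyError(f"cohort lacks panel feature {feat!r}")
        if cohort[feat].isna().mean() >= MAX_MISSING_FRACTION:
            logger.warning("feature %s has >= 5%% missing values; excluded", feat)
            continue
        if feat in continuous:
            cut = derived_cuts.get(feat)
            if cut is None:
                cut = dichotomize_continuous(cohort, feat, outcome=outcome)
                derived_cuts[feat] = cut
            col = f"{feat}_ge_{cut:g}"
            cohort[col] = np.where(
                cohort[feat].isna(), None, (cohort[feat] >= cut).map({True: "yes", False: "no"})
            )
            usable.append(col)
        else:
            usable.append(feat)
    return cohort, usable, derived_cuts


def derive_clinico_score(
    cohort: pd.DataFrame,
    features: Sequence[str] = PANEL_FEATURES,
    params: TreeParams = TreeParams(),
    outcome: str = OUTCOME_COLUMN,
) -> tuple[ClinicoScoreModel, pd.Series, TreeNode]:
    """End-to-end: dichotomize, grow tree, extract rules, score the cohort."""
    prepared, usable, cuts = prepare_features(cohort, features, outcome=outcome)
    tree = build_partition_tree(prepared, usable, outcome=outcome, params=params)
    model = tree_to_score(tree, prepared, usable)
    model.cuts = cuts
    scores = score_patients(model, prepared)
    return model, scores, tree


def apply_clinico_score(model: ClinicoScoreModel, cohort: pd.DataFrame) -> pd.Series:
    """Score a new cohort with a derived model (re-applies stored age cuts)."""
    prepared, _, _ = prepare_features(
        cohort,
        features=[f for f in PANEL_FEATURES if f in cohort.columns],
        cuts=model.cuts,
    )
    return score_patients(model, prepared)
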