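"""Recursive-partitioning score: cuts, splits, odds-ratio points, scoring."""

import numpy as np
import pandas as pd
import pytest

from reasonscore import SimulationConfig
from reasonscore.clinico import (
    ClinicoScoreModel,
    Rule,
    TreeParams,
    apply_clinico_score,
    build_partition_tree,
    chi2_2x2,
    derive_clinico_score,
    dichotomize_continuous,
    node_odds_ratio,
    score_patients,
    tree_to_score,
)
from reasonscore.simulate import generate_cohort


def _cohort(n, rng, effects=None, event_rate=0.37, seed=None):
    cfg = SimulationConfig(
        n_patients=n,
        event_rate=event_rate,
        clinical_effects=effects if effects is not None else {},
        seed=seed if seed is not None else int(rng.integers(0, 2**31 - 1)),
    )
    return generate_cohort(cfg)


class TestChiSquare:
    @pytest.mark.parametrize("table", [(8, 2, 2, 8), (10, 5, 3, 12), (1, 9, 9, 1)])
    def test_matches_closed_form(self, table):
        a, b, c, d = table
        n = a + b + c + d
        expected = (a * d - b * c) ** 2 * n / ((a + b) * (c + d) * (a + c) * (b + d))
        stat, p = chi2_2x2(a, b, c, d)
        assert stat == pytest.approx(expected)
        from scipy.stats import chi2

        assert p == pytest.approx(chi2.sf(expected, 1))

    def test_degenerate_margin_is_null(self):
        assert chi2_2x2(0, 0, 3, 4) == (0.0, 1.0)


class TestDichotomize:
    def test_planted_age_threshold_recovered(self):
        rng = np.random.default_rng(0)
        hits = 0
        for seed in range(20):
            cohort = _cohort(500, rng, effects={"age": 4.0}, seed=seed)
            cut = dichotomize_continuous(cohort, "age")
            hits += cut in {60.0, 65.0, 70.0}
        assert hits >= 18  # planted risk jump is at age 65

    def test_constant_feature_rejected(self):
        df = pd.DataFrame({"age": [50.0] * 40, "vital_status_5yr": [0, 1] * 20})
        with pytest.raises(ValueError, match="constant"):
            dichotomize_continuous(df, "age")

    def test_tie_takes_smaller_cut(self):
        # outcome independent of feature: all cuts give stat 0 -> smallest wins
        df = pd.DataFrame(
            {"age": np.r_[np.full(20, 50.0), np.full(20, 70.0)],
             "vital_status_5yr": [0, 1] * 20}
        )
        assert dichotomize_continuous(df, "age") == 55.0


class TestOddsRatioPoints:
    def test_hand_computed_or_sixteen(self):
        # exposed 8 dead / 2 alive vs unexposed 2 dead / 8 alive
        assert node_odds_ratio((8, 2, 2, 8), risk_in=True) == pytest.approx(16.0)

    def test_zero_cell_uses_haldane_correction(self):
        or_ = node_odds_ratio((5, 5, 0, 10), risk_in=True)
        assert or_ == pytest.approx((5.5 * 10.5) / (5.5 * 0.5))

    @pytest.mark.parametrize("or_,points", [(1.4, 1), (2.5, 2), (3.5, 4), (16.0, 16)])
    def test_rounding_is_half_even(self, or_, points):
        assert int(round(or_)) == points


class TestTree:
    def test_single_planted_factor_recovered(self):
        rng = np.random.default_rng(1)
        hits = 0
        for seed in range(20):
            cohort = _cohort(400, rng, effects={"pni": 6.0}, seed=seed)
            tree = build_partition_tree(cohort, ["pni", "sex", "alcohol"])
            hits += (not tree.is_leaf) and tree.feature == "pni"
        assert hits >= 18

    def test_pure_noise_usually_single_leaf(self):
        rng = np.random.default_rng(2)
        single = 0
        n_seeds = 30
        for seed in range(n_seeds):
            cohort = _cohort(300, rng, effects={}, seed=seed + 1000)
            _, usable = cohort, ["sex", "race", "tobacco", "alcohol", "grade", "stage", "pni", "lvi", "margin"]
            tree = build_partition_tree(cohort, usable)
            single += tree.is_leaf
        assert single >= int(0.9 * n_seeds)

    def test_deterministic_outcome_gives_pure_leaves(self):
        n = 100
        cohort = pd.DataFrame(
            {"pni": ["yes"] * 50 + ["no"] * 50, "vital_status_5yr": [1] * 50 + [0] * 50}
        )
        tree = build_partition_tree(cohort, ["pni"])
        assert tree.feature == "pni"
        assert {tree.in_child.n_dead, tree.out_child.n_dead} <= {0, 50}
        assert tree.in_child.is_leaf and tree.out_child.is_leaf

    def test_tree_is_deterministic(self):
        rng = np.random.default_rng(3)
        cohort = _cohort(300, rng, effects={"age": 3.0, "pni": 4.0}, seed=5)
        m1, s1, _ = derive_clinico_score(cohort)
        m2, s2, _ = derive_clinico_score(cohort)
        assert m1.to_dict() == m2.to_dict()
        assert (s1 == s2).all()

    def test_too_small_cohort_rejected(self):
        cohort = pd.DataFrame({"pni": ["yes"] * 10, "vital_status_5yr": [0, 1] * 5})
        with pytest.raises(ValueError, match="patients"):
            build_partition_tree(cohort, ["pni"])


class TestScoring:
    def _model(self):
        return ClinicoScoreModel(
            rules=[
                Rule("pni", ("yes",), 4, 4.2),
                Rule("grade", ("moderate", "poor"), 2, 2.1),
                Rule("age_band", ("old",), 3, 3.3),
            ],
            known_levels={
                "pni": ["no", "yes"],
                "grade": ["moderate", "poor", "well"],
                "age_band": ["old", "young"],
            },
        )

    def test_manual_tally(self):
        cohort = pd.DataFrame(
            {
                "pni": ["yes", "no", "yes"],
                "grade": ["well", "poor", "moderate"],
                "age_band": ["young", "young", "old"],
            },
            index=["p1", "p2", "p3"],
        )
        scores = score_patients(self._model(), cohort)
        assert scores.tolist() == [4, 2, 9]

    def test_no_rules_satisfied_and_all_satisfied(self):
        cohort = pd.DataFrame(
            {"pni": ["no", "yes"], "grade": ["well", "poor"], "age_band": ["young", "old"]}
        )
        assert score_patients(self._model(), cohort).tolist() == [0, 9]

    def test_missing_value_skips_rule(self):
        cohort = pd.DataFrame(
            {"pni": [None], "grade": ["poor"], "age_band": ["old"]}
        )
        assert score_patients(self._model(), cohort).tolist() == [5]

    def test_unknown_level_is_named(self):
        cohort = pd.DataFrame(
            {"pni": ["maybe"], "grade": ["poor"], "age_band": ["old"]}
        )
        with pytest.raises(ValueError, match="maybe"):
            score_patients(self._model(), cohort)

    def test_monotone_adding_satisfied_rule(self):
        model = self._model()
        cohort = pd.DataFrame({"pni": ["no"], "grade": ["poor"], "age_band": ["young"]})
        base = score_patients(model, cohort).iloc[0]
        cohort2 = cohort.assign(pni=["yes"])
        assert score_patients(model, cohort2).iloc[0] == base + 4

    def test_single_leaf_tree_scores_zero(self):
        rng = np.random.default_rng(4)
        cohort = _cohort(200, rng, effects={}, seed=77)
        tree = build_partition_tree(cohort, ["sex"], params=TreeParams(stop_alpha=1e-12))
        model = tree_to_score(tree, cohort, ["sex"])
        assert model.rules == []
        assert (score_patients(model, cohort) == 0).all()

    def test_model_json_roundtrip(self, tmp_path):
        model = self._model()
        model.write(tmp_path / "model.json")
        again = ClinicoScoreModel.read(tmp_path / "model.json")
        assert again.to_dict() == model.to_dict()

    def test_apply_reuses_stored_age_cut(self):
        rng = np.random.default_rng(6)
        train = _cohort(400, rng, effects={"age": 4.0}, seed=13)
        model, _, _ = derive_clinico_score(train)
        test = _cohort(400, rng, effects={"age": 4.0}, seed=14)
        scores = apply_clinico_score(model, test)
        assert scores.notna().all() and (scores >= 0).all()
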