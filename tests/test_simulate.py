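"""Synthetic-data generator: planted structure, calibration, reproducibility."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from reasonscore import SimulationConfig, generate_bundle, write_bundle
from reasonscore.simulate import (
    ConfigurationError,
    generate_cohort,
    generate_expression,
    generate_methylation,
)
from reasonscore import io as rsio


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_patients": 0},
            {"event_rate": 0.0},
            {"event_rate": 1.0},
            {"n_patients": 5, "event_rate": 0.1},  # expected events < 2
            {"n_signature_cpgs": 5, "n_signature_genes": 12},
            {"expr_corr": {"ABCA2": 1.0}},
            {"clinical_effects": {"shoe_size": 2.0}},
            {"batch_outcome_corr": 1.0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SimulationConfig(**kwargs)


class TestCohort:
    def test_event_rate_within_binomial_bounds(self):
        cfg = SimulationConfig(n_patients=100, event_rate=0.14, seed=42, clinical_effects={})
        cohort = generate_cohort(cfg)
        events = int(cohort["vital_status_5yr"].sum())
        lo, hi = stats.binom.interval(0.99, 100, 0.14)
        assert lo <= events <= hi

    def test_null_effects_leave_features_unassociated(self):
        # pooled over seeds and features, chi-square at alpha=0.01 should be
        # non-significant ~99% of the time
        tested = significant = 0
        features = ["sex", "tobacco", "alcohol", "pni", "lvi", "stage", "margin"]
        for seed in range(30):
            cfg = SimulationConfig(
                n_patients=120, event_rate=0.3, seed=seed, clinical_effects={}
            )
            cohort = generate_cohort(cfg)
            y = cohort["vital_status_5yr"]
            for feat in features:
                tab = pd.crosstab(cohort[feat], y)
                if tab.shape != (2, 2):
                    continue
                _, p, _, _ = stats.chi2_contingency(tab, correction=False)
                tested += 1
                significant += p < 0.01
        assert significant / tested <= 0.05

    def test_planted_effect_raises_risk(self):
        cfg = SimulationConfig(
            n_patients=2000, event_rate=0.3, seed=3, clinical_effects={"pni": 4.0}
        )
        cohort = generate_cohort(cfg)
        rate = cohort.groupby("pni")["vital_status_5yr"].mean()
        assert rate["yes"] > rate["no"] + 0.1

    def test_columns_complete(self):
        cohort = generate_cohort(SimulationConfig(seed=1))
        assert list(cohort.columns) == list(rsio.CLINICAL_COLUMNS)
        assert cohort.notna().all().all()


class TestMethylation:
    def test_beta_in_unit_interval_even_with_large_shift(self):
        cfg = SimulationConfig(seed=5, n_patients=40, n_probes=400, delta_beta=0.9,
                               event_rate=0.3)
        bundle = generate_bundle(cfg)
        b = bundle.methylation.beta.to_numpy()
        assert b.min() >= 0.0 and b.max() <= 1.0

    def test_planted_hyper_direction_forced(self, planted_bundle):
        beta = planted_bundle.methylation.beta
        y = planted_bundle.methylation.outcome
        dead = y.index[y == 1]
        alive = y.index[y == 0]
        for cpg, info in planted_bundle.truth["planted_cpgs"].items():
            diff = beta.loc[cpg, dead].mean() - beta.loc[cpg, alive].mean()
            assert diff > 0 if info["direction"] == "hyper" else diff < 0

    def test_manifest_fractions_materialize(self, planted_bundle):
        man = planted_bundle.manifest
        n = len(man)
        assert (man["chrom"].isin(["X", "Y"])).sum() == round(0.03 * n)
        assert man["snp_flag"].sum() == round(0.04 * n)
        assert (man["gene"] == "").sum() == round(0.20 * n)
        assert man["cross_reactive_flag"].sum() == round(0.04 * n)

    def test_null_delta_shows_no_signal_downstream(self):
        from reasonscore import run_cascade, run_differential_methylation

        cfg = SimulationConfig(seed=17, n_patients=60, n_probes=800, delta_beta=0.0,
                               event_rate=0.3)
        bundle = generate_bundle(cfg)
        ds, _ = run_cascade(bundle.methylation, bundle.manifest)
        res = run_differential_methylation(ds, None, bundle.manifest)
        assert res.table["p_adj"].min() >= 0.1

    def test_empty_cohort_rejected(self):
        cfg = SimulationConfig(seed=1)
        with pytest.raises(ConfigurationError):
            generate_methylation(cfg, pd.DataFrame())


class TestExpression:
    def test_target_correlation_realized(self):
        cfg = SimulationConfig(
            seed=23, n_patients=200, n_probes=300, expr_corr={"ABCA2": 0.5}
        )
        bundle = generate_bundle(cfg)
        cpg = next(
            c for c, info in bundle.truth["planted_cpgs"].items() if info["gene"] == "ABCA2"
        )
        r = np.corrcoef(
            bundle.expression.loc["ABCA2"], bundle.methylation.beta.loc[cpg]
        )[0, 1]
        assert r > 0 and abs(r - 0.5) <= 0.15

    def test_negative_sign_forced(self):
        cfg = SimulationConfig(
            seed=29, n_patients=150, n_probes=300, expr_corr={"TRPA1": -0.6}
        )
        bundle = generate_bundle(cfg)
        cpg = next(
            c for c, info in bundle.truth["planted_cpgs"].items() if info["gene"] == "TRPA1"
        )
        assert np.corrcoef(
            bundle.expression.loc["TRPA1"], bundle.methylation.beta.loc[cpg]
        )[0, 1] < 0

    def test_unconfigured_gene_within_null_bounds(self):
        cfg = SimulationConfig(seed=31, n_patients=200, n_probes=300, expr_corr={})
        bundle = generate_bundle(cfg)
        bound = 4.0 / np.sqrt(200)  # ~4 SE of a null Pearson r
        for cpg, info in bundle.truth["planted_cpgs"].items():
            r = np.corrcoef(
                bundle.expression.loc[info["gene"]], bundle.methylation.beta.loc[cpg]
            )[0, 1]
            assert abs(r) < bound

    def test_unknown_expr_gene_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(expr_corr={"NOT_A_GENE": 0.5})


class TestBundle:
    def test_fixed_seed_byte_identical(self, tmp_path):
        cfg = SimulationConfig(seed=8, n_patients=30, n_probes=200, event_rate=0.3)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_bundle(generate_bundle(cfg), d1)
        write_bundle(generate_bundle(cfg), d2)
        for f in sorted(p.name for p in d1.iterdir()):
            assert (d1 / f).read_bytes() == (d2 / f).read_bytes(), f

    def test_roundtrip_and_alignment(self, tmp_path):
        cfg = SimulationConfig(seed=9, n_patients=25, n_probes=150, event_rate=0.3)
        bundle = generate_bundle(cfg)
        paths = write_bundle(bundle, tmp_path)
        beta = rsio.read_matrix(paths["beta"], "beta")
        pd.testing.assert_frame_equal(beta, bundle.methylation.beta)
        clin = rsio.read_clinical(paths["clinical"])
        counts = rsio.read_matrix(paths["counts"], "counts")
        assert list(beta.columns) == list(clin.index) == list(counts.columns)

    def test_truth_lists_exactly_the_signature(self, tmp_path):
        cfg = SimulationConfig(seed=10, n_patients=30, n_probes=200, event_rate=0.3)
        paths = write_bundle(generate_bundle(cfg), tmp_path)
        truth = json.loads(paths["truth"].read_text())
        assert len(truth["planted_cpgs"]) == cfg.n_signature_cpgs
        assert len(set(i["gene"] for i in truth["planted_cpgs"].values())) == cfg.n_signature_genes
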