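"""Moderated-t machinery: transforms, OLS fits, variance shrinkage, BH, selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, special, stats

from reasonscore import (
    DMResults,
    Signature,
    adjust_bh,
    beta_to_m,
    empirical_bayes_moderate,
    fit_probe_models,
    run_differential_methylation,
    select_signature,
)
from reasonscore.dm import ProbeFits, estimate_prior, ordinary_t


class TestBetaToM:
    @pytest.mark.parametrize("beta,expected", [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0)])
    def test_known_values(self, beta, expected):
        assert beta_to_m(np.array([beta]))[0] == pytest.approx(expected)

    def test_extremes_clip_to_finite(self):
        m = beta_to_m(np.array([0.0, 1.0]), eps=1e-6)
        assert np.all(np.isfinite(m))
        assert m[0] == pytest.approx(np.log2(1e-6 / (1 - 1e-6)))
        assert m[1] == pytest.approx(-m[0])


class TestProbeFits:
    def test_two_group_effect_equals_mean_difference(self):
        rng = np.random.default_rng(0)
        y = np.array([0.0] * 5 + [1.0] * 5)
        m = rng.normal(0, 1, (20, 10))
        fits = fit_probe_models(m, y)
        expected = m[:, 5:].mean(axis=1) - m[:, :5].mean(axis=1)
        assert np.allclose(fits.effect, expected)
        assert fits.df_resid == 8

    def test_constant_probe_flagged_zero_variance(self):
        y = np.array([0.0, 0.0, 1.0, 1.0])
        m = np.vstack([np.full(4, 2.0), [0.0, 1.0, 2.0, 3.0]])
        fits = fit_probe_models(m, y)
        assert fits.sigma2[0] == pytest.approx(0.0)
        assert fits.effect[0] == pytest.approx(0.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        y = np.array([0.0, 1.0, 0.0, 1.0, 0.0, 1.0, 1.0, 0.0])
        cov = rng.normal(0, 1, (8, 2))
        m = rng.normal(0, 1, (5, 8))
        fits = fit_probe_models(m, y, cov)
        x = np.column_stack([np.ones(8), y, cov])
        for g in range(5):
            beta_hat = np.linalg.solve(x.T @ x, x.T @ m[g])
            assert fits.effect[g] == pytest.approx(beta_hat[1])
            resid = m[g] - x @ beta_hat
            assert fits.sigma2[g] == pytest.approx(resid @ resid / (8 - 4))

    def test_collinear_design_names_columns(self):
        y = np.array([0.0, 0.0, 1.0, 1.0, 0.0, 1.0])
        cov = pd.DataFrame({"dup": y})
        with pytest.raises(ValueError, match="dup"):
            fit_probe_models(np.random.default_rng(0).normal(0, 1, (3, 6)), y, cov)


def _oracle_prior(sigma2, df):
    """Independent (d0, s0^2) solver: brentq on the trigamma moment equation."""
    z = np.log(sigma2[sigma2 > 0])
    e = z - special.digamma(df / 2) + np.log(df / 2)
    excess = e.var(ddof=1) - special.polygamma(1, df / 2)
    if excess <= 0:
        return np.inf, float(np.exp(e.mean()))
    half_d0 = optimize.brentq(
        lambda h: special.polygamma(1, h) - excess, 1e-8, 1e8
    )
    d0 = 2 * half_d0
    s0 = np.exp(e.mean() + special.digamma(half_d0) - np.log(half_d0))
    return d0, float(s0)


class TestEmpiricalBayes:
    def test_prior_matches_independent_moment_oracle(self):
        rng = np.random.default_rng(7)
        d0_true, s0_true, df = 8.0, 0.5, 10
        # scaled inverse chi-square draws for per-probe variances
        true_var = d0_true * s0_true / rng.chisquare(d0_true, 500)
        s2 = true_var * rng.chisquare(df, 500) / df
        d0_hat, s0_hat = estimate_prior(s2, df)
        d0_oracle, s0_oracle = _oracle_prior(s2, df)
        assert d0_hat == pytest.approx(d0_oracle, rel=0.10)
        assert s0_hat == pytest.approx(s0_oracle, rel=0.10)
        # and the estimates recover the generating hyperparameters loosely
        assert 0.3 < s0_hat / s0_true < 3.0

    def test_identical_variances_hit_infinite_d0_branch(self):
        fits = ProbeFits(
            probe_ids=pd.Index([f"p{i}" for i in range(10)]),
            effect=np.linspace(-1, 1, 10),
            sigma2=np.full(10, 0.7),
            df_resid=6,
            v_outcome=0.5,
        )
        res = empirical_bayes_moderate(fits)
        assert np.isinf(res.d0)
        expected_t = fits.effect / np.sqrt(res.s0_sq * 0.5)
        assert np.allclose(res.table["t_mod"], expected_t)
        assert np.allclose(res.table["p"], 2 * stats.norm.sf(np.abs(expected_t)))

    def test_d0_zero_limit_equals_ordinary_t(self):
        rng = np.random.default_rng(3)
        fits = ProbeFits(
            probe_ids=pd.Index([f"p{i}" for i in range(50)]),
            effect=rng.normal(0, 1, 50),
            sigma2=rng.chisquare(5, 50) / 5,
            df_resid=5,
            v_outcome=0.25,
        )
        d0 = 1e-9  # shrinkage weight d0/(d0+df) -> 0
        s2_post = (d0 * 1.0 + 5 * fits.sigma2) / (d0 + 5)
        t_manual = fits.effect / np.sqrt(s2_post * 0.25)
        t_ord, _ = ordinary_t(fits)
        assert np.allclose(t_manual, t_ord, rtol=1e-6)

    def test_moderated_t_against_ttest_when_unshrunk(self):
        # sanity: ordinary t equals scipy's equal-variance two-sample t
        rng = np.random.default_rng(4)
        y = np.array([0.0] * 6 + [1.0] * 6)
        m = rng.normal(0, 1, (30, 12))
        fits = fit_probe_models(m, y)
        t_ord, p_ord = ordinary_t(fits)
        ref = stats.ttest_ind(m[:, 6:], m[:, :6], axis=1, equal_var=True)
        assert np.allclose(t_ord, ref.statistic)
        assert np.allclose(p_ord, ref.pvalue)

    def test_relabeling_preserving_design_leaves_p_unchanged(self):
        rng = np.random.default_rng(5)
        y = np.array([0.0] * 5 + [1.0] * 5)
        m = rng.normal(0, 1, (40, 10))
        res1 = empirical_bayes_moderate(fit_probe_models(m, y))
        perm = np.r_[rng.permutation(5), 5 + rng.permutation(5)]
        res2 = empirical_bayes_moderate(fit_probe_models(m[:, perm], y[perm]))
        assert np.allclose(res1.table["p"], res2.table["p"])


def _bh_bruteforce(p):
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        prev = min(prev, p[idx] * m / rank)
        adj[idx] = prev
    return adj


class TestBenjaminiHochberg:
    def test_hand_computed_step_up(self):
        assert np.allclose(adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_degenerate(self):
        assert adjust_bh([0.2])[0] == pytest.approx(0.2)
        assert np.allclose(adjust_bh([1.0, 1.0, 1.0]), 1.0)

    @settings(deadline=None, max_examples=200)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=8,
        )
    )
    def test_matches_bruteforce_on_short_inputs(self, p):
        assert np.allclose(adjust_bh(p), _bh_bruteforce(np.array(p)))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.5])


def _make_results(p_adj, genes, logfc):
    n = len(p_adj)
    table = pd.DataFrame(
        {
            "logFC_M": logfc,
            "t_mod": np.zeros(n),
            "df_total": 10.0,
            "p": np.asarray(p_adj) / 2,
            "p_adj": p_adj,
            "gene": genes,
        },
        index=pd.Index([f"cg{i:03d}" for i in range(n)]),
    )
    return DMResults(table=table, d0=4.0, s0_sq=1.0, df_resid=10)


class TestSignatureSelection:
    def test_printed_cardinalities_on_constructed_fixture(self):
        # 13 selected CpGs across 12 genes (one gene carries two CpGs)
        genes = [f"GENE{i:02d}" for i in range(12)] + ["GENE00", "OTHER", "OTHER2"]
        p_adj = [0.01] * 13 + [0.5, 0.9]
        logfc = [1.0] * 13 + [1.0, -1.0]
        sig = select_signature(_make_results(p_adj, genes, logfc), alpha=0.1)
        assert (sig.n_cpgs, sig.n_genes) == (13, 12)

    def test_alpha_zero_selects_nothing(self):
        sig = select_signature(
            _make_results([0.0001] * 3, ["A", "B", "C"], [1, 1, 1]), alpha=0.0
        )
        assert sig.n_cpgs == 0 and sig.n_genes == 0

    def test_direction_from_most_significant_cpg(self):
        res = _make_results([0.01, 0.05], ["A", "A"], [-2.0, 3.0])
        sig = select_signature(res, alpha=0.1)
        assert sig.directions["A"] == "hypo"  # best CpG has negative effect

    def test_signature_roundtrip(self):
        sig = Signature(
            cpgs=["cg1"], genes=["A"], cpg_to_gene={"cg1": "A"}, directions={"A": "hyper"}
        )
        assert Signature.from_dict(sig.to_dict()) == sig


class TestEndToEnd:
    def test_planted_cpgs_recovered(self, planted_bundle):
        from reasonscore import estimate_surrogates, run_cascade, select_covariates

        ds, _ = run_cascade(planted_bundle.methylation, planted_bundle.manifest)
        cov = select_covariates(estimate_surrogates(ds, n_sv="auto"))
        res = run_differential_methylation(ds, cov, planted_bundle.manifest)
        sig = select_signature(res, alpha=0.1)
        planted = set(planted_bundle.truth["planted_cpgs"]) & set(ds.probe_ids)
        assert planted, "planted CpGs should survive the cascade"
        recovered = planted & set(sig.cpgs)
        assert len(recovered) / len(planted) >= 0.8
        # planted directions recovered
        for cpg in recovered:
            truth = planted_bundle.truth["planted_cpgs"][cpg]
            gene = sig.cpg_to_gene[cpg]
            assert sig.directions[gene] == truth["direction"]
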