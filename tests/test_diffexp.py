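"""Voom weighting, weighted fits, eBayes moderation and BH adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sgnseq.design import StudyDesign, generate_design
from sgnseq.diffexp import (
    WeightedLogExpr,
    voom_transform,
    fit_model,
    ebayes_moderate,
    pairwise_contrasts,
    adjust_bh,
    trigamma_inverse,
    fit_f_dist,
)
from sgnseq.normalization import tmm_factors
from sgnseq.synthetic import null_dataset
from conftest import make_matrix
from _oracles import wls_normal_equations_oracle, pooled_t_test_oracle


def wle_from_arrays(y, w, design):
    genes = [f"g{i}" for i in range(y.shape[0])]
    cols = list(design.sample_ids)
    return WeightedLogExpr(
        logcpm=pd.DataFrame(y, index=genes, columns=cols),
        weights=pd.DataFrame(w, index=genes, columns=cols),
        trend_x=np.array([0.0, 1.0]),
        trend_y=np.array([1.0, 1.0]),
        design=design,
    )


class TestFitModel:
    def test_unit_weight_hand_example(self, two_group_design):
        y = np.array([[1.0, 3.0, 10.0, 10.0]])
        fit = fit_model(wle_from_arrays(y, np.ones_like(y), two_group_design))
        assert fit.coefficients.loc["g0", "A"] == 2.0
        assert fit.coefficients.loc["g0", "B"] == 10.0
        # residual sum of squares (1-2)^2 + (3-2)^2 = 2 over df 2
        assert np.isclose(fit.sigma.loc["g0"] ** 2, 1.0)
        assert fit.df_residual == 2.0

    def test_weighted_mean_hand_example(self, two_group_design):
        y = np.array([[1.0, 3.0, 0.0, 0.0]])
        w = np.array([[4.0, 1.0, 1.0, 1.0]])
        fit = fit_model(wle_from_arrays(y, w, two_group_design))
        assert np.isclose(fit.coefficients.loc["g0", "A"], 1.4)

    def test_matches_normal_equations_oracle(self, two_group_design):
        rng = np.random.default_rng(11)
        y = rng.normal(size=(20, 4))
        w = rng.uniform(0.2, 5.0, size=(20, 4))
        fit = fit_model(wle_from_arrays(y, w, two_group_design))
        X = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], float)
        for i in range(20):
            beta, s2, cov, df = wls_normal_equations_oracle(X, y[i], w[i])
            assert np.allclose(fit.coefficients.iloc[i].to_numpy(), beta, atol=1e-10)
            assert np.isclose(fit.sigma.iloc[i] ** 2, s2, atol=1e-10)
            assert np.allclose(
                fit.stdev_unscaled.iloc[i].to_numpy() ** 2, np.diag(cov), atol=1e-10
            )


class TestEBayes:
    def test_prior_disabled_recovers_raw_variances(self, two_group_design):
        rng = np.random.default_rng(3)
        y = rng.normal(size=(30, 4))
        fit = fit_model(wle_from_arrays(y, np.ones_like(y), two_group_design))
        mod = ebayes_moderate(fit, prior_df=0.0)
        assert np.allclose(mod.post_var, fit.sigma**2)

    def test_infinite_prior_ranks_by_effect_over_se(self, two_group_design):
        rng = np.random.default_rng(4)
        y = rng.normal(size=(30, 4))
        fit = fit_model(wle_from_arrays(y, np.ones_like(y), two_group_design))
        mod = ebayes_moderate(fit, prior_df=np.inf, prior_var=2.0)
        tab = pairwise_contrasts(mod, [("A", "B")])
        effect = (
            (fit.coefficients["A"] - fit.coefficients["B"]).abs()
            / np.sqrt(fit.stdev_unscaled["A"] ** 2 + fit.stdev_unscaled["B"] ** 2)
        )
        assert list(tab.sort_values("t", key=abs).gene_id) == list(
            effect.sort_values().index
        )

    def test_posterior_var_between_prior_and_sample(self, two_group_design):
        rng = np.random.default_rng(5)
        y = rng.normal(size=(100, 4)) * rng.uniform(0.5, 2, size=(100, 1))
        fit = fit_model(wle_from_arrays(y, np.ones_like(y), two_group_design))
        mod = ebayes_moderate(fit)
        s2 = fit.sigma**2
        lo = np.minimum(s2, mod.prior_var)
        hi = np.maximum(s2, mod.prior_var)
        assert ((mod.post_var >= lo - 1e-12) & (mod.post_var <= hi + 1e-12)).all()

    def test_equal_variances_hit_infinite_prior_branch(self, two_group_design):
        y = np.tile([1.0, 3.0, 2.0, 6.0], (15, 1))
        fit = fit_model(wle_from_arrays(y, np.ones_like(y), two_group_design))
        with pytest.warns(UserWarning, match="prior df is infinite"):
            mod = ebayes_moderate(fit)
        assert np.isinf(mod.prior_df)
        assert np.allclose(mod.post_var, mod.prior_var)

    def test_trigamma_inverse_round_trip(self):
        from scipy.special import polygamma

        for x in (1e-8, 0.01, 0.5, 3.0, 1e8):
            assert np.isclose(float(polygamma(1, trigamma_inverse(x))), x, rtol=1e-5)

    def test_fit_f_dist_recovers_known_prior(self):
        # variances drawn from s0^2 * F(d, d0): moments should land close
        rng = np.random.default_rng(42)
        d, d0, s0 = 10, 8.0, 1.5
        s2 = s0 * rng.f(d, d0, size=20000)
        d0_hat, s0_hat = fit_f_dist(s2, d)
        assert abs(d0_hat - d0) / d0 < 0.1
        assert abs(s0_hat - s0) / s0 < 0.05


class TestContrasts:
    def test_self_contrast_is_null(self, two_group_design):
        rng = np.random.default_rng(6)
        y = rng.normal(size=(12, 4))
        mod = ebayes_moderate(
            fit_model(wle_from_arrays(y, np.ones_like(y), two_group_design))
        )
        tab = pairwise_contrasts(mod, [("A", "A")])
        assert (tab.log2FC == 0).all() and (tab.t == 0).all() and (tab.p == 1).all()

    def test_swap_antisymmetry(self, two_group_design):
        rng = np.random.default_rng(7)
        y = rng.normal(size=(12, 4))
        mod = ebayes_moderate(
            fit_model(wle_from_arrays(y, np.ones_like(y), two_group_design))
        )
        ab = pairwise_contrasts(mod, [("A", "B")])
        ba = pairwise_contrasts(mod, [("B", "A")])
        assert np.allclose(ab.log2FC, -ba.log2FC)
        assert np.allclose(ab.t, -ba.t)
        assert np.allclose(ab.p, ba.p) and np.allclose(ab.q, ba.q)

    def test_all_pairs_of_seven_groups(self, pipeline_result):
        assert pipeline_result.contrasts.contrast.nunique() == 21

    def test_unknown_group_rejected(self, two_group_design):
        rng = np.random.default_rng(8)
        y = rng.normal(size=(12, 4))
        mod = ebayes_moderate(
            fit_model(wle_from_arrays(y, np.ones_like(y), two_group_design))
        )
        with pytest.raises(ValueError, match="C"):
            pairwise_contrasts(mod, [("A", "C")])


class TestBH:
    def test_stepwise_minimum_example(self):
        assert np.allclose(adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p(self):
        assert adjust_bh([0.2])[0] == 0.2

    def test_hand_applied_step_up(self):
        assert np.allclose(adjust_bh([0.001, 0.5, 0.9, 1.0]), [0.004, 1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.5])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_monotone_in_sorted_p(self, pvals):
        q = adjust_bh(pvals)
        order = np.argsort(pvals)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert ((q >= 0) & (q <= 1)).all()


class TestVoom:
    def test_nb_trend_decreases(self):
        m = null_dataset(seed=2, n_genes=1500)
        v = voom_transform(m, tmm_factors(m))
        # sqrt-sd trend falls from the low-count to the high-count end
        n = len(v.trend_x)
        low = v.trend_y[: n // 4].mean()
        high = v.trend_y[-n // 4:].mean()
        assert low > high

    def test_flat_variance_gives_flat_weights(self):
        # equal-mean, equal-dispersion genes: no trend to exploit
        rng = np.random.default_rng(9)
        design = generate_design(3, include_refs=False)
        counts = rng.poisson(500, size=(800, 15))
        m = make_matrix(counts, design)
        v = voom_transform(m)
        genes_mid = v.weights.to_numpy()
        assert genes_mid.max() / genes_mid.min() < 2.0

    def test_degenerate_constant_input_has_finite_weights(self):
        design = generate_design(2, include_refs=False)
        counts = np.tile([[50], [100], [400], [20]], (1, 10))
        m = make_matrix(counts, design)
        v = voom_transform(m)
        assert np.isfinite(v.weights.to_numpy()).all()

    def test_single_replicate_sgn_age_rejected(self):
        design = StudyDesign(
            tuple(f"SGN_{a}" for a in ("E15.5", "P1", "P8", "P14", "P30")),
            tuple((f"s{i}", g, 1) for i, g in enumerate(
                f"SGN_{a}" for a in ("E15.5", "P1", "P8", "P14", "P30"))),
        )
        counts = np.random.default_rng(0).poisson(100, size=(50, 5))
        m = make_matrix(counts, design)
        with pytest.raises(ValueError, match="replicates"):
            voom_transform(m)


class TestLimitEquivalence:
    def test_unit_weights_zero_prior_equals_pooled_t_test(self):
        """With weights 1 and the prior disabled, moderated results reduce
        to the ordinary pooled-variance two-sample t-test per gene."""
        rng = np.random.default_rng(10)
        design = generate_design(3, include_refs=False)
        y = rng.normal(size=(40, 15))
        mod = ebayes_moderate(
            fit_model(wle_from_arrays(y, np.ones_like(y), design)), prior_df=0.0
        )
        tab = pairwise_contrasts(mod, [("SGN_P1", "SGN_P8")]).set_index("gene_id")
        sids = list(design.sample_ids)
        gi = {g: [sids.index(s) for s in design.samples_in(g)] for g in design.groups}
        for i in range(40):
            t, p, df = pooled_t_test_oracle(y[i], gi, ("SGN_P1", "SGN_P8"))
            row = tab.iloc[i]
            assert np.isclose(row.t, t, atol=1e-8)
            assert np.isclose(row.p, p, atol=1e-8)


class TestNullCalibration:
    def test_type_i_error_near_nominal_single_seed(self):
        m = null_dataset(seed=3, n_genes=1200)
        mod = ebayes_moderate(fit_model(voom_transform(m, tmm_factors(m))))
        tab = pairwise_contrasts(mod)
        frac = (tab.p < 0.05).mean()
        assert 0.02 < frac < 0.08
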