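"""Fixed and mixed differential models, Satterthwaite df, LRT, BH, run_de."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mtxdiff.models import (
    ModelSpec,
    bh_adjust,
    build_design,
    fit_fixed,
    fit_mixed,
    lrt_select,
    run_de,
    satterthwaite_df,
)
from tests.conftest import make_view


def bh_bruteforce(p):
    """Direct double-loop evaluation of the BH step-up definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank, i in enumerate(order, start=1):
        tail = [p[j] * m / (r + 1) for r, j in enumerate(order) if r + 1 >= rank]
        q[i] = min(1.0, min(tail))
    return q


def simulate_longitudinal(seed, S=20, m=3, sigma_subject=1.0, sigma_resid=1.0, delta=0.0):
    rng = np.random.default_rng(seed)
    n = S * m
    subj = np.repeat([f"s{i}" for i in range(S)], m)
    grp = np.repeat(rng.integers(0, 2, S), m)
    dna = rng.normal(size=n)
    taxa = rng.normal(size=n)
    u = np.repeat(rng.normal(0, sigma_subject, S), m)
    y = 0.8 * dna + 0.5 * taxa + delta * grp + u + rng.normal(0, sigma_resid, n)
    return make_view(y, dna, taxa, subj, np.where(grp == 1, "B", "A"))


class TestFixedFit:
    def test_exact_interpolation(self):
        view = simulate_longitudinal(0, S=10, m=2)
        X, names, _ = build_design(view, ModelSpec())
        beta_true = np.array([1.0, -2.0, 0.5, 3.0])
        view.rna = X @ beta_true
        fit = fit_fixed(view, ModelSpec())
        assert np.allclose(fit.params.to_numpy(), beta_true, atol=1e-10)
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-18)

    def test_constructed_shift_recovered_exactly(self):
        n = 30
        rng = np.random.default_rng(4)
        base = rng.normal(size=n // 2)
        y = np.concatenate([base, base + 2.5])
        groups = ["A"] * (n // 2) + ["B"] * (n // 2)
        dna = np.concatenate([rng.normal(size=n // 2)] * 2)
        taxa = np.concatenate([rng.normal(size=n // 2)] * 2)
        view = make_view(y, dna, taxa, ["s"] * n, groups)
        # identical response distributions shifted by +2.5 and noise-free in
        # the group direction: the phenotype coefficient is exactly 2.5
        fit = fit_fixed(view, ModelSpec(controls=("dna", "taxa")))
        assert fit.params["group"] == pytest.approx(2.5, abs=1e-10)

    def test_matches_pseudoinverse(self):
        rng = np.random.default_rng(11)
        view = simulate_longitudinal(11, S=15, m=2)
        fit = fit_fixed(view, ModelSpec())
        X, names, y = build_design(view, ModelSpec())
        beta_pinv = np.linalg.pinv(X) @ y
        assert np.max(np.abs(fit.params.to_numpy() - beta_pinv)) < 1e-8

    def test_rank_deficiency_raises(self):
        view = simulate_longitudinal(2, S=10, m=2)
        view.dna = view.taxa.copy()  # collinear controls
        with pytest.raises(np.linalg.LinAlgError):
            fit_fixed(view, ModelSpec())

    def test_nesting_rss_ordering(self):
        view = simulate_longitudinal(5, S=25, m=2)
        full = fit_fixed(view, ModelSpec(controls=("dna", "taxa")))
        assert full.rss <= fit_fixed(view, ModelSpec(controls=("dna",))).rss + 1e-10
        assert full.rss <= fit_fixed(view, ModelSpec(controls=("taxa",))).rss + 1e-10


class TestMixedFit:
    def test_single_obs_per_subject_degenerates_to_ols(self):
        rng = np.random.default_rng(7)
        n = 40
        view = make_view(
            rng.normal(size=n), rng.normal(size=n), rng.normal(size=n),
            [f"s{i}" for i in range(n)], rng.choice(["A", "B"], n),
        )
        mixed = fit_mixed(view, ModelSpec())
        fixed = fit_fixed(view, ModelSpec())
        assert mixed.vc.sigma_subject_sq == pytest.approx(0.0, abs=1e-10)
        assert np.max(np.abs(mixed.params - fixed.params)) < 1e-6
        df, fellback = satterthwaite_df(mixed, "group")
        assert df == pytest.approx(fixed.df_resid, abs=0.5)

    def test_variance_recovery_against_grid_oracle(self):
        # coarse independent grid search over the variance ratio maximizing
        # the restricted likelihood must agree with the optimizer
        from mtxdiff.models import _make_suff, _profiled_reml

        view = simulate_longitudinal(21, S=30, m=4)
        fit = fit_mixed(view, ModelSpec())
        X, _, y = build_design(view, ModelSpec())
        codes = pd.Categorical(view.meta["subject_id"]).codes.astype(int)
        suff = _make_suff(X, y, codes)
        grid = np.linspace(0.0, 5.0, 2001)
        vals = [_profiled_reml(suff, l) for l in grid]
        lam_grid = grid[int(np.argmax(vals))]
        lam_fit = fit.vc.sigma_subject_sq / fit.vc.sigma_resid_sq
        assert lam_fit == pytest.approx(lam_grid, abs=5e-3)

    def test_matches_statsmodels_mixedlm(self):
        statsmodels = pytest.importorskip("statsmodels.regression.mixed_linear_model")
        view = simulate_longitudinal(31, S=25, m=3)
        fit = fit_mixed(view, ModelSpec())
        X, names, y = build_design(view, ModelSpec())
        sm_fit = statsmodels.MixedLM(
            y, X, groups=view.meta["subject_id"].to_numpy()
        ).fit(reml=True)
        assert np.max(np.abs(fit.params.to_numpy() - sm_fit.fe_params)) < 1e-5
        assert fit.vc.sigma_subject_sq == pytest.approx(float(np.asarray(sm_fit.cov_re)[0, 0]), rel=1e-3)
        assert fit.vc.sigma_resid_sq == pytest.approx(float(sm_fit.scale), rel=1e-3)

    def test_gls_internal_consistency(self):
        # fixed effects equal explicit GLS at the fitted variance components
        view = simulate_longitudinal(13, S=20, m=3)
        fit = fit_mixed(view, ModelSpec())
        X, _, y = build_design(view, ModelSpec())
        codes = pd.Categorical(view.meta["subject_id"]).codes.astype(int)
        Z = np.zeros((len(y), codes.max() + 1))
        Z[np.arange(len(y)), codes] = 1.0
        V = fit.vc.sigma_resid_sq * np.eye(len(y)) + fit.vc.sigma_subject_sq * Z @ Z.T
        Vi = np.linalg.inv(V)
        beta_gls = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        assert np.max(np.abs(fit.params.to_numpy() - beta_gls)) < 1e-8

    def test_constant_response_handled(self):
        n = 24
        view = make_view(
            np.ones(n), np.arange(n, dtype=float), np.arange(n, dtype=float)[::-1],
            [f"s{i % 8}" for i in range(n)], ["A", "B"] * (n // 2),
        )
        fit = fit_mixed(view, ModelSpec(controls=("dna",)))
        assert fit.vc.sigma_resid_sq <= 1e-10 or not fit.converged


class TestSatterthwaite:
    def test_between_subject_contrast_near_subject_df(self):
        # phenotype constant within subject: OLS on subject means has S-2
        # residual df in the balanced intercept+group design
        view = simulate_longitudinal(17, S=30, m=4, sigma_subject=2.0)
        spec = ModelSpec(controls=("dna",))
        fit = fit_mixed(view, spec)
        df, fellback = satterthwaite_df(fit, "group")
        assert not fellback
        assert df == pytest.approx(30 - 2, abs=1.5)

    def test_df_positive_and_bounded(self):
        for seed in range(20):
            view = simulate_longitudinal(seed + 100, S=12, m=3)
            fit = fit_mixed(view, ModelSpec())
            for name in ("group", "dna"):
                df, _ = satterthwaite_df(fit, name)
                assert 0 < df <= fit.df_resid + 1.0


class TestLRT:
    def test_no_random_effect_information(self):
        rng = np.random.default_rng(23)
        n = 50
        view = make_view(
            rng.normal(size=n), rng.normal(size=n), rng.normal(size=n),
            [f"s{i}" for i in range(n)], rng.choice(["A", "B"], n),
        )
        p, fixed, mixed = lrt_select(view, ModelSpec())
        assert p > 0.99

    def test_strong_subject_variance_detected(self):
        view = simulate_longitudinal(29, S=30, m=4, sigma_subject=5.0, sigma_resid=1.0)
        p, fixed, mixed = lrt_select(view, ModelSpec())
        assert p < 1e-6

    def test_statistic_never_negative(self):
        for seed in range(10):
            view = simulate_longitudinal(seed, S=10, m=2)
            p, fixed, mixed = lrt_select(view, ModelSpec())
            if mixed is not None and mixed.converged:
                assert mixed.loglik_ml - fixed.loglik_ml >= -1e-8
            assert 0.0 <= p <= 1.0


class TestBH:
    def test_single_value_identity(self):
        assert bh_adjust(np.array([0.05]))[0] == pytest.approx(0.05)

    def test_step_up_minimum(self):
        out = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(out, 0.04)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=30, deadline=None)
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(size=rng.integers(1, 40))
        assert np.array_equal(bh_adjust(p), bh_bruteforce(p))

    def test_matches_statsmodels(self):
        multipletests = pytest.importorskip("statsmodels.stats.multitest").multipletests
        rng = np.random.default_rng(0)
        p = rng.random(500)
        assert np.allclose(bh_adjust(p), multipletests(p, method="fdr_bh")[1], atol=1e-12)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(1)
        p = rng.random(200)
        q = bh_adjust(p)
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.2]))


class TestRunDE:
    def test_null_p_values_roughly_uniform(self, medium_dataset):
        data, _ = medium_dataset
        res = run_de(data, ModelSpec())
        frac = (res["p"] < 0.05).mean()
        # exact binomial 99% band at 200 features
        lo, hi = stats.binom.ppf([0.005, 0.995], len(res), 0.05) / len(res)
        assert lo - 1e-9 <= frac <= hi + 1e-9

    def test_overwhelming_shift_is_discovered(self, small_dataset):
        data, _ = small_dataset
        d = data.copy()
        f = d.features[3]
        boost = (d.meta["group"] == "B").to_numpy()
        d.rna.loc[f, boost] = d.rna.loc[f, boost] * 2.0**8
        res = run_de(d, ModelSpec())
        assert res.loc[f, "fdr"] < 0.05

    def test_min_obs_filter_counts_skipped(self, small_dataset):
        data, _ = small_dataset
        d = data.copy()
        f = d.features[0]
        d.rna.loc[f, d.rna.columns[2:]] = 0.0  # keep only 2 samples
        res = run_de(d, ModelSpec())
        assert f not in res.index
        assert res.attrs["skipped"] >= 1

    def test_t_equals_beta_over_se(self, small_dataset):
        data, _ = small_dataset
        res = run_de(data, ModelSpec())
        assert np.allclose(res["t"], res["beta"] / res["se"], atol=1e-9)
        assert ((res["p"] >= 0) & (res["p"] <= 1)).all()
        assert ((res["fdr"] >= 0) & (res["fdr"] <= 1)).all()
        assert (res["df"] > 0).all()

    def test_extra_covariates_accepted(self, small_dataset):
        data, _ = small_dataset
        d = data.copy()
        rng = np.random.default_rng(0)
        d.meta["age"] = rng.integers(20, 70, size=len(d.meta)).astype(float)
        d.meta["antibiotics"] = rng.choice(["yes", "no"], size=len(d.meta))
        res = run_de(d, ModelSpec(extra_covariates=("age", "antibiotics")))
        assert len(res) > 0
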