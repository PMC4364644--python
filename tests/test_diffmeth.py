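"""Design building, robust fitting, eBayes moderation, BH and ranking."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import special, stats

import methwas as mw
from methwas.diffmeth import (
    EBayesPrior, ModelSpec, estimate_prior, fit_locations, huber_consistency,
    moderated_t_pvalue, posterior_variance, trigamma_inverse,
)


def _random_covariates(n, seed=0, snp=True):
    # G and W follow fixed balanced patterns so tiny designs stay full-rank
    rng = np.random.default_rng(seed)
    cov = pd.DataFrame({
        "G": (np.arange(n) // 2) % 2, "T": rng.integers(1, 6, n),
        "B": rng.uniform(4, 10, n), "W": np.arange(n) % 2,
    }, index=[f"S{i:02d}" for i in range(n)])
    if snp:
        cov["S"] = rng.integers(0, 3, n)
    return cov


def _within_band_response(X, b_true, seed):
    """A response whose OLS residuals keep every Huber weight at 1: residuals
    are orthogonal-projected noise, re-drawn until max|r| < 1.9 median|r|
    (the c=1.345 band is max|r| < 1.994 median|r| under MAD scaling)."""
    n = X.shape[0]
    H = X @ np.linalg.solve(X.T @ X, X.T)
    rng = np.random.default_rng(seed)
    for _ in range(200):
        u = rng.uniform(0.5, 1.0, n) * rng.choice([-1.0, 1.0], n)
        r = u - H @ u  # OLS residuals of X @ b + r are exactly r
        if np.max(np.abs(r)) < 1.9 * np.median(np.abs(r)):
            return X @ b_true + r
    raise AssertionError("could not construct a within-band residual vector")


class TestBuildDesign:
    def test_shape_without_snp(self):
        X = mw.build_design(_random_covariates(4), ModelSpec())
        assert X.shape == (4, 5)
        assert list(X.columns) == ["intercept", "G", "T", "W", "B"]
        assert (X["intercept"] == 1).all()

    def test_snp_column_is_the_dose_vector(self):
        cov = _random_covariates(6, seed=1)
        cov["S"] = [0, 1, 2, 0, 1, 2]
        X = mw.build_design(cov, ModelSpec().with_snp())
        np.testing.assert_array_equal(X["S"].to_numpy(), cov["S"].to_numpy())

    def test_constant_sex_column_raises_named_error(self):
        cov = _random_covariates(8, seed=2)
        cov["G"] = 0  # all-female cohort
        with pytest.raises(mw.DesignMatrixError, match="G"):
            mw.build_design(cov, ModelSpec())

    def test_samples_with_missing_covariates_dropped(self):
        cov = _random_covariates(8, seed=3)
        cov.loc[cov.index[2], "B"] = np.nan
        X = mw.build_design(cov, ModelSpec())
        assert len(X) == 7
        assert cov.index[2] not in X.index

    def test_contrast_must_be_in_design(self):
        with pytest.raises(mw.DesignMatrixError):
            ModelSpec(contrast="S")  # S not among default covariates


def _design_matrix(n, seed=0):
    return mw.build_design(_random_covariates(n, seed=seed), ModelSpec()).to_numpy()


class TestRobustFit:
    def test_exact_linear_data_recovers_coefficients(self):
        X = _design_matrix(12, seed=4)
        b_true = np.array([1.0, -0.5, 0.2, 0.8, -0.1])
        y = X @ b_true
        coef, sigma2, df, converged = mw.robust_fit(y, X)
        np.testing.assert_allclose(coef, b_true, atol=1e-8)
        assert sigma2 == pytest.approx(0.0, abs=1e-16)
        assert df == 7 and converged

    def test_within_band_residuals_match_ols_oracle(self):
        # every OLS residual inside the Huber band -> weights stay 1 and the
        # robust fit is exactly least squares
        X = _design_matrix(24, seed=5)
        y = _within_band_response(X, np.array([0.3, 1.0, -0.2, 0.5, 0.05]), seed=5)
        ols = np.linalg.solve(X.T @ X, X.T @ y)  # normal-equations oracle
        coef, _, _, converged = mw.robust_fit(y, X)
        assert converged
        np.testing.assert_allclose(coef, ols, atol=1e-6)

    def test_outlier_pulls_robust_toward_clean_fit(self):
        rng = np.random.default_rng(6)
        X = _design_matrix(30, seed=6)
        y = X @ np.array([0.0, 0.1, 0.0, 1.0, 0.0]) + rng.normal(0, 0.3, 30)
        y_out = y.copy()
        y_out[3] += 25.0
        j = 3  # W column
        full_ols = np.linalg.solve(X.T @ X, X.T @ y_out)[j]
        Xc, yc = np.delete(X, 3, axis=0), np.delete(y_out, 3)
        clean_ols = np.linalg.solve(Xc.T @ Xc, Xc.T @ yc)[j]
        robust = mw.robust_fit(y_out, X)[0][j]
        assert abs(robust - clean_ols) < abs(full_ols - clean_ols)

    def test_matches_statsmodels_rlm(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(7)
        X = _design_matrix(40, seed=7)
        y = X @ np.array([0.5, -1.0, 0.2, 0.7, -0.05]) + rng.standard_t(3, 40)
        res = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=1.345)).fit(
            scale_est="mad", maxiter=5000, tol=1e-10)
        coef, _, _, _ = mw.robust_fit(y, X)
        np.testing.assert_allclose(coef, res.params, rtol=1e-4, atol=1e-6)

    def test_nonconvergence_flag_instead_of_exception(self):
        rng = np.random.default_rng(8)
        X = _design_matrix(20, seed=8)
        y = rng.standard_cauchy(20) * 5
        coef, _, _, converged = mw.robust_fit(y, X, ModelSpec(max_iter=1))
        assert not converged
        assert np.all(np.isfinite(coef))

    def test_needs_more_samples_than_columns(self):
        X = _design_matrix(5, seed=9)
        with pytest.raises(mw.DesignMatrixError):
            mw.robust_fit(np.zeros(5), X)


class TestEBayes:
    def test_equal_variances_give_infinite_prior(self):
        fits = pd.DataFrame({"coef_W": [1.0, 2.0, 3.0], "stderr_unscaled": 0.5,
                             "sigma2": 2.0, "df_residual": 10.0})
        out, prior = mw.ebayes_moderate(fits, "W")
        assert prior.d0 == np.inf
        np.testing.assert_allclose(out["sigma2_post"], 2.0)

    def test_infinite_prior_limit_uses_normal_reference(self):
        fits = pd.DataFrame({"coef_W": [1.0, -2.0], "stderr_unscaled": [0.5, 0.5],
                             "sigma2": [1.0, 3.0], "df_residual": 10.0})
        prior = EBayesPrior(d0=np.inf, s02=4.0)
        out, _ = mw.ebayes_moderate(fits, "W", prior=prior)
        np.testing.assert_allclose(out["t"], fits["coef_W"] / (0.5 * 2.0))
        np.testing.assert_allclose(out["p_value"],
                                   2 * stats.norm.sf(np.abs(out["t"])))

    def test_zero_prior_df_reproduces_classical_t(self):
        # with d0 forced to 0 and OLS fitting, the moderated t must equal the
        # per-location classical t from an independent direct solve
        rng = np.random.default_rng(10)
        n, P = 16, 30
        cov = _random_covariates(n, seed=10)
        Y = rng.normal(size=(P, n))
        m = pd.DataFrame(Y, columns=cov.index)
        fits, _ = mw.fit_differential(m, cov, ModelSpec(robust=False),
                                      prior=EBayesPrior(d0=0.0, s02=1.0))
        X = mw.build_design(cov, ModelSpec()).to_numpy()
        XtX_inv = np.linalg.inv(X.T @ X)
        j = 3  # W
        for k in range(P):
            b = XtX_inv @ X.T @ Y[k]
            resid = Y[k] - X @ b
            s2 = resid @ resid / (n - 5)
            t_classic = b[j] / np.sqrt(s2 * XtX_inv[j, j])
            p_classic = 2 * stats.t.sf(abs(t_classic), n - 5)
            assert fits["t"].iloc[k] == pytest.approx(t_classic, rel=1e-10)
            assert fits["p_value"].iloc[k] == pytest.approx(p_classic, rel=1e-10)

    def test_prior_recovery_from_scaled_inv_chi2(self):
        # simulate variances with known hyperparameters, recover them via the
        # moment equations, and cross-check against an independent root-finder
        rng = np.random.default_rng(11)
        d0_true, s02_true, d, P = 4.0, 1.0, 10.0, 200
        sigma2_probe = d0_true * s02_true / rng.chisquare(d0_true, P)
        s2 = sigma2_probe * rng.chisquare(d, P) / d
        prior = estimate_prior(s2, d)

        from scipy.optimize import brentq

        z = np.log(s2)
        e = z - special.digamma(d / 2) + np.log(d / 2)
        evar = e.var(ddof=1) - special.polygamma(1, d / 2)
        x = brentq(lambda v: special.polygamma(1, v) - evar, 1e-6, 1e6)
        d0_oracle = 2 * x
        s02_oracle = np.exp(e.mean() + special.digamma(x) - np.log(x))
        assert prior.d0 == pytest.approx(d0_oracle, rel=1e-6)
        assert prior.s02 == pytest.approx(s02_oracle, rel=1e-6)
        # simulation-level recovery (tolerance from the sampling noise of the
        # log-variance moments at P = 200)
        assert 2.0 < prior.d0 < 8.0
        assert 0.75 < prior.s02 < 1.35

    def test_posterior_variance_formula(self):
        s2 = np.array([1.0, 2.0])
        out = posterior_variance(s2, 10.0, EBayesPrior(d0=5.0, s02=0.5))
        np.testing.assert_allclose(out, (5 * 0.5 + 10 * s2) / 15.0)

    def test_trigamma_inverse_round_trip(self):
        for x in [0.01, 0.5, 3.0, 100.0]:
            y = float(special.polygamma(1, x))
            assert trigamma_inverse(y) == pytest.approx(x, rel=1e-6)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(mw.bh_adjust([0.3]), [0.3])

    def test_hand_computed_example(self):
        np.testing.assert_allclose(mw.bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_empty_input(self):
        assert mw.bh_adjust([]).size == 0

    def test_adjusted_at_least_raw_and_bounded(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(size=500)
        q = mw.bh_adjust(p)
        assert np.all(q >= p) and np.all(q <= 1)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=200))
    def test_matches_statsmodels_oracle(self, p):
        from statsmodels.stats.multitest import multipletests

        q = mw.bh_adjust(p)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(q, q_sm, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mw.bh_adjust([0.5, 1.2])


class TestRankTop:
    def _fits(self, pvals, ids=None):
        ids = ids or [f"L{i}" for i in range(len(pvals))]
        return pd.DataFrame({"coef_W": np.linspace(-1, 1, len(pvals)),
                             "p_value": pvals, "q_value": mw.bh_adjust(pvals)},
                            index=pd.Index(ids, name="location_id"))

    def test_k1_returns_minimal_p(self):
        top = mw.rank_top(self._fits([0.5, 0.01, 0.9]), k=1, contrast="W")
        assert list(top.frame.index) == ["L1"]

    def test_ties_break_by_location_id(self):
        top = mw.rank_top(self._fits([0.5, 0.02, 0.02], ids=["Lz", "Lb", "La"]),
                          k=2, contrast="W")
        assert list(top.frame.index) == ["La", "Lb"]

    def test_k_larger_than_table_warns(self):
        with pytest.warns(UserWarning):
            top = mw.rank_top(self._fits([0.1, 0.2]), k=5, contrast="W")
        assert len(top.frame) == 2

    def test_spiked_probe_ranks_first(self):
        cfg = mw.SimulationConfig(n_probes=2000, n_samples=69, seed=13,
                                  frac_weight_effect=1 / 2000, frac_snp_effect=0.0,
                                  effect_size_m=2.0, frac_island_members=0.0,
                                  frac_missing=0.0, detection_fail_rate=0.0,
                                  frac_snp_probes=0.0, frac_crossreactive=0.0,
                                  frac_sex_chrom=0.0)
        cohort, _, truth = mw.simulate_cohort(cfg)
        spiked = truth.index[truth["true_weight_effect"] != 0][0]
        m = mw.beta_to_m(cohort.beta)
        fits, _ = mw.fit_differential(m, cohort.covariates)
        top = mw.rank_top(fits, k=1)
        assert top.frame.index[0] == spiked
        # direct per-probe two-group Welch test oracle agrees on the winner
        w = cohort.covariates["W"].to_numpy() == 1
        vals = m.to_numpy()
        t_or, p_or = stats.ttest_ind(vals[:, w], vals[:, ~w], axis=1)
        assert m.index[np.argmin(p_or)] == spiked


class TestAgainstLimma:
    """Bioconductor limma (via Rscript) as an independent oracle for the
    non-robust fit + eBayes moderation on a tiny fixture."""

    def test_ols_ebayes_matches_limma(self, tmp_path):
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript is required for the limma oracle check")
        rng = np.random.default_rng(14)
        n, P = 12, 60
        cov = _random_covariates(n, seed=14, snp=False)
        sd = np.exp(rng.normal(0, 0.8, P))
        spikes = np.concatenate([np.ones(5), np.zeros(P - 5)])
        Y = rng.normal(size=(P, n)) * sd[:, None] + 0.8 * cov["W"].to_numpy() * spikes[:, None]
        m = pd.DataFrame(Y, index=[f"p{i}" for i in range(P)], columns=cov.index)
        fits, prior = mw.fit_differential(m, cov, ModelSpec(robust=False))

        m.to_csv(tmp_path / "y.tsv", sep="\t")
        cov.to_csv(tmp_path / "cov.tsv", sep="\t")
        script = tmp_path / "chk.R"
        script.write_text(f"""
suppressMessages(library(limma))
y <- as.matrix(read.delim('{tmp_path}/y.tsv', row.names=1))
cov <- read.delim('{tmp_path}/cov.tsv', row.names=1)
X <- model.matrix(~ G + T + B + W, data=cov)
fit <- eBayes(lmFit(y, X))
out <- data.frame(coef=fit$coefficients[,'W'], t=fit$t[,'W'],
                  p=fit$p.value[,'W'], s2post=fit$s2.post)
write.table(out, '{tmp_path}/limma.tsv', sep='\\t', quote=FALSE)
cat(fit$df.prior, fit$s2.prior, sep='\\n')
""")
        res = subprocess.run(["Rscript", str(script)], capture_output=True, text=True)
        assert res.returncode == 0, res.stderr
        d0_l, s02_l = (float(x) for x in res.stdout.split())
        lim = pd.read_csv(tmp_path / "limma.tsv", sep="\t", index_col=0)
        assert prior.d0 == pytest.approx(d0_l, rel=1e-5)
        assert prior.s02 == pytest.approx(s02_l, rel=1e-5)
        np.testing.assert_allclose(fits["coef_W"], lim["coef"], atol=1e-10)
        np.testing.assert_allclose(fits["t"], lim["t"], atol=1e-8)
        np.testing.assert_allclose(fits["p_value"], lim["p"], atol=1e-10)
        np.testing.assert_allclose(fits["sigma2_post"], lim["s2post"], atol=1e-10)


class TestEstimatorAPI:
    def test_fit_attributes_and_agreement_with_function(self):
        rng = np.random.default_rng(15)
        n, P = 20, 25
        cov = _random_covariates(n, seed=15)
        Y = pd.DataFrame(rng.normal(size=(n, P)), index=cov.index,
                         columns=[f"L{i}" for i in range(P)])
        est = mw.ModeratedDifferentialMethylation().fit(cov, Y)
        fits, prior = mw.fit_differential(Y.T, cov)
        np.testing.assert_allclose(est.pvalue_, fits["p_value"])
        np.testing.assert_allclose(est.qvalue_, fits["q_value"])
        assert est.prior_df_ == prior.d0
        assert est.df_residual_ == n - 5
        assert est.location_ids_ == list(Y.columns)
        top = est.top(k=3)
        assert len(top.frame) == 3

    def test_sklearn_clone_and_params(self):
        from sklearn.base import clone

        est = mw.ModeratedDifferentialMethylation(contrast="W", robust=False)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
        assert cloned.get_params()["robust"] is False


def test_fit_table_invariants(small_sim):
    _, cohort, annot, _ = small_sim
    filtered, _ = mw.qc_filter(cohort, annot)
    m = mw.quantile_normalize(mw.beta_to_m(filtered.beta))
    m_loc, _ = mw.collapse_islands(m, annot)
    fits, prior = mw.fit_differential(m_loc, filtered.covariates)
    assert (fits["q_value"] >= fits["p_value"] - 1e-15).all()
    assert fits["q_value"].between(0, 1).all()
    assert (fits["df_residual"] == filtered.n_samples - 5).all()
    assert prior.d0 > 0 and prior.s02 > 0


def test_huber_consistency_constant():
    # independent Monte-Carlo check of E[min(z^2, c|z|)]
    rng = np.random.default_rng(16)
    z = rng.standard_normal(400_000)
    mc = np.minimum(z ** 2, 1.345 * np.abs(z)).mean()
    assert huber_consistency(1.345) == pytest.approx(mc, abs=2e-3)


def test_moderated_p_normal_vs_t_reference():
    t = np.array([1.0, -2.5])
    np.testing.assert_allclose(moderated_t_pvalue(t, np.inf),
                               2 * stats.norm.sf(np.abs(t)))
    np.testing.assert_allclose(moderated_t_pvalue(t, 10.0),
                               2 * stats.t.sf(np.abs(t), 10.0))
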