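"""Per-location robust linear models with empirical-Bayes moderated statistics.

For every interrogated location k the M-value is modelled as

    M_k = a_k + b_kG G + b_kT T + b_kW W + b_kB B (+ b_kS S) + e_k

where G is sex (female=0, male=1), T the Tanner stage, W the weight category
(normal=0, obese=1), B the white-blood-cell count and S the optional additive
risk-allele dose (TT=0, TC=1, CC=2). Coefficients are estimated by Huber
M-estimation (iteratively reweighted least squares, tuning constant c=1.345,
scale from the rescaled median absolute residual), or by OLS when ``robust``
is off. Residual variances are then shrunk across locations toward an
inverse-chi-square prior whose parameters (d0, s0^2) are estimated by
matching the moments of log s_k^2 (the limma eBayes scheme), giving a
moderated t-statistic with d0 + d_k degrees of freedom per location, and
Benjamini-Hochberg adjusted p-values.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator

from .errors import DesignMatrixError

logger = logging.getLogger(__name__)


@dataclass
class ModelSpec:
    """Covariate list, contrast of interest, and fitting switches."""

    covariates: tuple = ("G", "T", "W", "B")
    contrast: str = "W"
    robust: bool = True
    huber_c: float = 1.345
    max_iter: int = 10000
    tol: float = 1e-8

    def __post_init__(self):
        if self.contrast not in self.covariates:
            raise DesignMatrixError(
                f"contrast {self.contrast!r} is not among covariates {self.covariates}")
        if self.max_iter < 1:
            raise DesignMatrixError("max_iter must be >= 1")

    def with_snp(self) -> "ModelSpec":
        """The same model with the genotype dose added and set as contrast."""
        covs = self.covariates if "S" in self.covariates else self.covariates + ("S",)
        return ModelSpec(covariates=covs, contrast="S", robust=self.robust,
                         huber_c=self.huber_c, max_iter=self.max_iter, tol=self.tol)


@dataclass
class EBayesPrior:
    """Prior degrees of freedom and variance of the shared variance model."""

    d0: float
    s02: float

    def __post_init__(self):
        if not (self.d0 >= 0):  # d0 = 0 disables moderation; d0 may be inf
            raise ValueError("prior degrees of freedom must be >= 0")
        if not (self.s02 > 0):
            raise ValueError("prior variance must be positive")


def build_design(covariates: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Design matrix [1 | covariates] for the included samples.

    Samples with any missing covariate are dropped (and logged). A
    rank-deficient design raises :class:`DesignMatrixError` naming the
    collinear columns.
    """
    missing_cols = [c for c in spec.covariates if c not in covariates.columns]
    if missing_cols:
        raise DesignMatrixError(f"covariate table lacks columns {missing_cols}")
    sub = covariates[list(spec.covariates)].astype(float)
    complete = sub.notna().all(axis=1)
    if (~complete).any():
        dropped = list(sub.index[~complete])
        logger.info("dropping %d sample(s) with missing covariates: %s", len(dropped), dropped[:5])
        sub = sub[complete]
    X = sub.copy()
    X.insert(0, "intercept", 1.0)
    arr = X.to_numpy()
    rank = np.linalg.matrix_rank(arr)
    # with fewer samples than columns the rank is trivially deficient; that
    # case is rejected at fit time, collinearity is what is diagnosed here
    if rank < X.shape[1] and len(X) >= X.shape[1]:
        culprits = []
        for j, name in enumerate(X.columns):
            if name == "intercept":
                continue
            reduced = np.delete(arr, j, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                culprits.append(name)
        raise DesignMatrixError(
            f"design matrix is rank-deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns: {culprits or 'unknown'}")
    return X


def huber_consistency(c: float) -> float:
    """E[min(z^2, c|z|)] for standard-normal z, which equals 2*Phi(c) - 1.

    The Huber weighted residual sum of squares divided by (n - p) estimates
    this fraction of the true error variance under Gaussian noise, so the
    robust variance estimate is divided by this constant to stay unbiased
    (and to keep null p-values calibrated).
    """
    return math.erf(c / math.sqrt(2.0))


def _irls_huber(Y: np.ndarray, X: np.ndarray, c: float, tol: float, max_iter: int):
    """Batched Huber IRLS over the rows of Y (locations x samples).

    Returns (B, W, converged, n_iter): coefficients, final weights and
    per-location convergence (max coefficient change < tol).
    """
    P, n = Y.shape
    XtX = X.T @ X
    B = np.linalg.solve(XtX, X.T @ Y.T).T
    converged = np.zeros(P, dtype=bool)
    n_iter = np.zeros(P, dtype=int)
    W = np.ones_like(Y)
    for it in range(1, max_iter + 1):
        idx = np.flatnonzero(~converged)
        if idx.size == 0:
            break
        Yb, Bb = Y[idx], B[idx]
        R = Yb - Bb @ X.T
        absR = np.abs(R)
        scale = np.median(absR, axis=1) / 0.6745
        safe = np.where(scale > 0, scale, np.inf)  # exact fit -> unit weights
        with np.errstate(divide="ignore"):
            z = absR / safe[:, None]
        w = np.where(z > c, c / np.maximum(z, 1e-300), 1.0)
        XtWX = np.einsum("kn,ni,nj->kij", w, X, X, optimize=True)
        XtWy = (w * Yb) @ X
        Bnew = np.linalg.solve(XtWX, XtWy[..., None])[..., 0]
        delta = np.max(np.abs(Bnew - Bb), axis=1)
        B[idx] = Bnew
        W[idx] = w
        n_iter[idx] = it
        converged[idx[delta < tol]] = True
    # final weights from the final residuals, for the variance/covariance step
    R = Y - B @ X.T
    absR = np.abs(R)
    scale = np.median(absR, axis=1) / 0.6745
    safe = np.where(scale > 0, scale, np.inf)
    with np.errstate(divide="ignore"):
        z = absR / safe[:, None]
    W = np.where(z > c, c / np.maximum(z, 1e-300), 1.0)
    return B, W, converged, n_iter


def fit_locations(Y: np.ndarray, X: np.ndarray, spec: ModelSpec):
    """Fit every row of Y against X; returns a dict of per-location arrays.

    ``sigma2`` is the (consistency-corrected, for Huber) residual variance on
    d = n - p degrees of freedom; ``stderr_unscaled`` the per-coefficient
    unscaled standard error sqrt(diag((X'WX)^-1)).
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    P, n = Y.shape
    p = X.shape[1]
    if n != X.shape[0]:
        raise DesignMatrixError("response and design row counts differ")
    if n <= p:
        raise DesignMatrixError(f"need more samples ({n}) than design columns ({p})")
    df = n - p
    if spec.robust:
        B, W, converged, n_iter = _irls_huber(Y, X, spec.huber_c, spec.tol, spec.max_iter)
        if not converged.all():
            logger.warning("%d location(s) did not converge within max_iter=%d",
                           int((~converged).sum()), spec.max_iter)
        kappa = huber_consistency(spec.huber_c)
    else:
        B = np.linalg.solve(X.T @ X, X.T @ Y.T).T
        W = np.ones_like(Y)
        converged = np.ones(P, dtype=bool)
        n_iter = np.zeros(P, dtype=int)
        kappa = 1.0
    R = Y - B @ X.T
    sigma2 = np.einsum("kn,kn->k", W, R * R) / (df * kappa)
    XtWX = np.einsum("kn,ni,nj->kij", W, X, X, optimize=True)
    cov_unscaled = np.linalg.inv(XtWX)
    stderr_unscaled = np.sqrt(np.maximum(np.diagonal(cov_unscaled, axis1=1, axis2=2), 0.0))
    if spec.robust:
        # Huber's finite-sample standard-error correction
        # K = 1 + (p/n) var(psi') / E[psi']^2, with psi' = 1{|z| <= c} so the
        # empirical moment is the within-band weight fraction per location
        f_band = np.clip(np.mean(W >= 1.0 - 1e-12, axis=1), 1.0 / n, 1.0)
        K = 1.0 + (p / n) * (1.0 - f_band) / f_band
        stderr_unscaled = stderr_unscaled * K[:, None]
    return {"coef": B, "sigma2": sigma2, "df": df, "stderr_unscaled": stderr_unscaled,
            "converged": converged, "n_iter": n_iter}


def robust_fit(y: np.ndarray, X: np.ndarray, spec: ModelSpec | None = None):
    """Single-location fit; returns ``(coefficients, sigma2, df, converged)``."""
    spec = spec or ModelSpec()
    out = fit_locations(np.asarray(y, float)[None, :], X, spec)
    return out["coef"][0], float(out["sigma2"][0]), out["df"], bool(out["converged"][0])


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(75):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) / x < 1e-10:
            break
    return x


def estimate_prior(sigma2: np.ndarray, df) -> EBayesPrior:
    """Moment-match (d0, s0^2) of the scaled inverse-chi-square variance prior.

    Uses the log-variance system: with z_k = log s_k^2,
    E z = log s0^2 + digamma(d/2) - log(d/2) - digamma(d0/2) + log(d0/2) and
    Var z = trigamma(d/2) + trigamma(d0/2). If the empirical variance of z
    falls at or below its minimum achievable value, d0 = infinity.
    """
    sigma2 = np.asarray(sigma2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), sigma2.shape)
    ok = np.isfinite(sigma2) & (sigma2 > 0) & (df > 0)
    if ok.sum() < 2:
        raise ValueError("need at least two locations with positive finite variance")
    s2, d = sigma2[ok], df[ok]
    z = np.log(s2)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(np.mean(special.polygamma(1, d / 2.0)))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s02 = math.exp(emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        # no excess spread in log s^2: infinite prior df, pooled variance
        d0 = math.inf
        s02 = float(s2.mean())
    return EBayesPrior(d0=d0, s02=s02)


def posterior_variance(sigma2: np.ndarray, df, prior: EBayesPrior) -> np.ndarray:
    sigma2 = np.asarray(sigma2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), sigma2.shape)
    if math.isinf(prior.d0):
        return np.full_like(sigma2, prior.s02)
    if prior.d0 == 0:
        return sigma2.copy()
    return (prior.d0 * prior.s02 + df * sigma2) / (prior.d0 + df)


def moderated_t_pvalue(t: np.ndarray, df_total) -> np.ndarray:
    """Two-sided p-values from a t reference (normal when df is infinite)."""
    t = np.asarray(t, dtype=float)
    df_total = np.broadcast_to(np.asarray(df_total, dtype=float), t.shape)
    p = np.empty_like(t)
    inf = ~np.isfinite(df_total)
    p[inf] = 2.0 * stats.norm.sf(np.abs(t[inf]))
    p[~inf] = 2.0 * stats.t.sf(np.abs(t[~inf]), df_total[~inf])
    return p


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def ebayes_moderate(fits: pd.DataFrame, contrast: str,
                    prior: EBayesPrior | None = None):
    """Add moderated statistics for ``contrast`` to a fit table.

    ``fits`` needs columns ``coef_<contrast>``, ``stderr_unscaled``,
    ``sigma2`` and ``df_residual``. Returns ``(augmented_table, prior)``;
    pass an explicit prior to override estimation (d0=0 reproduces the
    classical per-location t).
    """
    needed = [f"coef_{contrast}", "stderr_unscaled", "sigma2", "df_residual"]
    for c in needed:
        if c not in fits.columns:
            raise ValueError(f"fit table lacks column {c!r}")
    sigma2 = fits["sigma2"].to_numpy(float)
    df = fits["df_residual"].to_numpy(float)
    if prior is None:
        prior = estimate_prior(sigma2, df)
    s2_post = posterior_variance(sigma2, df, prior)
    t = fits[f"coef_{contrast}"].to_numpy(float) / (
        fits["stderr_unscaled"].to_numpy(float) * np.sqrt(s2_post))
    df_total = df + prior.d0
    pvals = moderated_t_pvalue(t, df_total)
    out = fits.copy()
    out["sigma2_post"] = s2_post
    out["t"] = t
    out["df_total"] = df_total
    out["p_value"] = pvals
    out["q_value"] = bh_adjust(pvals)
    out.attrs["contrast"] = contrast
    out.attrs["prior_d0"] = prior.d0
    out.attrs["prior_s02"] = prior.s02
    return out, prior


def fit_differential(m: pd.DataFrame, covariates: pd.DataFrame,
                     spec: ModelSpec | None = None,
                     prior: EBayesPrior | None = None):
    """Fit the moderated model over a location x sample M matrix.

    Returns ``(fit_table, prior)``: one row per location with the
    coefficients, residual and posterior variances, moderated t, raw and
    BH-adjusted p for ``spec.contrast``.
    """
    spec = spec or ModelSpec()
    design = build_design(covariates.loc[m.columns], spec)
    Y = m[design.index].to_numpy(float)
    res = fit_locations(Y, design.to_numpy(), spec)
    j = list(design.columns).index(spec.contrast)
    table = pd.DataFrame(index=m.index.copy())
    for i, name in enumerate(design.columns):
        table[f"coef_{name}"] = res["coef"][:, i]
    table["stderr_unscaled"] = res["stderr_unscaled"][:, j]
    table["sigma2"] = res["sigma2"]
    table["df_residual"] = res["df"]
    table["converged"] = res["converged"]
    table.index.name = "location_id"
    return ebayes_moderate(table, spec.contrast, prior=prior)


@dataclass
class RankedTable:
    """Top-k rows of one model's fit table, with location annotation."""

    frame: pd.DataFrame
    contrast: str
    k: int


def rank_top(fits: pd.DataFrame, k: int = 15,
             location_table: pd.DataFrame | None = None,
             contrast: str | None = None) -> RankedTable:
    """Top-k locations by ascending raw p, ties broken by location ID.

    When a location table is supplied, the rows carry the table-style output
    schema: gene, optional gene ID, genomic position, HIL class, closest-TSS
    position, coefficient, raw and adjusted p.
    """
    if fits.empty:
        raise ValueError("cannot rank an empty fit table")
    contrast = contrast or fits.attrs.get("contrast")
    if k > len(fits):
        warnings.warn(f"k={k} exceeds the {len(fits)} available rows; returning all",
                      stacklevel=2)
        k = len(fits)
    key = fits.assign(_lid=fits.index.astype(str)).sort_values(
        ["p_value", "_lid"], kind="mergesort")
    top = key.head(k).drop(columns="_lid")
    if location_table is not None:
        from .annotate import genomic_position_string

        loc = location_table.loc[top.index]
        out = pd.DataFrame(index=top.index)
        out["gene"] = loc["closest_tss_gene"]
        if "gene_id" in loc.columns:
            out["gene_id"] = loc["gene_id"]
        out["genomic_position"] = [genomic_position_string(r) for _, r in loc.iterrows()]
        out["hil_class"] = loc["hil_class"]
        out["closest_tss_position"] = loc["tss_position"]
        out["coefficient"] = top[f"coef_{contrast}"]
        out["raw_p"] = top["p_value"]
        out["adjusted_p"] = top["q_value"]
    else:
        out = top.rename(columns={f"coef_{contrast}": "coefficient",
                                  "p_value": "raw_p", "q_value": "adjusted_p"})
        keep = [c for c in ("coefficient", "raw_p", "adjusted_p") if c in out.columns]
        out = out[keep]
    return RankedTable(frame=out, contrast=contrast, k=k)


class ModeratedDifferentialMethylation(BaseEstimator):
    """Sklearn-style estimator for the moderated per-location model.

    ``fit(X, Y)`` takes X as the samples x covariates frame (columns named as
    in :class:`ModelSpec`) and Y as the samples x locations M-value matrix.
    Fitted attributes (per location unless noted): ``coef_`` (locations x
    design columns), ``design_columns_``, ``sigma2_``, ``df_residual_``
    (scalar), ``prior_df_``, ``prior_var_`` (scalars), ``sigma2_post_``,
    ``t_``, ``pvalue_``, ``qvalue_``, ``converged_``, ``location_ids_``.
    """

    def __init__(self, covariates=("G", "T", "W", "B"), contrast="W", robust=True,
                 huber_c=1.345, max_iter=10000, tol=1e-8):
        self.covariates = covariates
        self.contrast = contrast
        self.robust = robust
        self.huber_c = huber_c
        self.max_iter = max_iter
        self.tol = tol

    def _spec(self) -> ModelSpec:
        return ModelSpec(covariates=tuple(self.covariates), contrast=self.contrast,
                         robust=self.robust, huber_c=self.huber_c,
                         max_iter=self.max_iter, tol=self.tol)

    def fit(self, X, Y):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, float), columns=list(self.covariates))
        if not isinstance(Y, pd.DataFrame):
            Y = pd.DataFrame(np.asarray(Y, float))
        if len(X) != len(Y):
            raise ValueError("X and Y must have the same number of samples (rows)")
        Y = Y.set_axis(X.index, axis=0)
        table, prior = fit_differential(Y.T, X, self._spec())
        self.fit_table_ = table
        self.design_columns_ = ["intercept"] + list(self.covariates)
        self.coef_ = table[[f"coef_{c}" for c in self.design_columns_]].to_numpy()
        self.sigma2_ = table["sigma2"].to_numpy()
        self.sigma2_post_ = table["sigma2_post"].to_numpy()
        self.df_residual_ = float(table["df_residual"].iloc[0])
        self.prior_df_ = prior.d0
        self.prior_var_ = prior.s02
        self.t_ = table["t"].to_numpy()
        self.pvalue_ = table["p_value"].to_numpy()
        self.qvalue_ = table["q_value"].to_numpy()
        self.converged_ = table["converged"].to_numpy()
        self.location_ids_ = list(Y.columns)
        return self

    def top(self, k: int = 15, location_table: pd.DataFrame | None = None) -> RankedTable:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "fit_table_")
        return rank_top(self.fit_table_, k=k, location_table=location_table,
                        contrast=self.contrast)
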