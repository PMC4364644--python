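"""Beta/M transformation, the QC cascade, and quantile normalization.

The analysis scale is the M-value, the log2 ratio of methylated to
unmethylated signal. From a beta-value (proportion methylated) it is the
base-2 logit, M = log2(beta / (1 - beta)); beta-values are heteroscedastic
near 0 and 1, while M-values are approximately homoscedastic and suit linear
modelling.

Quality control removes failing probes (missing beta, poor aggregate
detection p, too few confidently detected samples, SNP-overlapping probes,
cross-reactive probes) and failing samples (missing beta anywhere, poor
aggregate detection p, too few confidently detected sites) — by default probe
rules first, configurable — and finally sex-chromosome probes, which are
counted separately from the QC failures. Each entity is attributed to the
first rule that removes it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import MethylationCohort, QCReport, RuleRemoval
from .errors import ConfigurationError, EmptyCohortError

logger = logging.getLogger(__name__)

#: Clamp for beta at the boundaries so M stays finite.
BETA_EPS = 1e-6


def beta_to_m(beta):
    """Base-2 logit transform of beta-values.

    Accepts scalars, arrays or DataFrames; beta is clamped to
    [BETA_EPS, 1 - BETA_EPS] before the transform. Values outside [0, 1]
    raise ``ValueError`` (NaN passes through).
    """
    arr = np.asarray(beta, dtype=float) if not isinstance(beta, pd.DataFrame) else beta.to_numpy(float)
    with np.errstate(invalid="ignore"):
        bad = (arr < 0) | (arr > 1)
    if np.nansum(bad):
        raise ValueError("beta values must lie in [0, 1]")
    clamped = np.clip(arr, BETA_EPS, 1.0 - BETA_EPS)
    m = np.log2(clamped / (1.0 - clamped))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    if np.isscalar(beta):
        return float(m)
    return m


def m_to_beta(m):
    """Inverse of :func:`beta_to_m` away from the clamp region: 2^m / (1 + 2^m)."""
    arr = np.asarray(m, dtype=float) if not isinstance(m, pd.DataFrame) else m.to_numpy(float)
    # logistic in base 2, computed stably for large |m|
    beta = np.empty_like(arr, dtype=float)
    pos = arr >= 0
    beta[pos] = 1.0 / (1.0 + np.exp2(-arr[pos]))
    p = np.exp2(arr[~pos])
    beta[~pos] = p / (1.0 + p)
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(beta, index=m.index, columns=m.columns)
    if np.isscalar(m):
        return float(beta)
    return beta


@dataclass
class QCThresholds:
    """Thresholds and switches for the QC cascade.

    probe_detection_p      probes with aggregate detection p above this fail
    sample_detection_p     samples with aggregate detection p above this fail
    confident_detection_p  a cell counts as confidently detected below this
    detection_fraction     minimum fraction of confidently detected cells
    aggregation            how the per-cell detection p is reduced to a
                           scalar per probe/sample: "mean" | "max" | "any"
                           ("any" behaves like "max": fail if any cell exceeds)
    samples_first          apply sample rules before probe rules; the default
                           runs probe rules first, so that a probe-confined
                           defect (one missing beta, a failed probe chemistry)
                           removes the probe rather than every sample touching
                           it — the sample aggregate rule at 1e-5 is strict
                           enough to reject a sample over a single bad cell
    """

    probe_detection_p: float = 0.05
    sample_detection_p: float = 1e-5
    confident_detection_p: float = 1e-5
    detection_fraction: float = 0.75
    aggregation: str = "mean"
    samples_first: bool = False

    def validate(self) -> "QCThresholds":
        for f in ("probe_detection_p", "sample_detection_p", "confident_detection_p"):
            v = getattr(self, f)
            if not (0 < v < 1):
                raise ConfigurationError(f, f"must lie in (0, 1), got {v}")
        if not (0 < self.detection_fraction <= 1):
            raise ConfigurationError("detection_fraction", "must lie in (0, 1]")
        if self.aggregation not in ("mean", "max", "any"):
            raise ConfigurationError("aggregation", "must be one of mean|max|any")
        return self


def _aggregate(det: pd.DataFrame, axis: int, how: str) -> pd.Series:
    if how == "mean":
        return det.mean(axis=axis)
    return det.max(axis=axis)  # "max" and "any" coincide for thresholding


def _is_sex_chromosome(chrom: pd.Series) -> pd.Series:
    c = chrom.astype(str).str.strip().str.lower().str.removeprefix("chr")
    return c.isin(["x", "y"])


def qc_filter(cohort: MethylationCohort, annot: pd.DataFrame,
              thresholds: QCThresholds | None = None):
    """Apply the QC cascade; returns ``(filtered_cohort, QCReport)``.

    ``annot`` must cover every probe of the cohort (see :mod:`methwas.annotate`
    for the expected columns: at least ``chromosome``, ``snp_flag`` and
    ``crossreactive_flag``).
    """
    thr = (thresholds or QCThresholds()).validate()
    missing = cohort.beta.index.difference(annot.index)
    if len(missing):
        raise ValueError(f"annotation does not cover probes {list(missing[:5])!r}")

    beta, det = cohort.beta, cohort.detection_p
    removals: list[RuleRemoval] = []

    def drop_samples(rule, ids):
        nonlocal beta, det
        removals.append(RuleRemoval(rule, "sample", list(ids)))
        if len(ids):
            beta, det = beta.drop(columns=ids), det.drop(columns=ids)

    def drop_probes(rule, ids):
        nonlocal beta, det
        removals.append(RuleRemoval(rule, "probe", list(ids)))
        if len(ids):
            beta, det = beta.drop(index=ids), det.drop(index=ids)

    def sample_rules():
        drop_samples("sample_missing_beta", beta.columns[beta.isna().any(axis=0)])
        agg = _aggregate(det, axis=0, how=thr.aggregation)
        drop_samples("sample_detection_p", agg.index[agg > thr.sample_detection_p])
        frac = (det < thr.confident_detection_p).mean(axis=0)
        drop_samples("sample_detection_fraction", frac.index[frac < thr.detection_fraction])

    def probe_rules():
        drop_probes("probe_missing_beta", beta.index[beta.isna().any(axis=1)])
        agg = _aggregate(det, axis=1, how=thr.aggregation)
        drop_probes("probe_detection_p", agg.index[agg > thr.probe_detection_p])
        frac = (det < thr.confident_detection_p).mean(axis=1)
        drop_probes("probe_detection_fraction", frac.index[frac < thr.detection_fraction])
        snp = annot["snp_flag"].reindex(beta.index).fillna(False).astype(bool)
        drop_probes("probe_snp", beta.index[snp])
        xr = annot["crossreactive_flag"].reindex(beta.index).fillna(False).astype(bool)
        drop_probes("probe_crossreactive", beta.index[xr])

    if thr.samples_first:
        sample_rules()
        probe_rules()
    else:
        probe_rules()
        sample_rules()

    sex = _is_sex_chromosome(annot["chromosome"].reindex(beta.index))
    drop_probes(QCReport.SEX_RULE, beta.index[sex.fillna(False)])

    report = QCReport(cohort.n_probes, cohort.n_samples, removals)
    for line in report.log_lines():
        logger.info(line)
    if beta.shape[0] == 0 or beta.shape[1] == 0:
        raise EmptyCohortError(
            f"empty after QC: {beta.shape[0]} probes x {beta.shape[1]} samples retained"
        )
    return MethylationCohort(beta, det, cohort.covariates), report


def _qn_reference(values: np.ndarray) -> np.ndarray:
    """Mean of the column-sorted values at each rank (rows ranked within column)."""
    return np.sort(values, axis=0).mean(axis=1)


def _qn_map_column(v: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Map one column onto the reference distribution; tied values share the
    mean of the reference values their rank span covers."""
    order = np.argsort(v, kind="mergesort")
    out = np.empty_like(ref)
    out[order] = ref
    uniq, inv, counts = np.unique(v, return_inverse=True, return_counts=True)
    if (counts > 1).any():
        sums = np.bincount(inv, weights=out)
        out = (sums / counts)[inv]
    return out


def quantile_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Classic across-sample quantile normalization of a probe x sample matrix.

    After the operation every sample (column) carries an identical empirical
    distribution: the per-rank mean of the column-sorted input. A single-sample
    matrix is returned unchanged with a warning. Input must be complete.
    """
    if m.isna().to_numpy().any():
        raise ValueError("quantile_normalize requires a complete matrix (no missing values)")
    if m.shape[1] < 2:
        warnings.warn("quantile normalization with a single sample is an identity", stacklevel=2)
        logger.warning("quantile normalization called with %d sample(s); returning input", m.shape[1])
        return m.copy()
    vals = m.to_numpy(float)
    ref = _qn_reference(vals)
    out = np.column_stack([_qn_map_column(vals[:, j], ref) for j in range(vals.shape[1])])
    return pd.DataFrame(out, index=m.index, columns=m.columns)


class QuantileNormalizer(BaseEstimator, TransformerMixin):
    """Sklearn-style quantile normalizer over samples-as-rows matrices.

    ``fit(X)`` learns the reference distribution (the per-rank mean of the
    row-sorted values of X); ``transform(X)`` maps each row (sample) onto that
    reference, ties sharing the mean of the spanned reference values. Note the
    orientation: X is samples x features, the transpose of the pipeline's
    probe x sample frames (use :func:`quantile_normalize` for those).
    """

    def fit(self, X, y=None):
        X = self._validate(X)
        self.reference_ = _qn_reference(X.T)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "reference_")
        X = self._validate(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count differs from fit")
        out = np.vstack([_qn_map_column(row, self.reference_) for row in X])
        return out

    @staticmethod
    def _validate(X) -> np.ndarray:
        arr = np.asarray(X, dtype=float) if not isinstance(X, pd.DataFrame) else X.to_numpy(float)
        if arr.ndim != 2:
            raise ValueError("expected a 2-D samples x features matrix")
        if np.isnan(arr).any():
            raise ValueError("missing values are not supported")
        return arr
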