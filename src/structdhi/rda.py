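"""Redundancy analysis, partial RDA, permutation tests, variation partitioning.

The ordination core is implemented from first principles on numpy linear
algebra: RDA is the multivariate least-squares regression of the response
matrix on the predictor matrix followed by an SVD (equivalently, a PCA)
of the fitted values.  Canonical eigenvalues partition the explained
variance across axes; loadings are Pearson correlations of the original
variables with the site scores.  Axis significance uses a sequential
permutation pseudo-F test; a parametric overall F is available as a
cross-check.  The estimators follow scikit-learn conventions
(``get_params``/``set_params``, fitted attributes with trailing
underscores) so they compose with sklearn tooling, and thin module-level
functions (`fit_rda`, `fit_partial_rda`, ...) wrap them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LogZTransformer",
    "StandardizedMatrix",
    "RedundancyAnalysis",
    "VarPartResult",
    "transform_standardize",
    "fit_rda",
    "fit_partial_rda",
    "axis_significance",
    "normalize_signs",
    "variation_partition",
    "adjusted_r2",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# standardization


class LogZTransformer:
    """ln(x + offset) followed by a z-score with stored statistics.

    The stored means/sds make the transform reusable: a stratum subset
    standardized with the full-sample statistics keeps the full-sample
    scale (its column means are then generally nonzero), which is what
    stratified reruns of the ordination require.

    Parameters
    ----------
    offset : float
        Added before the log so zero-valued attributes stay finite
        (default 1.0, i.e. log1p).
    log : bool
        Disable to z-score raw values (used for direct-mode tables whose
        predictors are already Gaussian).
    """

    def __init__(self, offset: float = 1.0, log: bool = True):
        self.offset = offset
        self.log = log

    # minimal sklearn estimator API
    def get_params(self, deep: bool = True) -> dict:
        return {"offset": self.offset, "log": self.log}

    def set_params(self, **params) -> "LogZTransformer":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def _lift(self, X: np.ndarray) -> np.ndarray:
        if not self.log:
            return X.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(X + self.offset > 0, np.log(np.maximum(X + self.offset, 1e-300)), np.nan)

    def fit(self, X, y=None) -> "LogZTransformer":
        X = pd.DataFrame(X)
        self.feature_names_in_ = list(X.columns)
        lifted = self._lift(X.to_numpy(dtype=float))
        if np.isnan(lifted).any():
            raise ValueError(
                "values with x + offset <= 0 present; drop them first "
                "(transform_standardize does this and logs the count)"
            )
        self.means_ = lifted.mean(axis=0)
        self.sds_ = lifted.std(axis=0, ddof=1)
        for j, sd in enumerate(self.sds_):
            if sd == 0:
                raise ValueError(
                    f"column {self.feature_names_in_[j]!r} is constant; cannot standardize"
                )
        return self

    def transform(self, X) -> pd.DataFrame:
        X = pd.DataFrame(X)
        lifted = self._lift(X[self.feature_names_in_].to_numpy(dtype=float))
        z = (lifted - self.means_) / self.sds_
        return pd.DataFrame(z, columns=self.feature_names_in_, index=X.index)

    def fit_transform(self, X, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)


@dataclass
class StandardizedMatrix:
    """Standardized values plus the transform record that produced them."""

    values: pd.DataFrame
    record: LogZTransformer
    n_dropped: int = 0

    @property
    def columns(self) -> list[str]:
        return list(self.values.columns)

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


def transform_standardize(
    table: pd.DataFrame,
    columns: list[str] | None = None,
    reference: LogZTransformer | None = None,
    offset: float = 1.0,
    log_transform: bool = True,
) -> StandardizedMatrix:
    """ln-transform and z-score a sample table.

    With ``reference`` given (the transform record of the full sample),
    its means/sds are reused, as required for per-stratum reruns.  Rows
    where any value + offset <= 0 are excluded, with the count logged.
    """
    cols = columns if columns is not None else list(table.columns)
    data = table[cols]
    if log_transform:
        ok = (data.to_numpy(dtype=float) + offset > 0).all(axis=1)
    else:
        ok = np.isfinite(data.to_numpy(dtype=float)).all(axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.warning("transform_standardize: dropped %d rows with value + offset <= 0",
                    n_dropped)
    data = data.loc[ok]
    if reference is None:
        record = LogZTransformer(offset=offset, log=log_transform).fit(data)
    else:
        record = reference
    return StandardizedMatrix(values=record.transform(data), record=record,
                              n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# RDA core


def _as_frame(M) -> pd.DataFrame:
    if isinstance(M, StandardizedMatrix):
        return M.values
    if isinstance(M, pd.DataFrame):
        return M
    M = np.asarray(M, dtype=float)
    return pd.DataFrame(M, columns=[f"v{j}" for j in range(M.shape[1])])

def _center(A: np.ndarray) -> np.ndarray:
    return A - A.mean(axis=0)


def _residualize(A: np.ndarray, W: np.ndarray | None) -> np.ndarray:
    """Residuals of (centred) A after least squares on centred W."""
    A = _center(A)
    if W is None or W.size == 0:
        return A
    Wc = _center(W)
    coef, *_ = np.linalg.lstsq(Wc, A, rcond=None)
    return A - Wc @ coef


def _corr_loadings(vars_: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Pearson r of each column of vars_ with each score column."""
    v = _center(vars_)
    s = _center(scores)
    vn = np.linalg.norm(v, axis=0)
    sn = np.linalg.norm(s, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (v.T @ s) / np.outer(vn, sn)
    r[~np.isfinite(r)] = np.nan
    return np.clip(r, -1.0, 1.0)


class RedundancyAnalysis:
    """Redundancy analysis (constrained ordination) estimator.

    ``fit(X, Y, covariates=W)`` regresses the responses Y on the
    predictors X (both typically ln+z standardized), after optionally
    residualizing both on covariates W (partial RDA), and decomposes the
    fitted values by SVD into canonical axes.

    Parameters
    ----------
    svd_tol : float
        Relative singular-value cutoff below which axes (and
        pseudo-inverse directions) are treated as null.
    proportion_basis : {"original", "conditional"}
        Whether partial-RDA axis proportions and R^2 are expressed
        relative to the total variance of the *original* responses
        (default; keeps fractions commensurable across partitions) or of
        the residualized responses.

    Attributes
    ----------
    eigenvalues_ : (k,) canonical eigenvalues, non-increasing.
    total_variance_ : trace of the response covariance (original Y).
    proportions_ : eigenvalues_ / total_variance_.
    r2_ : sum of proportions_ (constrained fraction of variance).
    site_scores_ : (n, k) sample scores, mutually orthogonal.
    predictor_loadings_, response_loadings_ : DataFrames of Pearson r of
        each original variable with each axis.
    axis_pvalues_, axis_retained_ : set by :meth:`permutation_test`.
    """

    def __init__(self, svd_tol: float = 1e-10, proportion_basis: str = "original"):
        self.svd_tol = svd_tol
        self.proportion_basis = proportion_basis

    def get_params(self, deep: bool = True) -> dict:
        return {"svd_tol": self.svd_tol, "proportion_basis": self.proportion_basis}

    def set_params(self, **params) -> "RedundancyAnalysis":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    # -- fitting -----------------------------------------------------------

    def fit(self, X, Y, covariates=None) -> "RedundancyAnalysis":
        Xf, Yf = _as_frame(X), _as_frame(Y)
        Wf = _as_frame(covariates) if covariates is not None and np.size(
            getattr(covariates, "values", covariates)) else None
        Xa, Ya = Xf.to_numpy(dtype=float), Yf.to_numpy(dtype=float)
        n, p = Xa.shape
        q = Ya.shape[1]
        if Ya.shape[0] != n:
            raise ValueError("X and Y must have the same number of rows")
        if n <= p + q + 1:
            raise ValueError(f"need n > p + q + 1 (= {p + q + 1}), got n = {n}")
        if Wf is not None and set(Wf.columns) & set(Xf.columns):
            raise ValueError("covariates must be column-disjoint from predictors")

        Yc_orig = _center(Ya)
        total = float((Yc_orig**2).sum() / (n - 1))
        if total <= 0:
            raise ValueError("zero total variance in responses")

        Wa = Wf.to_numpy(dtype=float) if Wf is not None else None
        Xr = _residualize(Xa, Wa)
        Yr = _residualize(Ya, Wa)

        # least squares via SVD (rank-deficiency safe), then SVD of fits;
        # the rank cutoff is relative to the ORIGINAL predictor scale so
        # that predictors annihilated by the covariates (Xr ~ 0 to
        # rounding) contribute nothing instead of amplified noise
        Ux, sx, Vxt = np.linalg.svd(Xr, full_matrices=False)
        x_scale = np.linalg.svd(_center(Xa), compute_uv=False)[0] if Wa is not None \
            else (sx[0] if sx.size else 0.0)
        keep_x = sx > self.svd_tol * max(x_scale, 1e-300)
        Bhat = Vxt[keep_x].T @ ((Ux[:, keep_x].T @ Yr) / sx[keep_x, None])
        Yhat = Xr @ Bhat
        U, s, Vt = np.linalg.svd(Yhat, full_matrices=False)
        keep = s > self.svd_tol * max(s[0], 1.0) if s.size else np.zeros(0, bool)
        U, s, Vt = U[:, keep], s[keep], Vt[keep]

        if self.proportion_basis == "conditional":
            denom = float((Yr**2).sum() / (n - 1))
        else:
            denom = total

        self.n_samples_, self.n_predictors_, self.n_responses_ = n, p, q
        self.coef_ = Bhat
        self.eigenvalues_ = s**2 / (n - 1)
        self.total_variance_ = total
        self.conditional_variance_ = float((Yr**2).sum() / (n - 1))
        self.proportions_ = self.eigenvalues_ / denom
        self.r2_ = float(self.proportions_.sum())
        self.site_scores_ = U * s
        self._vt = Vt
        self.n_axes_ = int(s.size)
        axes = [f"RDA{k + 1}" for k in range(self.n_axes_)]
        self.axis_names_ = axes
        self.predictor_loadings_ = pd.DataFrame(
            _corr_loadings(Xa, self.site_scores_), index=Xf.columns, columns=axes
        )
        self.response_loadings_ = pd.DataFrame(
            _corr_loadings(Ya, self.site_scores_), index=Yf.columns, columns=axes
        )
        # retained for permutation tests / transform
        self._X, self._Y, self._W = Xf, Yf, Wf
        self.axis_pvalues_ = None
        self.axis_retained_ = None
        return self

    def transform(self, X) -> np.ndarray:
        """Project new predictor rows onto the canonical axes.

        New rows are centred with the training predictor means, pushed
        through the fitted regression and rotated into axis space.
        """
        Xf = _as_frame(X)
        Xa = Xf.to_numpy(dtype=float) - self._X.to_numpy(dtype=float).mean(axis=0)
        return Xa @ self.coef_ @ self._vt.T

    def score(self, X=None, Y=None) -> float:
        """Constrained fraction of response variance (R^2) of the fit."""
        return self.r2_

    @property
    def adjusted_r2_(self) -> float:
        m = self.n_predictors_ + (self._W.shape[1] if self._W is not None else 0)
        return adjusted_r2(self.r2_, self.n_samples_, m)

    # -- inference ---------------------------------------------------------

    def permutation_test(
        self, n_permutations: int = 199, alpha: float = 0.1,
        random_state: int | np.random.Generator | None = None,
    ) -> np.ndarray:
        """Sequential per-axis permutation pseudo-F test.

        Axis k is tested conditioning on axes 1..k-1 (their site scores
        joining the covariates); rows of the residualized response matrix
        are permuted; ``p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)``.
        An axis is retained iff its p-value is below ``alpha`` and all
        earlier axes were retained.
        """
        if n_permutations < 99:
            raise ValueError("n_permutations must be >= 99 for alpha ~ 0.1 resolution")
        rng = np.random.default_rng(random_state)
        Xa = self._X.to_numpy(dtype=float)
        Ya = self._Y.to_numpy(dtype=float)
        Wa = self._W.to_numpy(dtype=float) if self._W is not None else None
        n, p = Xa.shape
        pvals = np.empty(self.n_axes_)
        for k in range(self.n_axes_):
            if Wa is None and k == 0:
                Wk = None
            else:
                parts = ([] if Wa is None else [Wa]) + (
                    [self.site_scores_[:, :k]] if k else []
                )
                Wk = np.hstack(parts) if parts else None
            Xr = _residualize(Xa, Wk)
            Yr = _residualize(Ya, Wk)
            pvals[k] = _perm_pvalue_first_axis(
                Xr, Yr, n_permutations, rng, svd_tol=self.svd_tol,
                resid_df=n - p - 1 - (0 if Wa is None else Wa.shape[1]),
                x_scale=np.linalg.svd(_center(Xa), compute_uv=False)[0],
            )
        self.axis_pvalues_ = pvals
        retained = np.zeros(self.n_axes_, dtype=bool)
        ok = True
        for k in range(self.n_axes_):
            ok = ok and pvals[k] < alpha
            retained[k] = ok
        self.axis_retained_ = retained
        return pvals

    def overall_f_test(self) -> tuple[float, float]:
        """Parametric overall pseudo-F cross-check (redundancy F statistic).

        F = (R^2 / p) / ((1 - R^2) / (n - p - 1)) referred to an
        F(p, n - p - 1) distribution; an approximation for screening,
        not a substitute for the permutation test.
        """
        n, p = self.n_samples_, self.n_predictors_
        r2 = self.r2_
        F = (r2 / p) / max((1.0 - r2) / (n - p - 1), 1e-300)
        pval = float(stats.f.sf(F, p, n - p - 1))
        return float(F), pval

    # -- sign convention ---------------------------------------------------

    def normalize_signs(self, response_column: str = "dhi_cum") -> "RedundancyAnalysis":
        """Flip axes so the designated response loading is non-negative.

        For every axis whose loading on ``response_column`` (the
        cumulative DHI by convention) is negative, all predictor and
        response loadings and the site scores of that axis are negated.
        Eigenvalues are untouched.  Idempotent.
        """
        if response_column not in self.response_loadings_.index:
            raise ValueError(
                f"no response column {response_column!r} among "
                f"{list(self.response_loadings_.index)}"
            )
        flips = self.response_loadings_.loc[response_column].to_numpy() < 0
        sign = np.where(flips, -1.0, 1.0)
        self.site_scores_ = self.site_scores_ * sign
        self._vt = self._vt * sign[:, None]
        self.predictor_loadings_ = self.predictor_loadings_ * sign
        self.response_loadings_ = self.response_loadings_ * sign
        return self

    # -- export ------------------------------------------------------------

    def summary(self) -> dict:
        out = {
            "n": self.n_samples_,
            "eigenvalues": self.eigenvalues_.tolist(),
            "total_variance": self.total_variance_,
            "proportions": self.proportions_.tolist(),
            "r2": self.r2_,
            "adjusted_r2": self.adjusted_r2_,
            "predictor_loadings": self.predictor_loadings_.to_dict(),
            "response_loadings": self.response_loadings_.to_dict(),
        }
        if self.axis_pvalues_ is not None:
            out["axis_pvalues"] = list(map(float, self.axis_pvalues_))
            out["axis_retained"] = list(map(bool, self.axis_retained_))
        return out


def _perm_pvalue_first_axis(
    Xr: np.ndarray, Yr: np.ndarray, n_perm: int, rng: np.random.Generator,
    svd_tol: float, resid_df: int, x_scale: float | None = None,
) -> float:
    """Permutation p-value of the leading canonical axis of Yr ~ Xr.

    Uses the thin-QR identity: with Q an orthonormal basis of the centred
    predictor column space, the singular values of the fitted values
    equal those of Q'Y, so each permutation costs one small matmul and a
    p x q SVD.
    """
    Xc = _center(Xr)
    Q, R = np.linalg.qr(Xc)
    diag = np.abs(np.diag(R))
    if diag.size:
        scale = x_scale if x_scale is not None else diag.max()
        Q = Q[:, diag > svd_tol * max(scale, 1e-300)]
    Yc = _center(Yr)
    ss_total = float((Yc**2).sum())
    resid_df = max(resid_df, 1)

    def f_stat(Y: np.ndarray) -> float:
        T = Q.T @ Y
        s2 = np.linalg.svd(T, compute_uv=False) ** 2
        lam1 = s2[0] if s2.size else 0.0
        resid = max(ss_total - s2.sum(), 0.0)
        if resid <= 0:
            return math.inf if lam1 > 0 else 0.0
        return lam1 * resid_df / resid

    f_obs = f_stat(Yc)
    count = 0
    n = Yc.shape[0]
    for _ in range(n_perm):
        if f_stat(Yc[rng.permutation(n)]) >= f_obs:
            count += 1
    return (1 + count) / (1 + n_perm)


# ---------------------------------------------------------------------------
# module-level wrappers (ecology-style signatures: responses first)


def fit_rda(Y, X, **kwargs) -> RedundancyAnalysis:
    """Fit an RDA of responses Y on predictors X."""
    return RedundancyAnalysis(**kwargs).fit(X, Y)


def fit_partial_rda(Y, X, W, **kwargs) -> RedundancyAnalysis:
    """Fit a partial RDA of Y on X conditioning on covariates W."""
    return RedundancyAnalysis(**kwargs).fit(X, Y, covariates=W)


def axis_significance(
    model: RedundancyAnalysis, n_permutations: int = 199, alpha: float = 0.1,
    random_state=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sequential permutation test of a fitted model's axes."""
    pvals = model.permutation_test(n_permutations=n_permutations, alpha=alpha,
                                   random_state=random_state)
    return pvals, model.axis_retained_


def normalize_signs(model: RedundancyAnalysis,
                    response_column: str = "dhi_cum") -> RedundancyAnalysis:
    """Apply the cumulative-DHI non-negativity sign convention."""
    return model.normalize_signs(response_column)


# ---------------------------------------------------------------------------
# variation partitioning


def adjusted_r2(r2: float, n: int, m: int) -> float:
    """Ezekiel adjustment: 1 - (1 - R^2)(n - 1)/(n - m - 1)."""
    if n - m - 1 <= 0:
        raise ValueError("adjusted R^2 undefined: n <= m + 1")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


@dataclass
class VarPartResult:
    """Two-set variation partition of the response variance.

    ``a`` is unique to the first predictor set, ``c`` unique to the
    second, ``b`` shared, ``residual`` unexplained; raw fractions satisfy
    a + b + c = R^2(X1 u X2) exactly.  Adjusted fractions use the Ezekiel
    correction on each component R^2 and may be slightly negative.
    """

    a: float
    b: float
    c: float
    residual: float
    a_adj: float
    b_adj: float
    c_adj: float
    residual_adj: float
    r2_x1: float
    r2_x2: float
    r2_full: float
    r2_x1_adj: float
    r2_x2_adj: float
    r2_full_adj: float
    n: int

    def as_dict(self) -> dict:
        return {k: float(v) if not isinstance(v, int) else v
                for k, v in self.__dict__.items()}


def variation_partition(Y, X1, X2, **kwargs) -> VarPartResult:
    """Partition the variance of Y explained by two disjoint predictor sets.

    Fits the two component RDAs and the combined RDA; unique fractions
    are differences of R^2, the shared fraction is the inclusion-
    exclusion remainder.  Both raw and Ezekiel-adjusted versions are
    reported because the choice materially changes small fractions.
    """
    X1f, X2f = _as_frame(X1), _as_frame(X2)
    overlap = set(X1f.columns) & set(X2f.columns)
    if overlap:
        raise ValueError(f"predictor sets share column names: {sorted(overlap)}")
    Xall = pd.concat([X1f, X2f], axis=1)
    m1 = fit_rda(Y, X1f, **kwargs)
    m2 = fit_rda(Y, X2f, **kwargs)
    mfull = fit_rda(Y, Xall, **kwargs)
    n = mfull.n_samples_
    r1, r2_, rf = m1.r2_, m2.r2_, mfull.r2_
    a = rf - r2_
    c = rf - r1
    b = r1 + r2_ - rf
    r1a = adjusted_r2(r1, n, X1f.shape[1])
    r2a = adjusted_r2(r2_, n, X2f.shape[1])
    rfa = adjusted_r2(rf, n, Xall.shape[1])
    return VarPartResult(
        a=a, b=b, c=c, residual=1.0 - rf,
        a_adj=rfa - r2a, b_adj=r1a + r2a - rfa, c_adj=rfa - r1a,
        residual_adj=1.0 - rfa,
        r2_x1=r1, r2_x2=r2_, r2_full=rf,
        r2_x1_adj=r1a, r2_x2_adj=r2a, r2_full_adj=rfa,
        n=n,
    )
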