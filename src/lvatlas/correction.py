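"""Protocol bias-correction transforms between paired shape populations.

The central method is the per-parameter maximum-likelihood z-score
correction: with (mu_G, sigma_G) and (mu_S, sigma_S) the ML-estimated
Gaussian parameters of a shape parameter over the GRE and SSFP training
populations,

    SSFP_hat = (GRE - mu_G) / sigma_G * sigma_S + mu_S

so that the corrected GRE population reproduces the SSFP mean and spread
exactly.  Six alternative regression families are provided for comparison:
per-parameter intercept-only, slope+intercept, slope-only and
identity-slope+intercept least squares, a multivariate least-squares map
per block of four parameters, and a global pseudo-inverse matrix map.

``ProtocolBiasCorrector`` is a scikit-learn style transformer:
``fit(X, Y)`` with X the (n_cases, n_params) GRE matrix and Y the paired
SSFP matrix, then ``transform(X)`` maps new GRE parameter vectors into
SSFP-equivalent ones.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "ProtocolBiasCorrector",
    "TRANSFORM_KINDS",
    "fit_transform_variant",
    "apply_transform",
]

TRANSFORM_KINDS = (
    "intercept_only",
    "slope_intercept",
    "slope_only",
    "identity_intercept",
    "mle_zscore",
    "nodal_grouped",
    "pseudo_inverse_global",
)


class ProtocolBiasCorrector(TransformerMixin, BaseEstimator):
    """Learn a GRE -> SSFP shape-parameter correction from paired cases.

    Parameters
    ----------
    kind : str
        One of :data:`TRANSFORM_KINDS`.  ``mle_zscore`` is the z-score
        correction; the others are the comparison regression families.
    unbiased_sd : bool
        Use the n-1 (unbiased) SD estimator instead of the maximum-
        likelihood divide-by-n one for ``mle_zscore``.  The default follows
        the ML convention; the corrected spread ratio is nearly invariant
        to the choice.
    fallback_intercept : bool
        Under ``mle_zscore``, parameters with zero GRE spread switch to an
        intercept-only correction instead of raising.
    block_size : int
        Group size for ``nodal_grouped`` (consecutive parameters in storage
        order; must partition the parameter set).
    sv_rcond : float or None
        Singular-value cutoff for ``pseudo_inverse_global`` (None: numpy's
        machine-precision default).  The global map is under-determined
        whenever parameters outnumber cases and is included for comparison
        only.

    Attributes (after fit)
    ----------------------
    mu_gre_, sigma_gre_, mu_ssfp_, sigma_ssfp_ : (p,) arrays (mle_zscore)
    slope_, intercept_ : (p,) arrays (univariate regression kinds)
    block_matrices_ : (n_blocks, b, b); block_intercepts_ : (n_blocks, b)
    matrix_ : (p, p) (pseudo_inverse_global)
    n_features_in_, n_train_ : int
    """

    def __init__(self, kind: str = "mle_zscore", *, unbiased_sd: bool = False,
                 fallback_intercept: bool = False, block_size: int = 4,
                 sv_rcond: float | None = None):
        self.kind = kind
        self.unbiased_sd = unbiased_sd
        self.fallback_intercept = fallback_intercept
        self.block_size = block_size
        self.sv_rcond = sv_rcond

    # ------------------------------------------------------------------
    def _validate_pair(self, X, Y):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.ndim != 2 or X.shape != Y.shape:
            raise ValueError("X and Y must be 2-D with identical shape")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
            raise ValueError("X and Y must be finite")
        if X.shape[0] < 2 and self.kind != "pseudo_inverse_global":
            raise ValueError("need at least 2 paired cases")
        if X.shape[0] < 10:
            warnings.warn(
                f"fitting a {self.kind} transform on only {X.shape[0]} cases",
                UserWarning, stacklevel=3)
        return X, Y

    def fit(self, X, y=None, **kw):
        """Fit on paired matrices; ``y`` is the SSFP matrix (required)."""
        if y is None:
            raise ValueError("paired SSFP matrix y is required")
        X, Y = self._validate_pair(X, y)
        if self.kind not in TRANSFORM_KINDS:
            raise ValueError(f"unknown transform kind {self.kind!r}")
        n, p = X.shape
        self.n_features_in_ = p
        self.n_train_ = n
        ddof = 1 if self.unbiased_sd else 0

        if self.kind == "mle_zscore":
            self.mu_gre_ = X.mean(axis=0)
            self.mu_ssfp_ = Y.mean(axis=0)
            self.sigma_gre_ = X.std(axis=0, ddof=ddof)
            self.sigma_ssfp_ = Y.std(axis=0, ddof=ddof)
            zero = self.sigma_gre_ <= 0.0
            self.fallback_mask_ = zero if self.fallback_intercept else np.zeros(p, bool)
            if zero.any() and not self.fallback_intercept:
                raise ValueError(
                    "zero GRE spread for parameter(s) "
                    f"{np.flatnonzero(zero).tolist()}; cannot form z-scores "
                    "(set fallback_intercept=True to use intercept-only there)")
        elif self.kind in ("intercept_only", "slope_intercept", "slope_only",
                           "identity_intercept"):
            xm, ym = X.mean(axis=0), Y.mean(axis=0)
            if self.kind == "intercept_only":
                self.slope_ = np.zeros(p)
                self.intercept_ = ym
            elif self.kind == "identity_intercept":
                self.slope_ = np.ones(p)
                self.intercept_ = (Y - X).mean(axis=0)
            elif self.kind == "slope_intercept":
                sxx = ((X - xm) ** 2).sum(axis=0)
                if np.any(sxx <= 0.0):
                    raise ValueError(
                        "degenerate design (constant GRE values) for "
                        f"parameter(s) {np.flatnonzero(sxx <= 0).tolist()}")
                sxy = ((X - xm) * (Y - ym)).sum(axis=0)
                self.slope_ = sxy / sxx
                self.intercept_ = ym - self.slope_ * xm
            else:  # slope_only, through the origin
                sxx = (X ** 2).sum(axis=0)
                if np.any(sxx <= 0.0):
                    raise ValueError(
                        "degenerate design (all-zero GRE values) for "
                        f"parameter(s) {np.flatnonzero(sxx <= 0).tolist()}")
                self.slope_ = (X * Y).sum(axis=0) / sxx
                self.intercept_ = np.zeros(p)
        elif self.kind == "nodal_grouped":
            b = int(self.block_size)
            if b < 1 or p % b:
                raise ValueError(
                    f"block_size {b} does not partition {p} parameters")
            mats, offs = [], []
            for lo in range(0, p, b):
                Xb = X[:, lo:lo + b]
                Yb = Y[:, lo:lo + b]
                A = np.column_stack([Xb, np.ones(n)])
                coef, *_ = np.linalg.lstsq(A, Yb, rcond=None)
                mats.append(coef[:b].T)   # (b, b): y = M x + c
                offs.append(coef[b])
            self.block_matrices_ = np.stack(mats)
            self.block_intercepts_ = np.stack(offs)
        else:  # pseudo_inverse_global
            # y_hat = P x with P = Y' (X')^+ ; interpolates the training set
            # when parameters outnumber cases (unstructured and noisy).
            self.matrix_ = Y.T @ np.linalg.pinv(
                X.T, rcond=self.sv_rcond if self.sv_rcond is not None else 1e-15)
        return self

    # ------------------------------------------------------------------
    def _check_fitted_input(self, X):
        if not hasattr(self, "n_features_in_"):
            raise ValueError("transform called before fit")
        X = np.asarray(X, dtype=float)
        one_d = X.ndim == 1
        X = np.atleast_2d(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"parameter count {X.shape[1]} does not match the fitted "
                f"transform ({self.n_features_in_})")
        return X, one_d

    def transform(self, X):
        """Map GRE parameter vectors to SSFP-equivalent vectors."""
        X, one_d = self._check_fitted_input(X)
        if self.kind == "mle_zscore":
            sg = np.where(self.fallback_mask_, 1.0, self.sigma_gre_)
            out = (X - self.mu_gre_) / sg * self.sigma_ssfp_ + self.mu_ssfp_
            if self.fallback_mask_.any():
                out[:, self.fallback_mask_] = self.mu_ssfp_[self.fallback_mask_]
        elif self.kind in ("intercept_only", "slope_intercept", "slope_only",
                           "identity_intercept"):
            out = self.slope_ * X + self.intercept_
        elif self.kind == "nodal_grouped":
            b = self.block_matrices_.shape[1]
            out = np.empty_like(X)
            for blk in range(self.block_matrices_.shape[0]):
                lo = blk * b
                out[:, lo:lo + b] = (X[:, lo:lo + b] @ self.block_matrices_[blk].T
                                     + self.block_intercepts_[blk])
        else:
            out = X @ self.matrix_.T
        return out[0] if one_d else out

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        """JSON-serializable coefficient dump (see lvatlas.io)."""
        d = {"kind": self.kind, "n_train": int(self.n_train_),
             "n_parameters": int(self.n_features_in_)}
        for attr in ("mu_gre_", "sigma_gre_", "mu_ssfp_", "sigma_ssfp_",
                     "slope_", "intercept_", "block_matrices_",
                     "block_intercepts_", "matrix_", "fallback_mask_"):
            if hasattr(self, attr):
                val = getattr(self, attr)
                d[attr.rstrip("_")] = np.asarray(val).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolBiasCorrector":
        est = cls(kind=d["kind"])
        est.n_train_ = int(d["n_train"])
        est.n_features_in_ = int(d["n_parameters"])
        for attr in ("mu_gre", "sigma_gre", "mu_ssfp", "sigma_ssfp",
                     "slope", "intercept", "block_matrices",
                     "block_intercepts", "matrix"):
            if attr in d:
                setattr(est, attr + "_", np.asarray(d[attr], dtype=float))
        if "fallback_mask" in d:
            est.fallback_mask_ = np.asarray(d["fallback_mask"], dtype=bool)
        return est


# ---------------------------------------------------------------------------
# functional wrappers over the estimator
# ---------------------------------------------------------------------------

def fit_transform_variant(cohort, kind: str = "mle_zscore", frame: str = "ED",
                          **estimator_kw) -> ProtocolBiasCorrector:
    """Fit one transform variant on a paired cohort at one cardiac frame."""
    est = ProtocolBiasCorrector(kind=kind, **estimator_kw)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        est.fit(cohort.params("GRE", frame), cohort.params("SSFP", frame))
    est.frame_ = frame
    return est


def apply_transform(transform: ProtocolBiasCorrector, shape_params):
    """Apply a fitted transform to parameter vector(s)."""
    return transform.transform(shape_params)
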