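"""Anderson-Darling normality screening of shape-parameter distributions.

The z-score correction assumes each shape parameter is approximately
Gaussian across the training population.  This module screens every
(parameter x protocol x frame) marginal with the Anderson-Darling test for
composite normality (mean and variance estimated from the sample), using
the small-sample-adjusted critical values of the Stephens case-4 table as
provided by scipy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["test_normality", "normality_report", "NormalityReport"]

_AD_LEVELS = (0.15, 0.10, 0.05, 0.025, 0.01)


def test_normality(values, alpha: float = 0.05):
    """Anderson-Darling composite-normality test of one parameter sample.

    Returns ``(statistic, passes)`` where ``passes`` is True when the
    statistic does not exceed the size-adjusted critical value at ``alpha``.
    Requires n >= 8; a zero-variance sample is an error (the test statistic
    is undefined).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 8:
        raise ValueError("need a 1-D sample of at least 8 values")
    if not np.all(np.isfinite(values)):
        raise ValueError("sample must be finite")
    if values.std() == 0.0:
        raise ValueError("zero-variance sample: normality test undefined")
    if alpha not in _AD_LEVELS:
        raise ValueError(f"alpha must be one of {_AD_LEVELS}")
    import warnings

    with warnings.catch_warnings():
        # scipy >= 1.17 warns about the future p-value API; the classic
        # critical-value table is exactly what this screen uses
        warnings.simplefilter("ignore", FutureWarning)
        res = stats.anderson(values, dist="norm")
    crit = res.critical_values[_AD_LEVELS.index(alpha)]
    return float(res.statistic), bool(res.statistic <= crit)


test_normality.__test__ = False  # library API, not a pytest case


@dataclass
class NormalityReport:
    """Per-marginal pass flags and the overall pass fraction."""

    pass_fraction: float
    flags: dict       # (frame, protocol) -> (p,) bool array
    statistics: dict  # (frame, protocol) -> (p,) float array
    alpha: float
    n_cases: int


def normality_report(cohort, alpha: float = 0.05) -> NormalityReport:
    """Screen every (parameter, protocol, frame) marginal of a paired cohort."""
    if cohort.n_cases < 8:
        raise ValueError("normality screening needs at least 8 cases")
    flags, statistics = {}, {}
    total, passed = 0, 0
    for frame in cohort.frames:
        for protocol in ("GRE", "SSFP"):
            X = cohort.params(protocol, frame)
            if X.shape[1] == 0:
                raise ValueError("empty parameter set")
            f = np.empty(X.shape[1], dtype=bool)
            s = np.empty(X.shape[1])
            for k in range(X.shape[1]):
                s[k], f[k] = test_normality(X[:, k], alpha)
            flags[(frame, protocol)] = f
            statistics[(frame, protocol)] = s
            total += len(f)
            passed += int(f.sum())
    return NormalityReport(
        pass_fraction=passed / total,
        flags=flags,
        statistics=statistics,
        alpha=alpha,
        n_cases=cohort.n_cases,
    )
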