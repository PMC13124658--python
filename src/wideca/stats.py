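"""Statistical primitives: paired t-test, Holm step-down adjustment, mean +/- SE.

These are written against their closed-form definitions so they can be tested
against independent oracles (textbook arithmetic, brute-force sequential
rejection, scipy/statsmodels cross-checks).  All tests are two-sided; planned
comparisons are run without an omnibus gate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats as sps

from .errors import DegenerateDataError, InvalidParameterError

__all__ = ["ComparisonResult", "MeanSE", "paired_t", "holm_adjust", "mean_se"]


@dataclass(frozen=True)
class ComparisonResult:
    """One planned comparison.  ``p_adjusted`` equals ``p_raw`` until a
    multiplicity adjustment is applied by the caller."""

    label: str
    t_statistic: float
    degrees_of_freedom: int
    p_raw: float
    p_adjusted: float
    significant: bool

    def adjusted(self, p_adjusted: float, alpha: float) -> "ComparisonResult":
        return ComparisonResult(
            label=self.label,
            t_statistic=self.t_statistic,
            degrees_of_freedom=self.degrees_of_freedom,
            p_raw=self.p_raw,
            p_adjusted=float(p_adjusted),
            significant=bool(p_adjusted < alpha),
        )


class MeanSE(NamedTuple):
    mean: float
    se: float
    n: int
    single_observation: bool


def paired_t(xs: Sequence[float], ys: Sequence[float], label: str = "", alpha: float = 0.05) -> ComparisonResult:
    """Two-sided paired t-test on per-subject values.

    t = mean(d) / (sd(d) / sqrt(n)) with d = xs - ys and sd the sample
    standard deviation (ddof=1); df = n - 1; p from the t distribution.
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidParameterError("paired_t requires two equal-length 1-D sequences")
    n = len(x)
    if n < 2:
        raise InvalidParameterError("paired_t requires n >= 2 subjects")
    d = x - y
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        raise DegenerateDataError("paired differences are identical to machine precision; no variance estimate")
    t = float(np.mean(d) / (sd / np.sqrt(n)))
    df = n - 1
    p = float(2.0 * sps.t.sf(abs(t), df))
    return ComparisonResult(
        label=label, t_statistic=t, degrees_of_freedom=df, p_raw=p, p_adjusted=p, significant=bool(p < alpha)
    )


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values, order-preserving.

    With p_(1) <= ... <= p_(m) sorted ascending, the adjusted value is
    adj_(i) = max_{j <= i} min(1, (m - j + 1) * p_(j)), mapped back to the
    input order.  Monotone non-decreasing in the sorted order and uniformly
    no smaller than the raw values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise InvalidParameterError("holm_adjust expects a 1-D sequence of p-values")
    if p.size and (np.min(p) < 0 or np.max(p) > 1):
        raise InvalidParameterError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    scaled = np.minimum(1.0, (m - np.arange(m)) * p[order])
    adjusted_sorted = np.maximum.accumulate(scaled)
    out = np.empty(m, dtype=float)
    out[order] = adjusted_sorted
    return out


def mean_se(values: Sequence[float]) -> MeanSE:
    """Mean and standard error (sample sd / sqrt(n)).

    A single observation yields SE = 0 with ``single_observation=True`` so
    callers can flag the degenerate case instead of silently plotting it.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise InvalidParameterError("mean_se requires a non-empty 1-D sequence")
    n = v.size
    if n == 1:
        return MeanSE(mean=float(v[0]), se=0.0, n=1, single_observation=True)
    return MeanSE(mean=float(np.mean(v)), se=float(np.std(v, ddof=1) / np.sqrt(n)), n=n, single_observation=False)
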