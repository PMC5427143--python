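"""Sparsity-integrated metrics and the group-level statistical toolbox.

To avoid tying conclusions to one arbitrary threshold, each graph metric
is integrated (trapezoidal area under its curve) over the whole sparsity
range before any statistics.  Group comparisons between the 0-back and
2-back conditions use two-tailed paired t-tests; the 80 nodal tests are
additionally screened with Benjamini-Hochberg FDR.  Brain-behavior
coupling is quantified by Pearson correlation with the two-tailed
p-value from the exact t-transform of r.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "MetricCurve",
    "IntegratedMetric",
    "PairedTestResult",
    "FdrResult",
    "CorrelationResult",
    "integrate_over_sparsity",
    "paired_t_test",
    "bh_fdr",
    "pearson_correlation_with_p",
    "pearson_p_from_r",
]


@dataclass
class MetricCurve:
    """One metric as a function of sparsity, for one subject/condition."""

    metric: str
    sparsities: np.ndarray
    values: np.ndarray
    subject_id: str = ""
    condition: str = ""
    band: str = ""

    def __post_init__(self) -> None:
        self.sparsities = np.asarray(self.sparsities, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.sparsities.shape != self.values.shape:
            raise ValueError("curve values must match the sparsity grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite values in {self.metric} curve")


@dataclass
class IntegratedMetric:
    metric: str
    value: float
    subject_id: str = ""
    condition: str = ""
    band: str = ""


@dataclass
class PairedTestResult:
    metric: str
    t: float
    df: int
    p: float
    mean_diff: float  # second condition minus first (2-back minus 0-back)


@dataclass
class FdrResult:
    p_values: np.ndarray
    q: float
    rejected: np.ndarray
    largest_rejected_rank: int  # 0 when nothing is rejected


@dataclass
class CorrelationResult:
    r: float
    n: int
    p: float
    metric: str = ""
    band: str = ""
    behavioral_variable: str = ""


def integrate_over_sparsity(curve: MetricCurve) -> IntegratedMetric:
    """Area under the metric curve (trapezoidal rule on the sparsity axis)."""
    if len(curve.sparsities) < 2:
        raise ValueError("integration requires at least 2 grid points")
    area = float(np.trapezoid(curve.values, curve.sparsities))
    return IntegratedMetric(curve.metric, area, curve.subject_id,
                            curve.condition, curve.band)


def paired_t_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    metric: str = "",
) -> PairedTestResult:
    """Two-tailed paired t-test on per-subject differences b - a."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and equal length")
    n = a.size
    if n < 3:
        raise ValueError("paired t-test requires at least 3 pairs")
    d = b - a
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return PairedTestResult(metric, 0.0, n - 1, 1.0, 0.0)
        raise ValueError("zero variance of paired differences, t undefined")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return PairedTestResult(metric, float(t), n - 1, float(p),
                            float(d.mean()))


def bh_fdr(p_values: Sequence[float], q: float = 0.05) -> FdrResult:
    """Benjamini-Hochberg step-up multiple-testing procedure.

    Rejects the k* smallest p-values, where k* is the largest k with
    p_(k) <= (k/m) q; the rejection set is a prefix of the sorted list.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    thresh = q * (np.arange(1, m + 1) / m)
    passing = np.nonzero(sorted_p <= thresh)[0]
    k_star = int(passing[-1]) + 1 if passing.size else 0
    rejected = np.zeros(m, dtype=bool)
    rejected[order[:k_star]] = True
    return FdrResult(p, q, rejected, k_star)


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-tailed p for a Pearson r via t = r sqrt(n-2)/sqrt(1-r^2)."""
    if n < 4:
        raise ValueError("need at least 4 observations")
    if not -1.0 <= r <= 1.0:
        raise ValueError("r must lie in [-1, 1]")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * sps.t.sf(abs(t), n - 2))


def pearson_correlation_with_p(
    x: Sequence[float],
    y: Sequence[float],
    **meta: str,
) -> CorrelationResult:
    """Sample Pearson r with its exact-t two-tailed p-value."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError("inputs must be 1-D and equal length")
    n = xv.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    if xv.std() == 0 or yv.std() == 0:
        raise ValueError("correlation is undefined for a constant input")
    r = float(np.corrcoef(xv, yv)[0, 1])
    r = min(1.0, max(-1.0, r))
    if 1.0 - abs(r) < 1e-12:  # exact linear dependence, up to rounding
        r = float(np.sign(r))
    return CorrelationResult(r=r, n=n, p=pearson_p_from_r(r, n), **meta)
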