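"""Group mean traces with 95% CI ribbons and two-group comparisons.

Ribbons are pointwise Student-t confidence intervals (a bootstrap
percentile alternative is available). Scalar response statistics are
compared between genotypes/conditions with an unpaired Welch t-test when
both groups pass a Shapiro-Wilk normality screen, otherwise with a
two-sided Mann-Whitney test — the selection is recorded in the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .traces import NormalizedTrace

__all__ = [
    "GroupSummary",
    "TestResult",
    "pointwise_mean_ci",
    "mean_trace_ci",
    "compare_groups",
    "crop_ribbon",
]


@dataclass
class GroupSummary:
    """Pointwise mean %dF/F with a 95% CI ribbon for one group of traces.

    ``ribbon_defined`` is False for n = 1 (no spread to estimate).
    A copy produced by :func:`crop_ribbon` is display-only: its
    statistics accessor raises, so clipped bounds can never re-enter an
    analysis.
    """

    time_s: np.ndarray
    mean: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    n: int
    group_key: Dict[str, object] = field(default_factory=dict)
    alpha: float = 0.05
    ribbon_defined: bool = True
    display_only: bool = False

    def statistics(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(mean, ci_lo, ci_hi) — refuses on display-only (cropped) copies."""
        if self.display_only:
            raise RuntimeError(
                "this summary is a display-only cropped copy; "
                "re-extracting statistics from it is forbidden"
            )
        return self.mean, self.ci_lo, self.ci_hi


@dataclass(frozen=True)
class TestResult:
    """Two-group comparison outcome with the test-selection diagnostics."""

    statistic: float
    p_value: float
    test_used: str  # "unpaired_t" | "mann_whitney"
    n_a: int
    n_b: int
    shapiro_p_a: float
    shapiro_p_b: float


def pointwise_mean_ci(
    values: np.ndarray, alpha: float = 0.05, method: str = "t"
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Columnwise mean and CI of an (n_traces, n_frames) array.

    ``method="t"`` gives mean +/- t_{1-alpha/2, n-1} * s / sqrt(n);
    ``method="bootstrap"`` a seeded percentile bootstrap (2,000 resamples).
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    mean = values.mean(axis=0)
    if n == 1:
        return mean, mean.copy(), mean.copy()
    if method == "t":
        sem = values.std(axis=0, ddof=1) / np.sqrt(n)
        half = sps.t.ppf(1 - alpha / 2, df=n - 1) * sem
        return mean, mean - half, mean + half
    if method == "bootstrap":
        rng = np.random.default_rng(0)
        idx = rng.integers(0, n, size=(2000, n))
        boot = values[idx].mean(axis=1)
        lo = np.quantile(boot, alpha / 2, axis=0)
        hi = np.quantile(boot, 1 - alpha / 2, axis=0)
        return mean, lo, hi
    raise ValueError(f"unknown CI method {method!r}")


def mean_trace_ci(
    traces: Sequence[NormalizedTrace],
    alpha: float = 0.05,
    method: str = "t",
    group_key: Optional[Dict[str, object]] = None,
) -> GroupSummary:
    """Aggregate traces sharing one frame grid into a mean +/- CI ribbon."""
    if not traces:
        raise ValueError("need at least one trace")
    t0 = traces[0].time_s
    for tr in traces[1:]:
        if len(tr) != len(t0) or not np.allclose(tr.time_s, t0, atol=1e-9):
            raise ValueError("traces do not share a common frame grid")
    arr = np.vstack([tr.dff_pct for tr in traces])
    mean, lo, hi = pointwise_mean_ci(arr, alpha=alpha, method=method)
    return GroupSummary(
        time_s=t0.copy(),
        mean=mean,
        ci_lo=lo,
        ci_hi=hi,
        n=len(traces),
        group_key=dict(group_key or {}),
        alpha=alpha,
        ribbon_defined=len(traces) > 1,
    )


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    normality_alpha: float = 0.05,
) -> TestResult:
    """Compare two samples of a scalar response statistic.

    Both groups pass Shapiro-Wilk at ``normality_alpha`` -> two-sided
    Welch t-test; otherwise two-sided Mann-Whitney. Groups of fewer than
    3 values are rejected.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError(f"each group needs n >= 3 (got {len(a)}, {len(b)})")

    # Shapiro is undefined for zero-variance samples; a constant sample
    # is trivially non-normal for test-selection purposes.
    sp_a = sps.shapiro(a).pvalue if np.ptp(a) > 0 else 0.0
    sp_b = sps.shapiro(b).pvalue if np.ptp(b) > 0 else 0.0

    if sp_a > normality_alpha and sp_b > normality_alpha:
        res = sps.ttest_ind(a, b, equal_var=False)
        return TestResult(
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            test_used="unpaired_t",
            n_a=len(a),
            n_b=len(b),
            shapiro_p_a=float(sp_a),
            shapiro_p_b=float(sp_b),
        )
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        test_used="mann_whitney",
        n_a=len(a),
        n_b=len(b),
        shapiro_p_a=float(sp_a),
        shapiro_p_b=float(sp_b),
    )


def crop_ribbon(summary: GroupSummary, y_limits: Tuple[float, float]) -> GroupSummary:
    """Display-only copy with mean and ribbon clamped to ``y_limits``.

    Used to keep consistent y-axes across panels; the original summary
    is untouched and the copy refuses to hand back statistics.
    """
    lo, hi = y_limits
    if not (np.isfinite(lo) and np.isfinite(hi)) or lo >= hi:
        raise ValueError("y_limits must be finite with lo < hi")
    return GroupSummary(
        time_s=summary.time_s.copy(),
        mean=np.clip(summary.mean, lo, hi),
        ci_lo=np.clip(summary.ci_lo, lo, hi),
        ci_hi=np.clip(summary.ci_hi, lo, hi),
        n=summary.n,
        group_key=dict(summary.group_key),
        alpha=summary.alpha,
        ribbon_defined=summary.ribbon_defined,
        display_only=True,
    )
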