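"""Windowed response statistics and ON/OFF/OFF-2/ON-OFF/NONE classification.

The bar statistics follow the figure convention: for each stimulus
transition (ON at 10 s, OFF at 30 s by default), the response amplitude
is the maximum %dF/F in the 10 s after the transition minus the minimum
%dF/F in the 10 s before it. The pre-window is closed at the transition
and the post-window half-open after it, so the transition frame belongs
to "pre".

Classification operationalizes the qualitative shape taxonomy:

* ON      — significant onset transient only
* OFF     — significant hyperpolarizing dip at removal that recovers
            toward baseline (a bump may accompany it)
* OFF-2   — significant removal bump without a dip and without an onset
* ON-OFF  — significant onset and removal bump (biphasic)
* NONE    — nothing significant

"Significant" means exceeding ``k_sig`` baseline standard deviations,
with an absolute floor so that noise-free traces remain classifiable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from scipy.ndimage import uniform_filter1d

from .traces import NormalizedTrace, StimulusProtocol

__all__ = [
    "WindowSpec",
    "ResponseMetrics",
    "ClassifierThresholds",
    "ResponseClass",
    "window_extrema",
    "response_amplitudes",
    "classify_response",
    "classify_trace",
]


@dataclass(frozen=True)
class WindowSpec:
    """Length of the pre/post windows flanking a stimulus transition."""

    window_s: float = 10.0
    reference: str = "ON_transition"  # or "OFF_transition"

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")
        if self.reference not in ("ON_transition", "OFF_transition"):
            raise ValueError("reference must be ON_transition or OFF_transition")


@dataclass(frozen=True)
class ResponseMetrics:
    """Windowed min/max statistics of one normalized trace.

    ``on_amplitude``/``off_amplitude`` are max-post minus min-pre around
    the respective transitions; ``off_dip`` is the minimum %dF/F in the
    10 s after removal; ``afd_on_max``/``afd_off_max`` are the plain
    post-window maxima used for the biphasic (AFD-style) bar plots.
    ``dip_recovery_frac`` is the fraction of the post-removal dip that
    has recovered toward baseline by the end of the window (mean of the
    final 2 s), and ``sigma_baseline`` the s.d. of %dF/F over the
    baseline window. ``off_level`` is the mean %dF/F over the final 1 s
    before removal and ``off_bump_height = off_max_post - off_level``
    the rise after removal relative to that level: an onset transient
    still decaying through the removal window contributes to
    ``off_max_post`` but not to ``off_bump_height``.
    """

    on_amplitude: float
    off_amplitude: float
    off_dip: float
    afd_on_max: float
    afd_off_max: float
    on_max_post: float
    off_min_post: float
    off_max_post: float
    off_level: float
    off_bump_height: float
    dip_recovery_frac: float
    sigma_baseline: float
    # detection statistics: same windowed quantities on a 2.5-s
    # boxcar-smoothed copy of the trace. The transient kernels are ~5 s
    # wide, so smoothing costs a few percent of signal but cuts frame
    # noise by ~sqrt(5); the classifier thresholds these, while the raw
    # extrema above remain the reported bar statistics.
    det_on_max: float = 0.0
    det_off_min: float = 0.0
    det_off_bump: float = 0.0
    det_sigma_baseline: float = 0.0


@dataclass(frozen=True)
class ClassifierThresholds:
    """Significance rules for the shape classifier.

    A windowed statistic counts as significant when it exceeds
    ``k_sig`` times the (smoothed-trace) frame-noise s.d., or, when the
    trace is numerically noise-free, the absolute floor
    ``min_amplitude_pct`` (%dF/F). The default ``k_sig = 3.5`` accounts
    for the search over a 10-s window (~20 frames): a plain 3-sigma
    per-frame cut would fire on a few percent of response-free windows
    just from the maximum over the window. A dip
    must additionally recover at least ``return_frac`` of its depth by
    the end of the post-removal window to count as the transient
    hyperpolarization; with the slow indicator kinetics modelled here
    (decay constant ~8 s) a genuine transient dip has recovered only
    ~40-50% ten seconds after removal, so the default gate is 0.25 —
    enough to reject a sustained depression while accepting the
    indicator-limited recovery.
    """

    k_sig: float = 3.5
    return_frac: float = 0.25
    min_amplitude_pct: float = 1.0

    def __post_init__(self) -> None:
        if self.k_sig <= 0:
            raise ValueError("k_sig must be positive")
        if not (0 < self.return_frac <= 1):
            raise ValueError("return_frac must be in (0, 1]")
        if self.min_amplitude_pct < 0:
            raise ValueError("min_amplitude_pct must be non-negative")


@dataclass(frozen=True)
class ResponseClass:
    """Assigned label plus the threshold comparisons that fired."""

    label: str
    evidence: Tuple[str, ...] = ()


def window_extrema(
    trace: NormalizedTrace,
    protocol: StimulusProtocol,
    spec: WindowSpec,
) -> Tuple[float, float, float]:
    """(min_pre, max_post, min_post) %dF/F around a stimulus transition.

    Pre-window: frames with t in [t_ref - window, t_ref] (closed);
    post-window: frames with t in (t_ref, t_ref + window] (half-open).
    """
    t_ref = protocol.t_on if spec.reference == "ON_transition" else protocol.t_off
    t = trace.time_s
    pre = (t >= t_ref - spec.window_s) & (t <= t_ref)
    post = (t > t_ref) & (t <= t_ref + spec.window_s)
    if not pre.any() or not post.any():
        raise ValueError(
            f"empty window around t = {t_ref} s (trace spans "
            f"{t[0]:.2f}-{t[-1]:.2f} s)"
        )
    d = trace.dff_pct
    return float(d[pre].min()), float(d[post].max()), float(d[post].min())


def response_amplitudes(
    trace: NormalizedTrace,
    protocol: StimulusProtocol,
    window_s: float = 10.0,
    recovery_tail_s: float = 2.0,
) -> ResponseMetrics:
    """Compute all windowed response statistics for one trace."""
    t = trace.time_s
    needed = protocol.t_off + window_s
    if t[-1] < needed - 0.5 / protocol.fps or t[0] > protocol.t_on - window_s:
        missing = []
        if t[0] > protocol.t_on - window_s:
            missing.append("pre-ON window")
        if t[-1] < needed - 0.5 / protocol.fps:
            missing.append("post-OFF window")
        raise ValueError(f"trace truncated: missing {', '.join(missing)}")

    on_min_pre, on_max_post, _ = window_extrema(
        trace, protocol, WindowSpec(window_s, "ON_transition")
    )
    off_min_pre, off_max_post, off_min_post = window_extrema(
        trace, protocol, WindowSpec(window_s, "OFF_transition")
    )

    base = t < protocol.baseline_window
    sigma = float(np.std(trace.dff_pct[base], ddof=1)) if base.sum() > 1 else 0.0

    # smoothed copy for detection (boxcar of ~2.5 s; the transient
    # kernels are ~5 s wide so the attenuation is a few percent)
    n_smooth = max(1, round(2.5 * protocol.fps) | 1)
    ds = uniform_filter1d(trace.dff_pct, size=n_smooth, mode="nearest")
    post_on = (t > protocol.t_on) & (t <= protocol.t_on + window_s)
    post_off = (t > protocol.t_off) & (t <= protocol.t_off + window_s)
    pre_off_tail = (t > protocol.t_off - 1.0) & (t <= protocol.t_off)
    det_on_max = float(ds[post_on].max())
    det_off_min = float(ds[post_off].min())
    # level before removal averaged over 2 s of the smoothed trace, so
    # the bump statistic is not dominated by the level estimate's noise
    det_level_win = (t > protocol.t_off - 2.0) & (t <= protocol.t_off)
    det_off_level = float(np.mean(ds[det_level_win]))
    det_off_bump = float(ds[post_off].max()) - det_off_level
    # frame-noise s.d. estimated from first differences of the raw %dF/F
    # with 10%-per-side trimming (the transients' rise frames land in the
    # trimmed tails); 0.6615 is the Gaussian consistency factor for this
    # trimming. More efficient than a MAD and far more stable than the
    # s.d. of the handful of correlated smoothed baseline frames, which
    # would make the significance threshold itself noisy.
    diffs = np.sort(np.diff(trace.dff_pct))
    n_trim = max(1, len(diffs) // 10)
    core = diffs[n_trim:-n_trim] - np.mean(diffs[n_trim:-n_trim])
    sigma_noise = float(np.sqrt(np.mean(core**2))) / 0.6615 / np.sqrt(2.0)
    det_sigma = sigma_noise / np.sqrt(n_smooth)

    # dip recovery: mean dF/F over the final stretch of the post-OFF
    # window, referenced to the (smoothed) dip depth — single end frames
    # are too noisy to anchor the "returns to baseline" judgement
    tail = (t > protocol.t_off + window_s - recovery_tail_s) & (t <= protocol.t_off + window_s)
    tail_mean = float(np.mean(ds[tail]))
    if det_off_min < 0:
        recovery = (tail_mean - det_off_min) / (0.0 - det_off_min)
        recovery = float(np.clip(recovery, 0.0, None))
    else:
        recovery = 1.0

    off_level = float(np.mean(trace.dff_pct[pre_off_tail]))

    return ResponseMetrics(
        on_amplitude=on_max_post - on_min_pre,
        off_amplitude=off_max_post - off_min_pre,
        off_dip=off_min_post,
        afd_on_max=on_max_post,
        afd_off_max=off_max_post,
        on_max_post=on_max_post,
        off_min_post=off_min_post,
        off_max_post=off_max_post,
        off_level=off_level,
        off_bump_height=off_max_post - off_level,
        dip_recovery_frac=recovery,
        sigma_baseline=sigma,
        det_on_max=det_on_max,
        det_off_min=det_off_min,
        det_off_bump=det_off_bump,
        det_sigma_baseline=det_sigma,
    )


def classify_response(
    metrics: ResponseMetrics,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> ResponseClass:
    """Assign exactly one shape label from the windowed statistics.

    Detection uses the smoothed statistics (``det_*``): onset fires when
    the post-ON maximum exceeds the threshold, the dip when the post-OFF
    minimum falls below its negative and the trace recovers, and the
    bump when the post-OFF rise over the pre-removal level exceeds it —
    so a decaying onset transient does not masquerade as a removal
    response.
    """
    thr = max(thresholds.k_sig * metrics.det_sigma_baseline, thresholds.min_amplitude_pct)

    onset = metrics.det_on_max >= thr
    dip = metrics.det_off_min <= -thr and metrics.dip_recovery_frac >= thresholds.return_frac
    bump = metrics.det_off_bump >= thr

    evidence = (
        f"threshold = {thr:.3g} %dF/F (k_sig={thresholds.k_sig} x sigma="
        f"{metrics.det_sigma_baseline:.3g}, floor={thresholds.min_amplitude_pct})",
        f"onset: smoothed max_post(ON) = {metrics.det_on_max:.3g} "
        f"{'>=' if onset else '<'} {thr:.3g}",
        f"dip: smoothed min_post(OFF) = {metrics.det_off_min:.3g} "
        f"{'<=' if metrics.det_off_min <= -thr else '>'} {-thr:.3g}, "
        f"recovery = {metrics.dip_recovery_frac:.2f} "
        f"(need >= {thresholds.return_frac})",
        f"bump: smoothed max_post(OFF) - pre-removal level = {metrics.det_off_bump:.3g} "
        f"{'>=' if bump else '<'} {thr:.3g}",
    )

    if dip and not onset:
        label = "OFF"  # dip with or without accompanying bump
    elif onset and bump:
        label = "ON_OFF"
    elif onset:
        label = "ON"
    elif bump:
        label = "OFF2"
    else:
        label = "NONE"
    return ResponseClass(label=label, evidence=evidence)


def classify_trace(
    trace: NormalizedTrace,
    protocol: StimulusProtocol,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> ResponseClass:
    """Convenience: metrics + classification in one call."""
    return classify_response(response_amplitudes(trace, protocol), thresholds)
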