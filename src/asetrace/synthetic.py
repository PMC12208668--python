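"""Synthetic recordings with known ground truth.

Every downstream stage of the pipeline is tested against traces, image
stacks and chemotaxis plates produced here, so each simulator returns its
ground truth alongside the data.

Calcium transients are modelled as rise-times-decay kernels

    k(t; t0, A, tau_r, tau_d) = A * (1 - exp(-(t-t0)/tau_r)) * exp(-(t-t0)/tau_d)

for t >= t0 (zero before), one kernel at stimulus onset and up to two
(a hyperpolarizing dip and/or a positive bump) at stimulus removal. The
default time constants (tau_r = 1.5 s, tau_d = 8 s) give the slow,
multi-second transients characteristic of the red indicator jRCaMP1a.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .chemo import PlateRecord
from .stacks import ImageStack
from .traces import RawTrace, StimulusProtocol, TraceMeta

__all__ = [
    "CLASS_LABELS",
    "ResponseTemplate",
    "NoiseModel",
    "GroundTruth",
    "RoiSpec",
    "ImageStack",
    "transient_kernel",
    "kernel_peak_time",
    "noiseless_dff",
    "default_template",
    "simulate_trace",
    "simulate_cohort",
    "simulate_stack",
    "simulate_chemotaxis_plate",
]

CLASS_LABELS = ("ON", "OFF", "OFF2", "ON_OFF", "NONE")


@dataclass(frozen=True)
class ResponseTemplate:
    """Noiseless response shape for one of the five observed classes.

    Amplitudes are in percent dF/F: ``a_on`` is the onset transient,
    ``a_off_dip`` the (non-positive) removal dip, ``a_off_bump`` the
    (non-negative) removal bump.
    """

    class_label: str
    a_on: float = 0.0
    a_off_dip: float = 0.0
    a_off_bump: float = 0.0
    tau_rise: float = 1.5
    tau_decay: float = 8.0

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")
        if self.tau_rise <= 0 or self.tau_decay <= 0:
            raise ValueError("time constants must be positive")
        lbl = self.class_label
        ok = {
            "ON": self.a_on > 0 and self.a_off_dip == 0 and self.a_off_bump == 0,
            "OFF": self.a_on == 0 and self.a_off_dip < 0,
            "OFF2": self.a_on == 0 and self.a_off_dip == 0 and self.a_off_bump > 0,
            "ON_OFF": self.a_on > 0 and self.a_off_bump > 0 and self.a_off_dip == 0,
            "NONE": self.a_on == 0 and self.a_off_dip == 0 and self.a_off_bump == 0,
        }[lbl]
        if not ok:
            raise ValueError(
                f"amplitudes (a_on={self.a_on}, a_off_dip={self.a_off_dip}, "
                f"a_off_bump={self.a_off_bump}) are inconsistent with class {lbl}"
            )
        if self.a_off_dip > 0 or self.a_off_bump < 0:
            raise ValueError("a_off_dip must be <= 0 and a_off_bump >= 0")


@dataclass(frozen=True)
class NoiseModel:
    """Recording-condition model: baseline brightness, background, noise.

    ``tau_bleach`` is the photobleaching time constant in seconds
    (``math.inf`` disables bleaching); bleaching multiplies the signal
    term only, not the additive background.
    """

    f0_true: float = 100.0
    background_level: float = 10.0
    sigma_shot: float = 0.0
    tau_bleach: float = math.inf
    seed: int = 0

    def __post_init__(self) -> None:
        if self.f0_true <= 0:
            raise ValueError("f0_true must be positive")
        if self.sigma_shot < 0:
            raise ValueError("sigma_shot must be non-negative")
        if self.background_level < 0:
            raise ValueError("background_level must be non-negative")
        if not (self.tau_bleach > 0):
            raise ValueError("tau_bleach must be positive (use math.inf for none)")


@dataclass
class GroundTruth:
    """What the generator actually drew: label, amplitudes, noiseless dF/F."""

    class_label: str
    template: ResponseTemplate
    f0_true: float
    dff_noiseless: np.ndarray  # percent dF/F per frame


def transient_kernel(
    t: np.ndarray, t0: float, amplitude: float, tau_rise: float, tau_decay: float
) -> np.ndarray:
    """Evaluate the rise-times-decay transient kernel at times ``t``."""
    t = np.asarray(t, dtype=float)
    dt = t - t0
    out = np.zeros_like(dt)
    pos = dt >= 0
    d = dt[pos]
    out[pos] = amplitude * (1.0 - np.exp(-d / tau_rise)) * np.exp(-d / tau_decay)
    return out


def kernel_peak_time(t0: float, tau_rise: float, tau_decay: float) -> float:
    """Closed-form time of the kernel extremum: t0 + tau_r*ln(1 + tau_d/tau_r)."""
    return t0 + tau_rise * math.log(1.0 + tau_decay / tau_rise)


def noiseless_dff(
    protocol: StimulusProtocol, template: ResponseTemplate, t: np.ndarray | None = None
) -> np.ndarray:
    """Ground-truth percent dF/F: onset kernel at ON, dip+bump kernels at OFF."""
    if t is None:
        t = protocol.times()
    g = transient_kernel(t, protocol.t_on, template.a_on, template.tau_rise, template.tau_decay)
    g += transient_kernel(
        t, protocol.t_off, template.a_off_dip, template.tau_rise, template.tau_decay
    )
    g += transient_kernel(
        t, protocol.t_off, template.a_off_bump, template.tau_rise, template.tau_decay
    )
    return g


def simulate_trace(
    protocol: StimulusProtocol,
    template: ResponseTemplate,
    noise: NoiseModel,
    meta: TraceMeta | None = None,
) -> Tuple[RawTrace, GroundTruth]:
    """Simulate one raw fluorescence trace plus its ground truth.

    Noiseless fluorescence is
    ``F(t) = background + f0_true * (1 + g(t)/100) * bleach(t)`` with
    ``g`` the summed transient kernels and ``bleach(t) = exp(-t/tau_bleach)``;
    i.i.d. Gaussian noise of s.d. ``sigma_shot`` is added per frame.
    Deterministic given ``noise.seed``.
    """
    t = protocol.times()
    g = noiseless_dff(protocol, template, t)
    bleach = (
        np.exp(-t / noise.tau_bleach) if math.isfinite(noise.tau_bleach) else np.ones_like(t)
    )
    f_clean = noise.background_level + noise.f0_true * (1.0 + g / 100.0) * bleach
    rng = np.random.default_rng(noise.seed)
    f = f_clean + rng.normal(0.0, noise.sigma_shot, size=t.shape) if noise.sigma_shot > 0 else f_clean
    f = np.maximum(f, 0.0)
    raw = RawTrace(
        time_s=t,
        f_raw=f,
        f_background=np.full_like(t, noise.background_level),
        meta=meta or TraceMeta(),
    )
    truth = GroundTruth(
        class_label=template.class_label,
        template=template,
        f0_true=noise.f0_true,
        dff_noiseless=g,
    )
    return raw, truth


_DEFAULT_SIGNS = {
    # which amplitude slots each class fills, as (on, dip, bump) multipliers
    "ON": (1.0, 0.0, 0.0),
    "OFF": (0.0, -1.0, 0.0),
    "OFF2": (0.0, 0.0, 1.0),
    "ON_OFF": (1.0, 0.0, 1.0),
    "NONE": (0.0, 0.0, 0.0),
}


def default_template(label: str, magnitude: float = 50.0) -> ResponseTemplate:
    """A canonical template of the given class with all active amplitudes
    set to ``magnitude`` (%dF/F)."""
    s_on, s_dip, s_bump = _DEFAULT_SIGNS[label]
    return ResponseTemplate(
        class_label=label,
        a_on=s_on * magnitude,
        a_off_dip=s_dip * magnitude,
        a_off_bump=s_bump * magnitude,
    )


def _trace_seed(master_seed: int, index: int) -> int:
    # reproducible parallel-safe per-trace stream
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0] % (2**31))


def simulate_cohort(
    protocol: StimulusProtocol,
    class_mix: Dict[str, int],
    amplitude_range: Tuple[float, float] = (40.0, 80.0),
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
) -> Tuple[List[RawTrace], List[GroundTruth]]:
    """Simulate a cohort of traces with labels drawn per ``class_mix``.

    Each active amplitude magnitude is drawn uniformly from
    ``amplitude_range`` (%dF/F); per-trace seeds are derived from the
    master seed so the cohort is reproducible trace by trace.
    """
    if not class_mix:
        raise ValueError("class_mix must not be empty")
    for label, count in class_mix.items():
        if label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {label!r}")
        if count < 0:
            raise ValueError("counts must be non-negative")
    lo, hi = amplitude_range
    if not (0 < lo <= hi):
        raise ValueError("amplitude_range must satisfy 0 < lo <= hi")
    rng = np.random.default_rng(seed)
    labels = [lbl for lbl in CLASS_LABELS for _ in range(class_mix.get(lbl, 0))]
    traces: List[RawTrace] = []
    truths: List[GroundTruth] = []
    for i, label in enumerate(labels):
        s_on, s_dip, s_bump = _DEFAULT_SIGNS[label]
        mags = rng.uniform(lo, hi, size=3)
        template = ResponseTemplate(
            class_label=label,
            a_on=s_on * mags[0],
            a_off_dip=s_dip * mags[1],
            a_off_bump=s_bump * mags[2],
        )
        trace_noise = NoiseModel(
            f0_true=noise.f0_true,
            background_level=noise.background_level,
            sigma_shot=noise.sigma_shot,
            tau_bleach=noise.tau_bleach,
            seed=_trace_seed(seed, i),
        )
        meta = TraceMeta(worm_id=f"worm-{i:03d}")
        raw, truth = simulate_trace(protocol, template, trace_noise, meta=meta)
        traces.append(raw)
        truths.append(truth)
    return traces, truths


@dataclass(frozen=True)
class RoiSpec:
    """One simulated neuron spot: start position, per-frame drift, width,
    and the fluorescence trace its integrated intensity follows."""

    start_xy: Tuple[float, float]
    drift_xy: Tuple[float, float] = (0.0, 0.0)
    sigma_px: float = 1.5
    trace: Sequence[float] = field(default_factory=tuple)


def simulate_stack(
    protocol: StimulusProtocol,
    roi_specs: Sequence[RoiSpec],
    frame_size: Tuple[int, int] = (64, 64),
    background: float = 20.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Tuple[ImageStack, np.ndarray]:
    """Render Gaussian spots over a uniform background into an image stack.

    Each ROI's spot is an isotropic 2-D Gaussian whose *integrated*
    intensity at frame k equals ``trace[k]``; spots drift linearly. The
    returned ground truth has shape (n_frames, n_rois, 2) holding (x, y)
    centroids. Raises if any spot would leave the frame (within
    3 sigma of an edge).
    """
    n_frames = protocol.n_frames
    h, w = frame_size
    yy, xx = np.mgrid[0:h, 0:w]
    rng = np.random.default_rng(seed)
    frames = np.full((n_frames, h, w), float(background))
    centroids = np.zeros((n_frames, len(roi_specs), 2))
    for r, spec in enumerate(roi_specs):
        trace = np.asarray(spec.trace, dtype=float)
        if len(trace) != n_frames:
            raise ValueError(
                f"roi {r}: trace length {len(trace)} != protocol n_frames {n_frames}"
            )
        x0, y0 = spec.start_xy
        dx, dy = spec.drift_xy
        sig = spec.sigma_px
        for k in range(n_frames):
            cx, cy = x0 + dx * k, y0 + dy * k
            if not (3 * sig <= cx <= w - 1 - 3 * sig and 3 * sig <= cy <= h - 1 - 3 * sig):
                raise ValueError(f"roi {r} leaves the frame at frame {k} (x={cx:.1f}, y={cy:.1f})")
            spot = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sig**2))
            frames[k] += trace[k] * spot / (2 * np.pi * sig**2)
            centroids[k, r] = (cx, cy)
    if noise_sd > 0:
        frames += rng.normal(0.0, noise_sd, size=frames.shape)
        frames = np.maximum(frames, 0.0)
    return ImageStack(frames=frames, frame_interval_s=protocol.frame_interval_s), centroids


def simulate_chemotaxis_plate(
    n_loaded: int = 200,
    participation: float = 0.4,
    p_attract: float = 0.5,
    seed: int = 0,
    plate_id: str = "plate-0",
    condition: str = "wildtype",
    salt: str = "NH4Cl",
) -> PlateRecord:
    """Simulate one end-point assay plate.

    Each of ``n_loaded`` worms independently reaches a scoring arena with
    probability ``participation``; a participant scores at the attractant
    spot with probability ``p_attract``, else at the control spot. The
    defaults emulate the assay conditions (about 200 worms loaded,
    roughly 40% participating).
    """
    if n_loaded < 0:
        raise ValueError("n_loaded must be non-negative")
    if not (0 <= participation <= 1 and 0 <= p_attract <= 1):
        raise ValueError("participation and p_attract must be probabilities")
    rng = np.random.default_rng(seed)
    n_scored = rng.binomial(n_loaded, participation)
    a = rng.binomial(n_scored, p_attract)
    return PlateRecord(
        plate_id=plate_id,
        genotype=condition,
        salt=salt,
        A=int(a),
        C=int(n_scored - a),
        n_loaded=n_loaded,
    )
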