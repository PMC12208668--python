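"""Stimulus protocol, raw/normalized fluorescence traces, and laterality.

The normalization follows the standard calcium-imaging convention for
these recordings: background-subtracted fluorescence F is referenced to a
baseline F0, the mean F over the pre-stimulus baseline window (first 9 s
of each 60-s recording by default), and expressed as percent change,
dF/F = 100 * (F - F0) / F0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "StimulusProtocol",
    "OrientationRecord",
    "TraceMeta",
    "RawTrace",
    "NormalizedTrace",
    "TraceRejected",
    "subtract_background",
    "compute_baseline",
    "normalize",
    "normalize_trace",
    "assign_laterality",
    "LATERALITY_TABLE",
]


class TraceRejected(ValueError):
    """A trace failed a validity rule (e.g. non-positive baseline)."""


@dataclass(frozen=True)
class StimulusProtocol:
    """Valve timing and frame-rate contract for one recording.

    Defaults encode the 60-s program used throughout: 10 s stimulant OFF,
    20 s stimulant ON, 30 s stimulant OFF, imaged at 2 fps, with the
    first 9 s serving as the F0 baseline window.
    """

    t_on: float = 10.0
    stim_duration: float = 20.0
    t_total: float = 60.0
    fps: float = 2.0
    baseline_window: float = 9.0

    def __post_init__(self) -> None:
        if not (0.0 < self.baseline_window <= self.t_on):
            raise ValueError("baseline_window must satisfy 0 < baseline_window <= t_on")
        if not (self.t_on + self.stim_duration < self.t_total):
            raise ValueError("stimulus must end before the recording does")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def t_off(self) -> float:
        """Time of stimulus removal (s)."""
        return self.t_on + self.stim_duration

    @property
    def n_frames(self) -> int:
        return round(self.t_total * self.fps)

    @property
    def frame_interval_s(self) -> float:
        return 1.0 / self.fps

    def times(self) -> np.ndarray:
        """Frame timestamps; frame i is stamped at t = i / fps."""
        return np.arange(self.n_frames) / self.fps


@dataclass(frozen=True)
class OrientationRecord:
    """Worm orientation as seen in the image frame.

    nose_direction and ventral_side are read off the recording (the vulva
    marks the ventral side); focal_neuron says whether the imaged neuron
    of the bilateral pair was in the focal plane nearer to or farther
    from the objective.
    """

    nose_direction: str  # "left" | "right"
    ventral_side: str  # "top" | "bottom"
    focal_neuron: str  # "near_objective" | "far_objective"

    def __post_init__(self) -> None:
        if self.nose_direction not in ("left", "right"):
            raise ValueError(f"nose_direction must be left/right, got {self.nose_direction!r}")
        if self.ventral_side not in ("top", "bottom"):
            raise ValueError(f"ventral_side must be top/bottom, got {self.ventral_side!r}")
        if self.focal_neuron not in ("near_objective", "far_objective"):
            raise ValueError(
                f"focal_neuron must be near_objective/far_objective, got {self.focal_neuron!r}"
            )


@dataclass(frozen=True)
class TraceMeta:
    """Per-recording metadata carried alongside a trace."""

    neuron: str = "ASEL"  # ASEL | ASER | AFDL | AFDR (or unassigned "ASE"/"AFD")
    genotype: str = "wildtype"
    stimulus: str = "NH4Cl"
    conc_mM: float = 250.0
    worm_id: str = "worm-0"
    orientation: Optional[OrientationRecord] = None


@dataclass
class RawTrace:
    """Per-frame raw and background fluorescence (arbitrary units)."""

    time_s: np.ndarray
    f_raw: np.ndarray
    f_background: np.ndarray
    meta: TraceMeta = field(default_factory=TraceMeta)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.f_raw = np.asarray(self.f_raw, dtype=float)
        self.f_background = np.asarray(self.f_background, dtype=float)
        n = len(self.time_s)
        if len(self.f_raw) != n or len(self.f_background) != n:
            raise ValueError("time_s, f_raw and f_background must have equal length")
        if n > 1:
            dt = np.diff(self.time_s)
            if np.any(dt <= 0):
                raise ValueError("timestamps must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("timestamps must be uniformly spaced")
        if np.any(self.f_raw < 0):
            raise ValueError("raw fluorescence must be non-negative")

    def __len__(self) -> int:
        return len(self.time_s)


@dataclass
class NormalizedTrace:
    """Percent dF/F trace with its baseline F0 and protocol."""

    time_s: np.ndarray
    dff_pct: np.ndarray
    f0: float
    protocol: StimulusProtocol
    meta: TraceMeta = field(default_factory=TraceMeta)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.dff_pct = np.asarray(self.dff_pct, dtype=float)
        if len(self.time_s) != len(self.dff_pct):
            raise ValueError("time_s and dff_pct must have equal length")
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")

    def __len__(self) -> int:
        return len(self.time_s)


def subtract_background(raw: RawTrace) -> RawTrace:
    """Subtract the per-frame background from the raw fluorescence.

    Negative results are floored at zero; the number of floored frames is
    logged as a warning so callers can audit it.
    """
    diff = raw.f_raw - raw.f_background
    n_floored = int(np.sum(diff < 0))
    if n_floored:
        logger.warning(
            "background subtraction floored %d negative frame(s) at 0 (worm %s)",
            n_floored,
            raw.meta.worm_id,
        )
        diff = np.maximum(diff, 0.0)
    return replace(raw, f_raw=diff, f_background=np.zeros_like(raw.f_background))


def compute_baseline(raw: RawTrace, protocol: StimulusProtocol) -> float:
    """Baseline F0: mean fluorescence over frames with t < baseline_window.

    Strict inequality: at 2 fps with a 9-s window this is frames 0-17.
    Assumes the background has already been subtracted.
    """
    mask = raw.time_s < protocol.baseline_window
    if int(mask.sum()) < 2:
        raise ValueError(
            f"too few baseline frames: {int(mask.sum())} with t < {protocol.baseline_window} s"
        )
    f0 = float(np.mean(raw.f_raw[mask]))
    if f0 <= 0:
        raise TraceRejected(
            f"non-positive baseline (F0 = {f0:g}); normalization undefined for worm "
            f"{raw.meta.worm_id}"
        )
    return f0


def normalize(raw: RawTrace, f0: float, protocol: StimulusProtocol) -> NormalizedTrace:
    """Express a background-subtracted trace as percent dF/F about f0."""
    if f0 <= 0:
        raise ValueError("f0 must be positive")
    dff = 100.0 * (raw.f_raw - f0) / f0
    return NormalizedTrace(
        time_s=raw.time_s.copy(), dff_pct=dff, f0=f0, protocol=protocol, meta=raw.meta
    )


def normalize_trace(raw: RawTrace, protocol: StimulusProtocol) -> NormalizedTrace:
    """Full pipeline: subtract background, compute F0, normalize to %dF/F."""
    sub = subtract_background(raw)
    f0 = compute_baseline(sub, protocol)
    return normalize(sub, f0, protocol)


def _laterality_parity(o: OrientationRecord) -> str:
    flips = (
        (o.nose_direction == "right")
        ^ (o.ventral_side == "top")
        ^ (o.focal_neuron == "far_objective")
    )
    return "right" if flips else "left"


# Declared 8-row lookup from (nose_direction, ventral_side, focal_neuron)
# to the imaged neuron's body side. The anchor is (left, bottom,
# near_objective) -> left; flipping any single field flips the output,
# which is the geometric consistency the orientation bookkeeping must
# obey. The table is the package's declared convention.
LATERALITY_TABLE: dict[tuple[str, str, str], str] = {
    (nose, ventral, focal): _laterality_parity(
        OrientationRecord(nose, ventral, focal)
    )
    for nose in ("left", "right")
    for ventral in ("top", "bottom")
    for focal in ("near_objective", "far_objective")
}


def assign_laterality(o: OrientationRecord) -> str:
    """Map worm orientation to the imaged neuron's side ("left"/"right").

    Deterministic lookup over the 8 orientation combinations; raises if
    any field is missing.
    """
    for name in ("nose_direction", "ventral_side", "focal_neuron"):
        if getattr(o, name, None) is None:
            raise ValueError(f"laterality indeterminate: missing {name}")
    return LATERALITY_TABLE[(o.nose_direction, o.ventral_side, o.focal_neuron)]
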