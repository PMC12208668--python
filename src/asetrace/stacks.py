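"""ROI tracking in time-lapse stacks and raw-trace extraction.

Follows each neuron's fluorescent spot across frames: the centroid in a
frame is the background-floored intensity-weighted centroid of pixels
within a search radius of the previous centroid; the ROI fluorescence is
the pixel sum within the ROI radius, and the local background is the
median of a surrounding annulus, scaled to the ROI pixel count. Pixel
coordinates have their origin at the image top-left with x = column,
y = row, and integer pixel centers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .traces import RawTrace, TraceMeta

__all__ = ["ImageStack", "RoiTrack", "TrackingError", "track_roi", "extract_traces"]


class TrackingError(ValueError):
    """Tracking failed (lost spot, overlapping ROIs, ...)."""


@dataclass
class ImageStack:
    """Ordered frames of a time-lapse recording (x = column, y = row)."""

    frames: np.ndarray  # (n_frames, h, w)
    frame_interval_s: float = 0.5
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, h, w) array")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> Tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class RoiTrack:
    """Per-frame centroid, integrated fluorescence and local background."""

    roi_id: int
    centroids: np.ndarray  # (n_frames, 2) as (x, y)
    fluorescence: np.ndarray  # (n_frames,) pixel sum within roi_radius
    background: np.ndarray  # (n_frames,) annulus median * roi pixel count
    flagged: np.ndarray  # (n_frames,) bool, spot lost on that frame


def _disk_mask(shape: Tuple[int, int], cx: float, cy: float, radius: float) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2


def track_roi(
    stack: ImageStack,
    initial_centroid: Tuple[float, float],
    search_radius_px: float = 5.0,
    roi_radius_px: float = 5.0,
    lost_threshold: float = 10.0,
    max_flagged_frac: float = 0.2,
    roi_id: int = 0,
) -> RoiTrack:
    """Track one spot across all frames starting from ``initial_centroid``.

    A frame is flagged as "spot lost" when the peak intensity inside the
    search window does not exceed the local background by
    ``lost_threshold``; the previous centroid is then carried forward.
    The whole trace is rejected when more than ``max_flagged_frac`` of
    frames are flagged.
    """
    if search_radius_px <= 0 or roi_radius_px <= 0:
        raise ValueError("radii must be positive")
    h, w = stack.frame_shape
    cx, cy = initial_centroid
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError("initial centroid outside the frame")

    n = stack.n_frames
    centroids = np.zeros((n, 2))
    fluor = np.zeros(n)
    bg = np.zeros(n)
    flagged = np.zeros(n, dtype=bool)
    yy, xx = np.mgrid[0:h, 0:w]

    for k in range(n):
        frame = stack.frames[k]
        search = (xx - cx) ** 2 + (yy - cy) ** 2 <= search_radius_px**2
        vals = frame[search]
        # floor at the local median so uniform background carries no weight
        floor = np.median(vals)
        weights = np.clip(vals - floor, 0.0, None)
        if frame[search].max() < floor + lost_threshold or weights.sum() <= 0:
            flagged[k] = True  # carry previous centroid
        else:
            cx = float(np.average(xx[search], weights=weights))
            cy = float(np.average(yy[search], weights=weights))
        centroids[k] = (cx, cy)

        roi = (xx - cx) ** 2 + (yy - cy) ** 2 <= roi_radius_px**2
        annulus = ((xx - cx) ** 2 + (yy - cy) ** 2 > roi_radius_px**2) & (
            (xx - cx) ** 2 + (yy - cy) ** 2 <= (2 * roi_radius_px) ** 2
        )
        fluor[k] = float(frame[roi].sum())
        bg[k] = float(np.median(frame[annulus])) * int(roi.sum())

    frac = flagged.mean()
    if frac > max_flagged_frac:
        raise TrackingError(
            f"roi {roi_id}: spot lost on {flagged.sum()}/{n} frames "
            f"({100 * frac:.0f}% > {100 * max_flagged_frac:.0f}% allowed)"
        )
    return RoiTrack(
        roi_id=roi_id, centroids=centroids, fluorescence=fluor, background=bg, flagged=flagged
    )


def extract_traces(
    stack: ImageStack,
    initial_centroids: Sequence[Tuple[float, float]],
    search_radius_px: float = 5.0,
    roi_radius_px: float = 5.0,
    lost_threshold: float = 10.0,
    metas: Sequence[TraceMeta] | None = None,
) -> List[RawTrace]:
    """Track every ROI and emit one RawTrace per ROI.

    Initial centroids must be pairwise separated by more than twice the
    ROI radius so the ROIs (and their background annuli) do not overlap.
    """
    pts = np.asarray(initial_centroids, dtype=float)
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            if np.hypot(*(pts[i] - pts[j])) <= 2 * roi_radius_px:
                raise TrackingError(
                    f"ROIs {i} and {j} overlap: centroids closer than 2*roi_radius"
                )
    times = np.arange(stack.n_frames) * stack.frame_interval_s
    out: List[RawTrace] = []
    for i, c in enumerate(pts):
        track = track_roi(
            stack,
            (c[0], c[1]),
            search_radius_px=search_radius_px,
            roi_radius_px=roi_radius_px,
            lost_threshold=lost_threshold,
            roi_id=i,
        )
        meta = metas[i] if metas is not None else TraceMeta(worm_id=f"roi-{i}")
        out.append(
            RawTrace(
                time_s=times,
                f_raw=track.fluorescence,
                f_background=track.background,
                meta=meta,
            )
        )
    return out
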