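"""Reading and writing the package's file formats.

Traces travel as CSV (columns time_s, F_raw, F_background) with a YAML
sidecar carrying the recording metadata; protocols and classifier
thresholds are YAML; chemotaxis plates are CSV; image stacks are
multi-page 16-bit TIFF with a ground-truth centroid CSV.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import tifffile
import yaml

from .chemo import PlateRecord
from .responses import ClassifierThresholds
from .stacks import ImageStack
from .traces import OrientationRecord, RawTrace, StimulusProtocol, TraceMeta

__all__ = [
    "write_trace_csv",
    "read_trace_csv",
    "write_protocol_yaml",
    "read_protocol_yaml",
    "read_thresholds_yaml",
    "write_plates_csv",
    "read_plates_csv",
    "write_stack_tiff",
    "read_stack_tiff",
]

TRACE_COLUMNS = ("time_s", "F_raw", "F_background")


def write_trace_csv(trace: RawTrace, path: str | Path) -> None:
    """Write a trace CSV plus its ``<stem>.meta.yaml`` sidecar."""
    path = Path(path)
    pd.DataFrame(
        {"time_s": trace.time_s, "F_raw": trace.f_raw, "F_background": trace.f_background}
    ).to_csv(path, index=False)
    meta = trace.meta
    record = {
        "neuron": meta.neuron,
        "genotype": meta.genotype,
        "stimulus": meta.stimulus,
        "conc_mM": meta.conc_mM,
        "worm_id": meta.worm_id,
    }
    if meta.orientation is not None:
        record.update(asdict(meta.orientation))
    path.with_suffix(".meta.yaml").write_text(yaml.safe_dump(record, sort_keys=False))


def read_trace_csv(path: str | Path) -> RawTrace:
    """Read a trace CSV, picking up the YAML sidecar when present."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    meta = TraceMeta()
    sidecar = path.with_suffix(".meta.yaml")
    if sidecar.exists():
        rec = yaml.safe_load(sidecar.read_text()) or {}
        orientation = None
        if all(k in rec for k in ("nose_direction", "ventral_side", "focal_neuron")):
            orientation = OrientationRecord(
                rec["nose_direction"], rec["ventral_side"], rec["focal_neuron"]
            )
        meta = TraceMeta(
            neuron=rec.get("neuron", "ASEL"),
            genotype=rec.get("genotype", "wildtype"),
            stimulus=rec.get("stimulus", "NH4Cl"),
            conc_mM=float(rec.get("conc_mM", 250.0)),
            worm_id=rec.get("worm_id", path.stem),
            orientation=orientation,
        )
    return RawTrace(
        time_s=df["time_s"].to_numpy(),
        f_raw=df["F_raw"].to_numpy(),
        f_background=df["F_background"].to_numpy(),
        meta=meta,
    )


def write_protocol_yaml(protocol: StimulusProtocol, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(protocol), sort_keys=False))


def read_protocol_yaml(path: str | Path) -> StimulusProtocol:
    rec = yaml.safe_load(Path(path).read_text()) or {}
    return StimulusProtocol(**rec)


def read_thresholds_yaml(path: str | Path) -> ClassifierThresholds:
    rec = yaml.safe_load(Path(path).read_text()) or {}
    return ClassifierThresholds(**rec)


PLATE_COLUMNS = ("plate_id", "genotype", "salt", "A", "C", "n_loaded")


def write_plates_csv(plates: Sequence[PlateRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "plate_id": p.plate_id,
                "genotype": p.genotype,
                "salt": p.salt,
                "A": p.A,
                "C": p.C,
                "n_loaded": p.n_loaded,
            }
            for p in plates
        ]
    ).to_csv(path, index=False)


def read_plates_csv(path: str | Path) -> List[PlateRecord]:
    df = pd.read_csv(path)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns and c != "n_loaded"]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    plates = []
    for _, row in df.iterrows():
        plates.append(
            PlateRecord(
                plate_id=str(row["plate_id"]),
                genotype=str(row["genotype"]),
                salt=str(row["salt"]),
                A=int(row["A"]),
                C=int(row["C"]),
                n_loaded=int(row.get("n_loaded", row["A"] + row["C"])),
            )
        )
    return plates


def write_stack_tiff(
    stack: ImageStack,
    path: str | Path,
    centroids: Optional[np.ndarray] = None,
    gain: float = 1.0,
) -> None:
    """Write a multi-page 16-bit TIFF (values scaled by ``gain``, clipped).

    If ground-truth ``centroids`` (n_frames, n_rois, 2) are given, a
    sibling ``<stem>.centroids.csv`` with columns frame, roi_id, x, y is
    written alongside.
    """
    path = Path(path)
    data = np.clip(stack.frames * gain, 0, 65535).round().astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack")
    if centroids is not None:
        rows = [
            {"frame": k, "roi_id": r, "x": centroids[k, r, 0], "y": centroids[k, r, 1]}
            for k in range(centroids.shape[0])
            for r in range(centroids.shape[1])
        ]
        pd.DataFrame(rows).to_csv(path.with_suffix(".centroids.csv"), index=False)


def read_stack_tiff(path: str | Path, frame_interval_s: float = 0.5) -> ImageStack:
    frames = tifffile.imread(Path(path))
    if frames.ndim == 2:
        frames = frames[None]
    return ImageStack(frames=frames.astype(float), frame_interval_s=frame_interval_s)
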