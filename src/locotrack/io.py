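"""TSV and TIFF interchange.

All intermediates are plain TSV so every stage can be re-run or audited
by hand; image stacks are multi-page TIFF.  Numeric columns are written at
6-decimal precision (mm and s), which round-trips losslessly at the scales
involved.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .detection import Detection
from .tracking import Track

__all__ = [
    "write_tracks",
    "read_tracks",
    "write_detections",
    "read_detections",
    "write_stack",
    "read_stack",
]

TRACK_COLUMNS = ["track_id", "frame", "time_s", "x_mm", "y_mm"]
DETECTION_COLUMNS = ["frame", "time_s", "x_mm", "y_mm", "area_px"]


class FormatError(ValueError):
    """A file does not match the expected TSV schema."""


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")


def write_tracks(tracks: list[Track], path: str | Path) -> None:
    rows = []
    for t in tracks:
        for f, ts, x, y in zip(t.frames, t.times, t.xs, t.ys):
            row = {
                "track_id": t.track_id,
                "frame": int(f),
                "time_s": ts,
                "x_mm": x,
                "y_mm": y,
            }
            if t.genotype is not None:
                row["genotype"] = t.genotype
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_tracks(path: str | Path) -> list[Track]:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, TRACK_COLUMNS, path)
    df = df.sort_values(["track_id", "time_s"], kind="stable")
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        geno = None
        if "genotype" in grp.columns and grp["genotype"].notna().any():
            geno = str(grp["genotype"].iloc[0])
        tracks.append(
            Track(
                track_id=int(tid),
                frames=grp["frame"].to_numpy(dtype=int),
                times=grp["time_s"].to_numpy(dtype=float),
                xs=grp["x_mm"].to_numpy(dtype=float),
                ys=grp["y_mm"].to_numpy(dtype=float),
                genotype=geno,
            )
        )
    return tracks


def write_detections(
    per_frame: list[list[Detection]], path: str | Path, dt: float = 1.0
) -> None:
    rows = [
        {
            "frame": d.frame_index,
            "time_s": d.frame_index * dt,
            "x_mm": d.x,
            "y_mm": d.y,
            "area_px": d.area,
        }
        for frame in per_frame
        for d in frame
    ]
    pd.DataFrame(rows, columns=DETECTION_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )


def read_detections(path: str | Path) -> list[np.ndarray]:
    """Read a detections TSV back into per-frame (k, 2) centroid arrays,
    indexed 0..max frame (frames with no detections are empty)."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["frame", "x_mm", "y_mm"], path)
    if len(df) == 0:
        return []
    n = int(df["frame"].max()) + 1
    out = [np.empty((0, 2)) for _ in range(n)]
    for f, grp in df.groupby("frame"):
        out[int(f)] = grp[["x_mm", "y_mm"]].to_numpy(dtype=float)
    return out


def write_stack(stack: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32), photometric="minisblack")


def read_stack(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=float)
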