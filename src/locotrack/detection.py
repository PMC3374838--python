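"""Per-frame centroid detection from dark-field-style intensity images.

Animals appear as bright blobs on a dark background, so detection is a
fixed global threshold followed by connected-component labeling
(8-connectivity) and an intensity-weighted center of mass per component,
giving sub-pixel centroids.  Merged/touching animals are detected as a
single object; separating them is left to the tracker's track-termination
logic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label, regionprops

__all__ = ["Detection", "detect_centroids", "detect_stack", "detections_to_xy"]


@dataclass(frozen=True)
class Detection:
    """One detected animal centroid.  Coordinates are mm (x = column axis,
    y = row axis after pixel calibration); area is the supra-threshold
    pixel count of the component."""

    frame_index: int
    x: float
    y: float
    area: int


def detect_centroids(
    image: np.ndarray,
    threshold: float,
    min_area: int = 1,
    mm_per_px: float = 0.01,
    frame_index: int = 0,
) -> list[Detection]:
    """Detect blob centroids in a single frame.

    One :class:`Detection` per 8-connected component of pixels strictly
    above ``threshold`` with at least ``min_area`` pixels; the centroid is
    the intensity-weighted center of mass of the component.  Output is
    sorted by (y, x) so it is independent of component discovery order.
    An empty image yields an empty list.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2D")
    if np.any(image < 0):
        raise ValueError("image intensities must be nonnegative")
    mask = image > threshold
    if not mask.any():
        return []
    lbl = label(mask, connectivity=2)
    out = []
    for p in regionprops(lbl, intensity_image=image):
        if p.area < min_area:
            continue
        cy, cx = p.centroid_weighted
        out.append(
            Detection(
                frame_index=frame_index,
                x=cx * mm_per_px,
                y=cy * mm_per_px,
                area=int(p.area),
            )
        )
    out.sort(key=lambda d: (d.y, d.x))
    return out


def detect_stack(
    frames: np.ndarray | list[np.ndarray],
    threshold: float,
    min_area: int = 1,
    mm_per_px: float = 0.01,
) -> list[list[Detection]]:
    """Detect centroids in every frame of a stack.

    Frames must share a single shape; results are exactly those of
    :func:`detect_centroids` applied to each frame independently, with
    strictly increasing ``frame_index``.
    """
    shapes = {np.asarray(f).shape for f in frames}
    if len(shapes) > 1:
        raise ValueError(f"ragged frame shapes in stack: {sorted(shapes)}")
    return [
        detect_centroids(f, threshold, min_area, mm_per_px, frame_index=i)
        for i, f in enumerate(frames)
    ]


def detections_to_xy(dets: list[Detection]) -> np.ndarray:
    """Stack a frame's detections into an (k, 2) array of (x, y) mm."""
    if not dets:
        return np.empty((0, 2))
    return np.array([[d.x, d.y] for d in dets])
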