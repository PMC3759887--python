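"""Nucleus detection on the DAPI channel and area measurement in points.

Segmentation is an Otsu threshold on the DAPI maximum-intensity
projection, hole filling, and a minimum-size prefilter at the debris
gate. Touching nuclei are *not* split by watershed: merged objects are
rejected downstream by the pericentrin count and the >250-point area
gate, which is the scoring strategy this pipeline implements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import regionprops, label

from .config import CaptureSettings
from .io import ZStackField


@dataclass
class NucleusRecord:
    """One segmented nucleus measured on the DAPI projection."""

    nucleus_id: str
    mask: np.ndarray            # boolean, full-field shape
    area_points: float
    centroid: tuple[float, float]   # (x, y), 0-based pixel-centered
    dapi_mean: float
    boundary_touching: bool
    label: int = 0              # label-image id, for spot assignment


def area_in_points(area_px: int, points_scale: float) -> float:
    """Convert a pixel area to the scoring system's linear 'points' unit."""
    if area_px <= 0:
        raise ValueError(f"area_px must be positive, got {area_px}")
    if points_scale <= 0:
        raise ValueError(f"points_scale must be positive, got {points_scale}")
    return float(area_px) * float(points_scale)


def segment_nuclei(field: ZStackField, settings: CaptureSettings,
                   *, smooth_sigma: float = 2.0
                   ) -> tuple[list[NucleusRecord], np.ndarray]:
    """Segment nuclei from the DAPI max projection.

    Returns the records plus the integer label image used for spot
    assignment. Border-touching regions are flagged, not removed, so
    callers can exclude them from scoring while keeping the tally.
    An all-zero DAPI channel yields an empty result.
    """
    if field.pixels.shape[1] != settings.z_planes:
        raise ValueError(
            f"field has {field.pixels.shape[1]} z-planes, settings expect {settings.z_planes}")
    proj = field.max_projection("DAPI").astype(np.float32)
    labels = np.zeros(proj.shape, dtype=np.int32)
    if proj.max() <= 0:
        return [], labels
    smoothed = ndimage.gaussian_filter(proj, smooth_sigma)
    try:
        thr = threshold_otsu(smoothed)
    except ValueError:      # constant image
        return [], labels
    fg = smoothed > thr
    if not fg.any() or fg.all():
        return [], labels
    fg = ndimage.binary_fill_holes(fg)
    labels = label(fg, connectivity=2).astype(np.int32)

    min_px = settings.min_area_points / settings.points_scale
    records: list[NucleusRecord] = []
    h, w = proj.shape
    keep = np.zeros(labels.max() + 1, dtype=bool)
    for rp in regionprops(labels, intensity_image=proj):
        if rp.area < min_px:
            continue
        keep[rp.label] = True
        (y0, x0, y1, x1) = rp.bbox
        touching = y0 == 0 or x0 == 0 or y1 == h or x1 == w
        mask = labels == rp.label
        cy, cx = rp.centroid
        records.append(NucleusRecord(
            nucleus_id=f"{field.field_id}_n{rp.label:04d}",
            mask=mask,
            area_points=area_in_points(int(rp.area), settings.points_scale),
            centroid=(float(cx), float(cy)),
            dapi_mean=float(rp.intensity_mean),
            boundary_touching=touching,
            label=int(rp.label),
        ))
    labels[~keep[labels]] = 0
    return records, labels
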