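"""Focus and pericentrin spot detection across z-planes.

Detection is a band-pass (difference-of-Gaussians) seed check plus a
threshold-connected footprint, run per plane and merged across adjacent
planes. Two foci whose footprints touch at the detection threshold are
returned as ONE spot — the overlap behavior responsible for count
saturation at high dose is deliberately preserved, not corrected.
Thresholds are fixed per run, mirroring constant exposure settings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.segmentation import expand_labels

from .config import CaptureSettings
from .io import ZStackField


@dataclass
class FocusRecord:
    """One detected spot, possibly spanning several z-planes."""

    focus_id: str
    channel: str                    # "gH2AX" or "pericentrin"
    nucleus_id: str
    centroid: tuple[float, float, float]    # x, y in px; z in plane index
    diameter_px: float
    intensity_min: float
    intensity_max: float
    integrated_intensity: float

    def __post_init__(self) -> None:
        if self.intensity_min > self.intensity_max:
            raise ValueError("intensity_min must not exceed intensity_max")


@dataclass
class _PlaneSpot:
    plane: int
    x: float
    y: float
    diameter: float
    vmin: float
    vmax: float
    integrated: float


def _detect_plane(plane_raw: np.ndarray, threshold: float, settings: CaptureSettings
                  ) -> list[_PlaneSpot]:
    img = plane_raw.astype(np.float32)
    bg = float(np.median(img[::4, ::4]))    # strided subsample: same estimate, 16x cheaper
    f = img - bg
    mask = f > threshold
    if not mask.any():
        return []
    s1 = max(1.0, settings.reference_diameter_px / 3.0)
    dog = ndimage.gaussian_filter(f, s1) - ndimage.gaussian_filter(f, 2.0 * s1)
    labels, n = ndimage.label(mask)
    if n == 0:
        return []
    seeds = peak_local_max(dog, min_distance=1, threshold_abs=0.1 * threshold,
                           exclude_border=False)
    seeded = np.zeros(n + 1, dtype=bool)
    if seeds.size:
        seeded[labels[seeds[:, 0], seeds[:, 1]]] = True
    seeded[0] = False

    out: list[_PlaneSpot] = []
    objs = ndimage.find_objects(labels)
    for lab in range(1, n + 1):
        if not seeded[lab]:
            continue
        sl = objs[lab - 1]
        sub = labels[sl] == lab
        area = int(sub.sum())
        if area < settings.min_spot_px:
            continue
        fv = f[sl][sub]
        rawv = img[sl][sub]
        yy, xx = np.nonzero(sub)
        w = np.clip(fv, 1e-6, None)
        cy = float((yy * w).sum() / w.sum()) + sl[0].start
        cx = float((xx * w).sum() / w.sum()) + sl[1].start
        out.append(_PlaneSpot(
            plane=0, x=cx, y=cy,
            diameter=float(2.0 * np.sqrt(area / np.pi)),
            vmin=float(rawv.min()), vmax=float(rawv.max()),
            integrated=float(fv.sum()),
        ))
    return out


def _merge_planes(per_plane: list[list[_PlaneSpot]], merge_radius: float
                  ) -> list[list[_PlaneSpot]]:
    """Union spots in adjacent planes whose xy-centroids fall within the radius."""
    flat: list[_PlaneSpot] = []
    for z, spots in enumerate(per_plane):
        for s in spots:
            s.plane = z
            flat.append(s)
    parent = list(range(len(flat)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    by_plane: dict[int, list[int]] = {}
    for i, s in enumerate(flat):
        by_plane.setdefault(s.plane, []).append(i)
    for z in sorted(by_plane):
        for i in by_plane.get(z, []):
            for j in by_plane.get(z + 1, []):
                si, sj = flat[i], flat[j]
                # footprints merged in one plane sit off-center from their
                # per-plane fragments, so the link radius tracks spot size
                r = max(merge_radius, 0.5 * max(si.diameter, sj.diameter))
                if (si.x - sj.x) ** 2 + (si.y - sj.y) ** 2 <= r * r:
                    parent[find(i)] = find(j)
    groups: dict[int, list[_PlaneSpot]] = {}
    for i, s in enumerate(flat):
        groups.setdefault(find(i), []).append(s)
    return list(groups.values())


def detect_spots(field: ZStackField, nuclei, channel: str,
                 settings: CaptureSettings,
                 labels: np.ndarray | None = None) -> list[FocusRecord]:
    """Detect spots in one channel and assign each to a nucleus.

    Pericentrin spots are assigned after dilating nucleus masks by
    ``pericentrin_dilation_px`` (the centrosome sits at the nuclear
    periphery, frequently only overlapping the nuclear area). Spots whose
    centroid lands in no nucleus are discarded.
    """
    if channel not in ("gH2AX", "pericentrin"):
        raise ValueError(f"unknown spot channel {channel!r}")
    threshold = (settings.gH2AX_threshold if channel == "gH2AX"
                 else settings.pericentrin_threshold)
    stack = field.channel(channel)
    per_plane = [_detect_plane(stack[z], threshold, settings)
                 for z in range(stack.shape[0])]
    groups = _merge_planes(per_plane, settings.effective_merge_radius_px)

    if labels is None:
        labels = np.zeros(field.shape_yx, dtype=np.int32)
        for rec in nuclei:
            labels[rec.mask] = rec.label
    assign = labels
    if channel == "pericentrin" and settings.pericentrin_dilation_px > 0:
        assign = expand_labels(labels, distance=settings.pericentrin_dilation_px)
    by_label = {rec.label: rec for rec in nuclei}

    h, w = labels.shape
    out: list[FocusRecord] = []
    for k, grp in enumerate(groups):
        wt = np.array([max(s.integrated, 1e-9) for s in grp])
        x = float(np.dot(wt, [s.x for s in grp]) / wt.sum())
        y = float(np.dot(wt, [s.y for s in grp]) / wt.sum())
        z = float(np.dot(wt, [s.plane for s in grp]) / wt.sum())
        iy, ix = min(max(int(round(y)), 0), h - 1), min(max(int(round(x)), 0), w - 1)
        lab = int(assign[iy, ix])
        rec = by_label.get(lab)
        if rec is None:
            continue
        out.append(FocusRecord(
            focus_id=f"{field.field_id}_{channel}_s{k:05d}",
            channel=channel,
            nucleus_id=rec.nucleus_id,
            centroid=(x, y, z),
            diameter_px=max(s.diameter for s in grp),
            intensity_min=min(s.vmin for s in grp),
            intensity_max=max(s.vmax for s in grp),
            integrated_intensity=float(sum(s.integrated for s in grp)),
        ))
    out.sort(key=lambda r: (r.nucleus_id, r.centroid[0], r.centroid[1]))
    return out


def max_diameter_filter(spot: FocusRecord, settings: CaptureSettings,
                        reference_diameter_px: float) -> bool:
    """Accept a spot iff its diameter is within the percent-of-reference cap.

    The boundary is inclusive: a spot exactly at the cap is accepted.
    """
    if reference_diameter_px <= 0:
        raise ValueError("reference_diameter_px must be positive")
    return spot.diameter_px <= reference_diameter_px * settings.spot_diameter_pct / 100.0


def brightest_focus_intensity(nucleus_foci) -> float:
    """Peak intensity of the brightest focus of a cell; 0 with no foci."""
    if not nucleus_foci:
        return 0.0
    return float(max(f.intensity_max for f in nucleus_foci))
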