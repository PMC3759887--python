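"""Cell-cycle/area gating, pattern flags and per-cell validity.

A cell enters scoring ("valid") only when it carries 1 or 2 pericentrin
signals, its nuclear area falls in the G1 or G2 gate, and its
gamma-H2AX staining is discrete foci rather than a pan-nuclear S/M
pattern. Zero pericentrin means the marker was not captured; three or
more means presumed touching nuclei; both invalidate the cell rather
than contributing a possibly wrong focus count. Valid cells get a class
group, the (pericentrin count, capped foci count) pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .config import AreaGates, CaptureSettings
from .nuclei import NucleusRecord
from .spots import FocusRecord, brightest_focus_intensity

AREA_CLASSES = ("debris", "G1", "G2", "overlap_or_polyploid")
PHASE_FLAGS = ("interphase_foci", "S_pattern", "M_pattern")

#: Exhaustive class-group ids over valid cells: {1,2} pericentrin x {0..10} foci.
#: (The source protocol quotes "20 class groups" for the same criteria; the
#: cross product is 22 and is kept complete here.)
CLASS_GROUPS = tuple((p, f) for p in (1, 2) for f in range(11))


@dataclass
class CellClassification:
    """Scoring decision for one nucleus."""

    nucleus_id: str
    area_points: float
    pericentrin_count: int
    foci_count_raw: int
    foci_count: int                 # capped at max_foci_class
    area_class: str
    phase_flag: str
    valid: bool
    class_group: tuple[int, int] | None
    brightest_focus_intensity: float = 0.0
    pericentrin_integrated_intensity: float = 0.0


def classify_area(area_points: float, gates: AreaGates) -> str:
    """Total, deterministic partition of (0, inf) into the four area classes.

    Boundaries: the G1/G2 gate value itself belongs to G2 (G2-marker
    positives were observed down to exactly that area), and the upper G2
    gate is inclusive; the debris gate value belongs to G1.
    """
    if not area_points > 0:
        raise ValueError(f"area must be positive, got {area_points!r}")
    if area_points < gates.debris_max_points:
        return "debris"
    if area_points < gates.g1_max_points:
        return "G1"
    if area_points <= gates.g2_max_points:
        return "G2"
    return "overlap_or_polyploid"


def pan_nuclear_flag(nucleus: NucleusRecord, gH2AX_projection: np.ndarray,
                     settings: CaptureSettings,
                     pericentrin_count: int | None = None,
                     background: float | None = None) -> str:
    """Classify the gamma-H2AX staining pattern of one nucleus.

    Works on the background-subtracted max projection: ``coverage`` is
    the supra-threshold fraction of nuclear pixels and ``cv`` the
    coefficient of variation of the supra-threshold signal. High coverage
    with low CV (uniform bright staining, or high coverage with two
    pericentrin spots) reads as M; high coverage with high CV (rough,
    granular) as S; anything else is interphase with discrete foci.
    """
    mask = nucleus.mask
    if not mask.any():
        raise ValueError(f"nucleus {nucleus.nucleus_id} has an empty mask")
    vals = gH2AX_projection[mask].astype(np.float64)
    bg = float(np.median(gH2AX_projection)) if background is None else float(background)
    vals = vals - bg
    supra = vals > settings.gH2AX_threshold
    coverage = float(supra.mean())
    if coverage <= settings.s_coverage_min:
        return "interphase_foci"
    sv = vals[supra]
    cv = float(sv.std() / sv.mean()) if sv.mean() > 0 else 0.0
    if coverage > settings.m_coverage_min and (cv < settings.cv_cut or pericentrin_count == 2):
        return "M_pattern"
    if cv >= settings.cv_cut:
        return "S_pattern"
    return "interphase_foci"


def classify_cell(nucleus: NucleusRecord, foci: Sequence[FocusRecord],
                  pericentrin: Sequence[FocusRecord], gates: AreaGates,
                  settings: CaptureSettings,
                  gH2AX_projection: np.ndarray | None = None,
                  projection_background: float | None = None) -> CellClassification:
    """Combine area gate, pericentrin count and pattern flag into one decision."""
    for rec in list(foci) + list(pericentrin):
        if rec.nucleus_id != nucleus.nucleus_id:
            raise ValueError(
                f"spot {rec.focus_id} belongs to {rec.nucleus_id}, not {nucleus.nucleus_id}")
    pc = len(pericentrin)
    area_class = classify_area(nucleus.area_points, gates)
    if gH2AX_projection is not None:
        flag = pan_nuclear_flag(nucleus, gH2AX_projection, settings,
                                pericentrin_count=pc, background=projection_background)
    else:
        flag = "interphase_foci"
    raw = len(foci)
    capped = min(raw, settings.max_foci_class)
    valid = (pc in (1, 2) and area_class in ("G1", "G2")
             and flag == "interphase_foci" and not nucleus.boundary_touching)
    group = (pc, capped) if valid else None
    return CellClassification(
        nucleus_id=nucleus.nucleus_id,
        area_points=nucleus.area_points,
        pericentrin_count=pc,
        foci_count_raw=raw,
        foci_count=capped,
        area_class=area_class,
        phase_flag=flag,
        valid=valid,
        class_group=group,
        brightest_focus_intensity=brightest_focus_intensity(list(foci)),
        pericentrin_integrated_intensity=float(sum(p.integrated_intensity
                                                   for p in pericentrin)),
    )


@dataclass(frozen=True)
class GateCalibration:
    gates: AreaGates
    mean_labelled_area: float
    n_labelled: int


def calibrate_area_gates(labelled_g2_areas: Sequence[float],
                         debris_max: float = 50.0) -> GateCalibration:
    """Derive area gates from a G2-marker-labelled population.

    Reproduces the calibration procedure: the observed range of
    G2-labelled nuclear areas becomes the G1/G2 gate (its minimum) and
    the rejection gate (its maximum); the mean labelled area is reported
    alongside.
    """
    areas = np.asarray(list(labelled_g2_areas), dtype=float)
    if areas.size < 2:
        raise ValueError("at least two labelled G2 areas are required")
    if not (areas > 0).all():
        raise ValueError("labelled areas must be positive")
    lo, hi = float(areas.min()), float(areas.max())
    if lo == hi:
        raise ValueError("degenerate labelled population: zero area range")
    gates = AreaGates(debris_max_points=debris_max, g1_max_points=lo, g2_max_points=hi)
    return GateCalibration(gates=gates, mean_labelled_area=float(areas.mean()),
                           n_labelled=int(areas.size))
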