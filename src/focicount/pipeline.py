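"""End-to-end scoring: segment -> detect -> classify -> summarize."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .classify import CellClassification, classify_cell
from .config import AreaGates, CaptureSettings
from .io import ZStackField
from .nuclei import segment_nuclei, NucleusRecord
from .spots import FocusRecord, detect_spots, max_diameter_filter
from .stats import SampleResult, summarize_sample


def score_field(field: ZStackField, settings: CaptureSettings, gates: AreaGates
                ) -> tuple[list[NucleusRecord], list[CellClassification],
                           list[FocusRecord]]:
    """Score one field; border-touching nuclei are excluded from scoring."""
    nuclei, labels = segment_nuclei(field, settings)
    scored = [n for n in nuclei if not n.boundary_touching]
    foci = detect_spots(field, scored, "gH2AX", settings, labels=labels)
    peri = detect_spots(field, scored, "pericentrin", settings, labels=labels)
    foci = [f for f in foci
            if max_diameter_filter(f, settings, settings.reference_diameter_px)]
    peri = [p for p in peri
            if max_diameter_filter(p, settings, settings.reference_diameter_px)]
    by_nucleus_f: dict[str, list[FocusRecord]] = {}
    by_nucleus_p: dict[str, list[FocusRecord]] = {}
    for f in foci:
        by_nucleus_f.setdefault(f.nucleus_id, []).append(f)
    for p in peri:
        by_nucleus_p.setdefault(p.nucleus_id, []).append(p)
    proj = field.max_projection("gH2AX").astype(np.float32)
    proj_bg = float(np.median(proj[::4, ::4]))
    cells = [
        classify_cell(n, by_nucleus_f.get(n.nucleus_id, []),
                      by_nucleus_p.get(n.nucleus_id, []), gates, settings,
                      gH2AX_projection=proj, projection_background=proj_bg)
        for n in scored
    ]
    return nuclei, cells, foci + peri


def score_sample(fields: Sequence[ZStackField], settings: CaptureSettings,
                 gates: AreaGates, *, sample_id: str = "sample",
                 dose_Gy: float = 0.0, minimum_nuclei: int = 1000,
                 stratify: bool = True
                 ) -> tuple[list[CellClassification], SampleResult]:
    """Score every field of a sample and summarize."""
    cells: list[CellClassification] = []
    for f in fields:
        _, cc, _ = score_field(f, settings, gates)
        cells.extend(cc)
    result = summarize_sample(cells, sample_id=sample_id, dose_Gy=dose_Gy,
                              stratify=stratify, minimum_nuclei=minimum_nuclei)
    return cells, result


def cells_to_frame(cells: Sequence[CellClassification]) -> pd.DataFrame:
    """Per-cell classification table (the per-cell CSV schema)."""
    rows = []
    for c in cells:
        rows.append({
            "nucleus_id": c.nucleus_id,
            "area_points": c.area_points,
            "area_class": c.area_class,
            "pericentrin_count": c.pericentrin_count,
            "foci_count_raw": c.foci_count_raw,
            "foci_count": c.foci_count,
            "phase_flag": c.phase_flag,
            "valid": c.valid,
            "class_group": "" if c.class_group is None
                           else f"{c.class_group[0]}-{c.class_group[1]}",
            "brightest_focus_intensity": c.brightest_focus_intensity,
            "pericentrin_integrated_intensity": c.pericentrin_integrated_intensity,
        })
    return pd.DataFrame(rows, columns=[
        "nucleus_id", "area_points", "area_class", "pericentrin_count",
        "foci_count_raw", "foci_count", "phase_flag", "valid", "class_group",
        "brightest_focus_intensity", "pericentrin_integrated_intensity"])


def spots_to_frame(records: Sequence[FocusRecord]) -> pd.DataFrame:
    """Per-spot export table."""
    rows = [{
        "focus_id": r.focus_id, "nucleus_id": r.nucleus_id, "channel": r.channel,
        "x": r.centroid[0], "y": r.centroid[1], "z": r.centroid[2],
        "diameter_px": r.diameter_px, "intensity_min": r.intensity_min,
        "intensity_max": r.intensity_max,
        "integrated_intensity": r.integrated_intensity,
    } for r in records]
    return pd.DataFrame(rows, columns=[
        "focus_id", "nucleus_id", "channel", "x", "y", "z", "diameter_px",
        "intensity_min", "intensity_max", "integrated_intensity"])


def result_to_dict(result: SampleResult) -> dict:
    """JSON-serializable view of a sample result."""
    return {
        "sample_id": result.sample_id,
        "dose_Gy": result.dose_Gy,
        "n_valid_cells": result.n_valid_cells,
        "mean_foci": result.mean_foci,
        "se_foci": result.se_foci,
        "foci_histogram": [int(v) for v in result.foci_histogram],
        "mean_brightest_intensity": result.mean_brightest_intensity,
        "per_area_class": {
            k: {
                "n_cells": s.n_cells,
                "mean_foci": s.mean_foci,
                "se_foci": s.se_foci,
                "foci_histogram": [int(v) for v in s.foci_histogram],
                "mean_brightest_intensity": s.mean_brightest_intensity,
            } for k, s in result.per_area_class_results.items()
        },
        "qc": result.qc,
    }
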