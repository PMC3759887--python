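"""Sample-level summaries and dose-response statistics.

Covers the analyses run on scored cells: per-sample focus-count
distributions (optionally stratified by the G1/G2 area gates),
Mann-Whitney dose comparisons, the linear fit of brightest-focus
intensity on dose, the Spearman correlation of pericentrin intensity
with nuclear area, scoring repeatability, and the regression of
automatic on manual focus means. No multiple-testing correction is
applied; p-values are reported unadjusted.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .classify import CellClassification

_EXACT_MAX_N = 8    # exact Mann-Whitney enumeration up to this group size


class QCError(RuntimeError):
    """Raised when a sample fails quality control (e.g. no valid cells)."""


@dataclass
class StratumSummary:
    n_cells: int
    mean_foci: float
    se_foci: float
    foci_histogram: np.ndarray
    mean_brightest_intensity: float


@dataclass
class SampleResult:
    """Aggregate scoring result for one sample (one dose / time point)."""

    sample_id: str
    dose_Gy: float
    n_valid_cells: int
    mean_foci: float
    se_foci: float                      # cell-level SE: sd / sqrt(n)
    foci_histogram: np.ndarray          # counts indexed 0..max class
    mean_brightest_intensity: float
    per_area_class_results: dict[str, StratumSummary] = field(default_factory=dict)
    qc: dict = field(default_factory=dict)


def _summary(cells: Sequence[CellClassification], max_class: int) -> StratumSummary:
    counts = np.array([c.foci_count for c in cells], dtype=float)
    hist = np.bincount(counts.astype(int), minlength=max_class + 1)[: max_class + 1]
    bright = np.array([c.brightest_focus_intensity for c in cells
                       if c.foci_count_raw > 0], dtype=float)
    n = counts.size
    return StratumSummary(
        n_cells=int(n),
        mean_foci=float(counts.mean()) if n else float("nan"),
        se_foci=float(counts.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0,
        foci_histogram=hist,
        mean_brightest_intensity=float(bright.mean()) if bright.size else 0.0,
    )


def summarize_sample(cells: Sequence[CellClassification], *,
                     sample_id: str = "sample", dose_Gy: float = 0.0,
                     stratify: bool = True, minimum_nuclei: int = 1000) -> SampleResult:
    """Mean/SE and histogram of capped foci counts over valid cells.

    The brightest-focus mean is taken over valid cells with at least one
    detected focus (a cell without foci has no brightest focus).
    Raises :class:`QCError` with a tally when no cell is valid.
    """
    cells = list(cells)
    valid = [c for c in cells if c.valid]
    qc = {
        "n_total": len(cells),
        "n_valid": len(valid),
        "n_boundary_or_invalid_pericentrin": sum(
            1 for c in cells if c.pericentrin_count not in (1, 2)),
        "n_area_rejected": sum(
            1 for c in cells if c.area_class in ("debris", "overlap_or_polyploid")),
        "n_pattern_flagged": sum(
            1 for c in cells if c.phase_flag != "interphase_foci"),
        "meets_minimum_nuclei": len(valid) >= minimum_nuclei,
    }
    if not valid:
        raise QCError(f"no valid cells in sample {sample_id!r}: {qc}")
    max_class = max(10, max(c.foci_count for c in valid))
    overall = _summary(valid, max_class)
    strata: dict[str, StratumSummary] = {}
    if stratify:
        for cls in ("G1", "G2"):
            sub = [c for c in valid if c.area_class == cls]
            if sub:
                strata[cls] = _summary(sub, max_class)
    return SampleResult(
        sample_id=sample_id, dose_Gy=float(dose_Gy),
        n_valid_cells=overall.n_cells, mean_foci=overall.mean_foci,
        se_foci=overall.se_foci, foci_histogram=overall.foci_histogram,
        mean_brightest_intensity=overall.mean_brightest_intensity,
        per_area_class_results=strata, qc=qc,
    )


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled, method="average")


def _u_from_ranks(ranks: np.ndarray, idx_a: np.ndarray, n1: int, n2: int) -> float:
    r1 = ranks[idx_a].sum()
    return r1 - n1 * (n1 + 1) / 2.0


def compare_doses(a: Sequence[float] | Sequence[CellClassification],
                  b: Sequence[float] | Sequence[CellClassification]
                  ) -> tuple[float, float]:
    """Two-sided Mann-Whitney U on per-cell focus counts; midranks for ties.

    Exact p by full enumeration of group assignments when both groups
    have at most 8 observations; the normal approximation with tie
    correction otherwise. Returns (U of the first group, p-value).
    """
    xa = _foci_values(a)
    xb = _foci_values(b)
    if xa.size == 0 or xb.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = xa.size, xb.size
    if max(n1, n2) <= _EXACT_MAX_N:
        pooled = np.concatenate([xa, xb])
        ranks = _midranks(pooled)
        n = n1 + n2
        u_obs = _u_from_ranks(ranks, np.arange(n1), n1, n2)
        le = ge = total = 0
        for comb in itertools.combinations(range(n), n1):
            u = _u_from_ranks(ranks, np.array(comb), n1, n2)
            total += 1
            le += u <= u_obs + 1e-9
            ge += u >= u_obs - 1e-9
        # two-sided: double the smaller tail, capped at 1
        return float(u_obs), min(1.0, 2.0 * min(le, ge) / total)
    res = sps.mannwhitneyu(xa, xb, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def _foci_values(group) -> np.ndarray:
    vals = []
    for c in group:
        if isinstance(c, CellClassification):
            if c.valid:
                vals.append(c.foci_count)
        else:
            vals.append(float(c))
    return np.asarray(vals, dtype=float)


def intensity_dose_fit(samples: Sequence[SampleResult]
                       ) -> tuple[float, float, float]:
    """OLS of per-sample mean brightest-focus intensity on dose.

    Returns (slope, intercept, r_squared). Requires >= 3 dose points.
    """
    if len(samples) < 3:
        raise ValueError("at least 3 dose points are required for the fit")
    x = np.array([s.dose_Gy for s in samples], dtype=float)
    y = np.array([s.mean_brightest_intensity for s in samples], dtype=float)
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)


def pericentrin_area_correlation(cells: Sequence[CellClassification]
                                 ) -> tuple[float, float]:
    """Spearman correlation of pericentrin integrated intensity vs area.

    Restricted to cells with exactly one pericentrin signal, as in the
    calibration analysis; requires at least 10 such cells.
    """
    sub = [c for c in cells if c.pericentrin_count == 1
           and c.pericentrin_integrated_intensity > 0]
    if len(sub) < 10:
        raise ValueError(
            f"need >= 10 single-pericentrin cells, got {len(sub)}")
    area = np.array([c.area_points for c in sub])
    inten = np.array([c.pericentrin_integrated_intensity for c in sub])
    r, p = sps.spearmanr(area, inten)
    return float(r), float(p)


def repeatability(run1: SampleResult, run2: SampleResult) -> float:
    """Absolute difference of mean foci/cell between two scoring rounds."""
    return abs(run1.mean_foci - run2.mean_foci)


def manual_agreement(pairs: Sequence[tuple[float, float]]
                     ) -> tuple[float, float, float]:
    """OLS of automatic (stratified) sample means on manual means.

    Returns (slope, intercept, r_squared). Requires >= 3 pairs.
    """
    if len(pairs) < 3:
        raise ValueError("at least 3 paired sample means are required")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)
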