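"""Configuration objects for capture, gating and simulation.

Defaults encode the capture protocol the pipeline emulates: four z-planes
2.1 µm apart, a maximum-spot-diameter acceptance of 280% of the reference
focus size, nuclear area expressed in "points" (a linear rescaling of pixel
area), and cell-class gates at 50/130/250 points.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, asdict, fields
from typing import Sequence

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value is out of its valid domain."""


@dataclass(frozen=True)
class CaptureSettings:
    """Detection and measurement settings held fixed across a whole run.

    Thresholds are intensities *above local background*; per-channel
    thresholds are constant per run (the acquisition contract is constant
    exposure and camera settings), never auto-adapted per field.
    """

    spot_diameter_pct: float = 280.0        # max accepted spot diameter, % of reference
    z_planes: int = 4
    z_step_um: float = 2.1
    gH2AX_threshold: float = 250.0          # footprint threshold, counts above background
    pericentrin_threshold: float = 150.0
    pericentrin_dilation_px: int = 6        # pericentrin is cytoplasm-adjacent
    points_scale: float = 0.02              # nuclear-area points per pixel
    max_foci_class: int = 10                # foci counts are capped at this class
    reference_diameter_px: float = 6.0      # nominal focus diameter
    merge_radius_px: float | None = None    # cross-plane merge radius; None -> reference
    min_spot_px: int = 4                    # reject sub-PSF specks
    min_area_points: float = 50.0           # debris prefilter at segmentation time
    s_coverage_min: float = 0.5             # pan-nuclear S-pattern coverage gate
    m_coverage_min: float = 0.8             # pan-nuclear M-pattern coverage gate
    cv_cut: float = 0.6                     # supra-threshold CV separating S from M

    def __post_init__(self) -> None:
        positive = (
            "spot_diameter_pct", "z_planes", "z_step_um", "gH2AX_threshold",
            "pericentrin_threshold", "points_scale", "max_foci_class",
            "reference_diameter_px", "min_area_points",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)!r}")
        if self.pericentrin_dilation_px < 0:
            raise ConfigError("pericentrin_dilation_px must be non-negative")

    @property
    def effective_merge_radius_px(self) -> float:
        return self.reference_diameter_px if self.merge_radius_px is None else self.merge_radius_px

    @property
    def max_spot_diameter_px(self) -> float:
        return self.reference_diameter_px * self.spot_diameter_pct / 100.0


@dataclass(frozen=True)
class AreaGates:
    """Nuclear-area gates (in points) separating debris / G1 / G2 / rejects.

    Boundary convention: 130 points belongs to G2 and 250 is inclusive in
    G2, because CENP-F-positive (G2) cells were observed at both extremes
    of the 130-250 range; 50 belongs to G1.
    """

    debris_max_points: float = 50.0
    g1_max_points: float = 130.0
    g2_max_points: float = 250.0

    def __post_init__(self) -> None:
        if not (0 < self.debris_max_points < self.g1_max_points < self.g2_max_points):
            raise ConfigError(
                "area gates must satisfy 0 < debris_max < g1_max < g2_max, got "
                f"{self.debris_max_points}/{self.g1_max_points}/{self.g2_max_points}"
            )


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic z-stack generator.

    The defaults emulate an exponentially growing HMEC culture imaged at
    60x: a bimodal nuclear-area distribution (G1 vs G2) inside the 50-130 /
    130-250 point gates, Poisson focus counts whose mean rises linearly
    with dose from the 1.12 foci/cell control rate, focus diameter and peak
    intensity growing with dose, 24% S-phase and 2% M-phase pattern cells,
    and 1-2 pericentrin spots whose integrated intensity is rank-coupled to
    nuclear area (Spearman 0.4942).
    """

    doses_Gy: Sequence[float] = (0.0, 0.5, 1.0)
    cells_per_dose: int = 1000
    control_mean_foci: float = 1.12
    foci_per_Gy: float = 7.26
    g2_fraction: float = 0.16               # of interphase cells
    g2_foci_multiplier: float = 2.0         # G2 background has ~double histone content
    s_fraction: float = 0.24                # BrdU-positive fraction in growing culture
    m_fraction: float = 0.02
    g2_two_pericentrin_prob: float = 0.5    # centrosome splitting in late G2
    g1_area_range_points: tuple[float, float] = (55.0, 125.0)
    g2_area_range_points: tuple[float, float] = (135.0, 248.0)
    s_area_range_points: tuple[float, float] = (90.0, 180.0)
    focus_diameter_base_px: float = 6.0
    focus_diameter_per_Gy: float = 2.0
    focus_peak_intensity_base: float = 600.0
    focus_peak_intensity_per_Gy: float = 900.0
    pericentrin_area_correlation: float = 0.4942
    pericentrin_mean_log_intensity: float = 10.6    # lognormal marginal, ln scale
    pericentrin_sd_log_intensity: float = 0.5
    pericentrin_sigma_px: float = 1.8
    noise_sd: float = 25.0
    background: float = 100.0
    dapi_amplitude: float = 2500.0
    gH2AX_nuclear_wash: float = 60.0
    z_planes: int = 4
    z_step_um: float = 2.1
    width_px: int = 1392
    height_px: int = 1040
    pixel_size_um: float = 0.1075
    points_scale: float = 0.02
    allow_focus_overlap: bool = False       # False -> enforce >2-diameter separation
    touching_fraction: float = 0.0          # fraction of nuclei placed as touching pairs
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("control_mean_foci", "focus_diameter_base_px", "points_scale",
                     "z_step_um", "pixel_size_um", "dapi_amplitude"):
            v = getattr(self, name)
            if not (v > 0 and v == v and v != float("inf")):
                raise ConfigError(f"{name} must be positive and finite, got {v!r}")
        for name in ("foci_per_Gy", "focus_diameter_per_Gy", "focus_peak_intensity_per_Gy",
                     "noise_sd", "g2_foci_multiplier"):
            v = getattr(self, name)
            if not (v >= 0 and v == v and v != float("inf")):
                raise ConfigError(f"{name} must be non-negative and finite, got {v!r}")
        if any(d < 0 or d != d for d in self.doses_Gy):
            raise ConfigError("doses_Gy must all be non-negative")
        if self.cells_per_dose < 0:
            raise ConfigError("cells_per_dose must be non-negative")
        for frac in ("g2_fraction", "s_fraction", "m_fraction",
                     "g2_two_pericentrin_prob", "touching_fraction"):
            v = getattr(self, frac)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{frac} must lie in [0, 1], got {v!r}")
        if self.s_fraction + self.m_fraction > 1.0:
            raise ConfigError("s_fraction + m_fraction must not exceed 1")
        if not -1.0 <= self.pericentrin_area_correlation <= 1.0:
            raise ConfigError("pericentrin_area_correlation must lie in [-1, 1]")
        g1, g2 = self.g1_area_range_points, self.g2_area_range_points
        if not (g1[0] < g1[1] and g2[0] < g2[1]):
            raise ConfigError("area ranges must be non-empty intervals")
        if g1[1] > g2[0]:
            raise ConfigError("G1 and G2 area ranges must not overlap")
        if self.z_planes < 1:
            raise ConfigError("z_planes must be >= 1")

    def focus_diameter_px(self, dose_Gy: float) -> float:
        return self.focus_diameter_base_px + self.focus_diameter_per_Gy * dose_Gy

    def focus_peak_intensity(self, dose_Gy: float) -> float:
        return self.focus_peak_intensity_base + self.focus_peak_intensity_per_Gy * dose_Gy

    def mean_foci(self, dose_Gy: float) -> float:
        return self.control_mean_foci + self.foci_per_Gy * dose_Gy


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def to_yaml(cfg) -> str:
    """Serialize a config dataclass to canonical YAML (sorted keys)."""
    return yaml.safe_dump(_to_plain(asdict(cfg)), sort_keys=True)


def _coerce(cls, data: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for f in fields(cls):
        if f.name in data:
            v = data[f.name]
            if isinstance(v, list):
                v = tuple(v)
            kwargs[f.name] = v
    return cls(**kwargs)


def generator_config_from_yaml(text: str) -> GeneratorConfig:
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError("generator config YAML must be a mapping")
    return _coerce(GeneratorConfig, data)


def capture_settings_from_yaml(text: str) -> CaptureSettings:
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError("capture settings YAML must be a mapping")
    return _coerce(CaptureSettings, data)


def config_hash(cfg) -> str:
    """Short provenance hash of a config's canonical YAML."""
    return hashlib.sha256(to_yaml(cfg).encode()).hexdigest()[:12]
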