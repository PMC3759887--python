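"""Shared fixtures: small synthetic samples reused across test modules."""

import pytest

from focicount.config import AreaGates, CaptureSettings, GeneratorConfig
from focicount.fixtures import generate_sample
from focicount.pipeline import score_sample


SMALL_GEOMETRY = dict(width_px=760, height_px=760)


@pytest.fixture(scope="session")
def settings() -> CaptureSettings:
    return CaptureSettings()

@pytest.fixture(scope="session")
def gates() -> AreaGates:
    return AreaGates()


def small_config(**overrides) -> GeneratorConfig:
    base = dict(doses_Gy=(0.0, 0.5, 1.0), cells_per_dose=60, seed=101,
                **SMALL_GEOMETRY)
    base.update(overrides)
    return GeneratorConfig(**base)


@pytest.fixture(scope="session")
def clean_sample(settings, gates):
    """60 interphase-only cells at 0.5 Gy, flat rate, well-separated foci."""
    cfg = small_config(s_fraction=0.0, m_fraction=0.0, g2_foci_multiplier=1.0)
    fields, truth = generate_sample(cfg, 0.5)
    cells, result = score_sample(fields, settings, gates, dose_Gy=0.5,
                                 minimum_nuclei=1, stratify=True)
    return dict(config=cfg, fields=fields, truth=truth, cells=cells, result=result)


@pytest.fixture(scope="session")
def noise_free_sample(settings, gates):
    """Noise-free fixture with disjoint nuclei for exact-count oracles."""
    cfg = small_config(noise_sd=0.0, s_fraction=0.0, m_fraction=0.0, seed=7)
    fields, truth = generate_sample(cfg, 0.5)
    cells, result = score_sample(fields, settings, gates, dose_Gy=0.5,
                                 minimum_nuclei=1, stratify=False)
    return dict(config=cfg, fields=fields, truth=truth, cells=cells, result=result)


@pytest.fixture(scope="session")
def default_mixture_sample(settings, gates):
    """Default phase mixture (S/M/G2 fractions) at 0 Gy for gating tests."""
    cfg = small_config(cells_per_dose=80, seed=19)
    fields, truth = generate_sample(cfg, 0.0)
    cells, result = score_sample(fields, settings, gates, dose_Gy=0.0,
                                 minimum_nuclei=1, stratify=True)
    return dict(config=cfg, fields=fields, truth=truth, cells=cells, result=result)
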