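"""Shared fixtures: noiseless configs, a reference calibration, simulated gels."""

import numpy as np
import pytest
from hypothesis import settings

from rnmpgel import GelSimConfig, MigrationCalibration

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture
def quiet_config() -> GelSimConfig:
    """Noiseless, baseline-free, delta-band simulator config."""
    return GelSimConfig(noise_sigma=0.0, baseline=0.0, band_sigma=0.0)


@pytest.fixture
def band_config() -> GelSimConfig:
    """Noiseless config with a realistic band point-spread."""
    return GelSimConfig(noise_sigma=0.0, baseline=0.0, band_sigma=0.5)


@pytest.fixture
def true_calibration(quiet_config: GelSimConfig) -> MigrationCalibration:
    """Calibration matching the simulator's default migration law, with the
    default ladder hull [200, 50000] nt."""
    return MigrationCalibration(
        a=quiet_config.migration_a,
        b=quiet_config.migration_b,
        size_min=200.0,
        size_max=50_000.0,
        residual_rms=0.0,
        n_points=8,
    )


@pytest.fixture
def ladder_sizes() -> list[float]:
    return [200.0, 500.0, 1000.0, 2000.0, 5000.0, 10_000.0, 20_000.0, 50_000.0]
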