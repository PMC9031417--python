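import dataclasses

import pytest

from secmscc import (
    CalibrationPoint,
    MediumConstants,
    PortGeometry,
    ScanProtocol,
    SimulationConfig,
)


@pytest.fixture
def chip_constants():
    return MediumConstants.chip()


@pytest.fixture
def cone_constants():
    return MediumConstants.cone_well()


@pytest.fixture
def chip_geometry():
    return PortGeometry.chip()


@pytest.fixture
def chip_calibration_points():
    """Milk-cell-chip calibration measurements: (cells/mL, |dI| pA)."""
    return [
        CalibrationPoint(5.5e4, 23.0),
        CalibrationPoint(5.5e5, 70.0),
        CalibrationPoint(1.1e6, 116.0),
    ]


@pytest.fixture
def noiseless_config():
    """Clinical-level sample simulated without noise or artefacts."""
    return SimulationConfig(
        cell_concentration_per_ml=1.1e6,
        noise_sd_pA=0.0,
        settling_excess=0.0,
        seed=0,
    )


@pytest.fixture
def noisy_config(noiseless_config):
    return dataclasses.replace(
        noiseless_config, noise_sd_pA=2.0, settling_excess=0.20, seed=1
    )
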