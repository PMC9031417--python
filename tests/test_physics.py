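"""Current-to-concentration conversion, the hemispherical rate equation and
its inverse, the steady-state field profile, and per-cell normalisation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from secmscc import (
    DiffusionField,
    DomainError,
    InfeasibleRateError,
    MediumConstants,
    PortGeometry,
    current_to_concentration,
    per_cell_rate,
    respiration_from_delta_i,
    respiration_rate,
    surface_concentration_from_rate,
)
from secmscc.physics import respiration_rate_cgs
from secmscc.units import um_to_cm, uM_to_mol_per_cm3


@pytest.mark.parametrize(
    "delta_i_pA, bulk_nA, expected_uM",
    [
        (105.0, -1.76, 14.795454545454547),  # cone well, high-count sample
        (20.0, -1.76, 2.8181818181818183),
        (116.0, -1.7, 16.92235294117647),  # chip samples
        (70.0, -1.7, 10.211764705882354),
        (23.0, -1.7, 3.3552941176470585),
        (0.0, -1.7, 0.0),
    ],
)
def test_concentration_conversion_is_linear_in_delta_i(delta_i_pA, bulk_nA, expected_uM):
    constants = MediumConstants(bulk_current_nA=bulk_nA)
    assert current_to_concentration(delta_i_pA, constants) == pytest.approx(expected_uM)


def test_negative_delta_i_is_rejected(chip_constants):
    with pytest.raises(DomainError):
        current_to_concentration(-1.0, chip_constants)


@pytest.mark.parametrize(
    "delta_c_uM, expected_mol_s",
    [
        (16.92235294117647, 2.3179128901113787e-14),
        (10.211764705882354, 1.3987405371361767e-14),
        (3.3552941176470585, 4.595861764876009e-15),
        (0.0, 0.0),
    ],
)
def test_respiration_rate_from_depletion(delta_c_uM, expected_mol_s,
                                         chip_geometry, chip_constants):
    f = respiration_rate(delta_c_uM, chip_geometry, chip_constants)
    assert f == pytest.approx(expected_mol_s, rel=1e-12)


def test_respiration_rate_rejects_negative_depletion(chip_geometry, chip_constants):
    with pytest.raises(DomainError):
        respiration_rate(-1.0, chip_geometry, chip_constants)


def test_rate_is_linear_in_depletion_and_radius(chip_geometry, chip_constants):
    f1 = respiration_rate(5.0, chip_geometry, chip_constants)
    assert respiration_rate(15.0, chip_geometry, chip_constants) == pytest.approx(3 * f1)
    wider = PortGeometry(equivalent_radius_um=200.0)
    assert respiration_rate(5.0, wider, chip_constants) == pytest.approx(2 * f1)


def test_unit_consistency_uM_vs_cgs(chip_geometry, chip_constants):
    """F computed from uM via the interface equals F computed in CGS."""
    dc_uM = 16.92235294117647
    f_cgs = respiration_rate_cgs(
        uM_to_mol_per_cm3(dc_uM),
        um_to_cm(chip_geometry.equivalent_radius_um),
        chip_constants.diffusion_coefficient_cm2_s,
    )
    assert respiration_rate(dc_uM, chip_geometry, chip_constants) == f_cgs


@settings(max_examples=100, derandomize=True)
@given(rate=st.floats(min_value=0.0, max_value=3.3e-13))
def test_forward_inverse_rate_round_trip(rate):
    geometry, constants = PortGeometry.chip(), MediumConstants.chip()
    field = surface_concentration_from_rate(rate, geometry, constants)
    back = respiration_rate(field.delta_C_uM, geometry, constants)
    assert back == pytest.approx(rate, rel=1e-12, abs=1e-30)


def test_inverse_example_matches_arithmetic(chip_geometry, chip_constants):
    field = surface_concentration_from_rate(2.3e-14, chip_geometry, chip_constants)
    assert field.delta_C_uM == pytest.approx(16.79, abs=0.01)


def test_unsupportable_rate_raises(chip_geometry, chip_constants):
    # demands more oxygen than bulk saturation can deliver
    with pytest.raises(InfeasibleRateError):
        surface_concentration_from_rate(1e-12, chip_geometry, chip_constants)


class TestFieldProfile:
    def field(self, delta_c=17.0):
        return DiffusionField(MediumConstants.chip(), PortGeometry.chip(), delta_c)

    def test_surface_boundary_condition(self):
        assert self.field().concentration_at(0.0) == pytest.approx(248.0 - 17.0)

    def test_depletion_halves_at_one_radius(self):
        # R = 2 r_s at r = r_s halves the depletion
        assert self.field().concentration_at(100.0) == pytest.approx(248.0 - 8.5)

    def test_far_field_limit(self):
        assert self.field().concentration_at(1e6) == pytest.approx(248.0, abs=0.01)
        # within 1% of bulk at 100 port radii
        assert self.field().concentration_at(100 * 100.0) >= 0.99 * 248.0

    def test_profile_is_monotone_nondecreasing(self):
        r = np.linspace(0.0, 5000.0, 400)
        c = self.field().concentration_at(r)
        assert np.all(np.diff(c) >= 0)

    def test_negative_distance_rejected(self):
        with pytest.raises(DomainError):
            self.field().concentration_at(-1.0)

    def test_field_requires_physical_depletion(self):
        constants = MediumConstants.chip()
        with pytest.raises(DomainError):
            DiffusionField(constants, PortGeometry.chip(), -1.0)
        with pytest.raises(DomainError):
            DiffusionField(constants, PortGeometry.chip(), constants.bulk_oxygen_uM + 1)
        field = DiffusionField(constants, PortGeometry.chip(), 17.0)
        assert field.surface_concentration_uM == constants.bulk_oxygen_uM - 17.0


class TestPerCellRate:
    def test_chip_sample_order_of_magnitude(self, chip_geometry):
        # 1.1e6 cells/mL in a 1.5 uL well at 1:9 dilution -> 165 cells
        rate = per_cell_rate(2.3179128901113787e-14, 1.1e6, chip_geometry)
        assert rate == pytest.approx(1.4047956909765933e-16, rel=1e-12)
        assert math.floor(math.log10(rate)) == -16

    def test_zero_total_rate(self, chip_geometry):
        assert per_cell_rate(0.0, 1e6, chip_geometry) == 0.0

    def test_doubling_volume_halves_per_cell_rate(self, chip_geometry):
        doubled = PortGeometry(well_volume_uL=2 * chip_geometry.well_volume_uL)
        assert per_cell_rate(1e-14, 1e6, doubled) == pytest.approx(
            per_cell_rate(1e-14, 1e6, chip_geometry) / 2
        )

    def test_zero_cells_raises_with_message(self, chip_geometry):
        with pytest.raises(DomainError, match="cell_concentration"):
            per_cell_rate(1e-14, 0.0, chip_geometry)


def test_full_chain_from_delta_i(chip_geometry, chip_constants):
    res = respiration_from_delta_i(116.0, chip_geometry, chip_constants, 1.1e6)
    assert res.delta_C_uM == pytest.approx(16.92235294117647)
    assert res.total_rate_F_mol_s == pytest.approx(2.3179128901113787e-14, rel=1e-12)
    assert res.per_cell_rate_mol_s == pytest.approx(1.4047956909765933e-16, rel=1e-12)


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(diffusion_coefficient_cm2_s=0.0),
        dict(bulk_oxygen_uM=-1.0),
        dict(bulk_current_nA=0.0),
    ],
)
def test_medium_constants_invariants(kwargs):
    with pytest.raises(DomainError):
        MediumConstants(**kwargs)


@pytest.mark.parametrize(
    "kwargs",
    [dict(equivalent_radius_um=0.0), dict(cell_fraction=0.0), dict(cell_fraction=1.5)],
)
def test_port_geometry_invariants(kwargs):
    with pytest.raises(DomainError):
        PortGeometry(**kwargs)
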