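"""Turnaround scheduling, per-cycle |dI| extraction and bulk normalisation."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from secmscc import (
    DomainError,
    InsufficientDataError,
    ScanProtocol,
    ScanTrace,
    SimulationConfig,
    compute_delta_i,
    expected_delta_i,
    normalize_to_bulk,
    simulate_z_scan,
    turnaround_times,
)
from secmscc.scans import cycle_pairs


def synthetic_trace(protocol, surface_nA, bulk_nA, dt=0.1):
    """Square-wave trace: one current level near the surface, another in
    bulk, switching at the midpoint of each leg."""
    n = int(round(protocol.total_duration_s / dt)) + 1
    times = np.arange(n) * dt
    L = protocol.leg_duration_s
    phase = np.mod(times, 2 * L) / L
    frac = np.where(phase <= 1, phase, 2 - phase)  # 0 at surface, 1 at bulk
    currents = np.where(frac < 0.5, surface_nA, bulk_nA)
    return ScanTrace(times_s=times, currents_nA=currents, protocol=protocol)


class TestSchedule:
    def test_cone_well_turnarounds(self):
        pairs = cycle_pairs(ScanProtocol.cone_well())
        assert pairs == [(100.0, 200.0), (300.0, 400.0), (500.0, 600.0)]

    def test_chip_turnarounds(self):
        pairs = cycle_pairs(ScanProtocol.chip())
        assert pairs == [(10.0, 20.0), (30.0, 40.0), (50.0, 60.0)]

    def test_surface_start_schedule_kinds(self):
        tt = turnaround_times(ScanProtocol.chip())
        assert tt[0] == (0.0, "surface")
        assert tt[1] == (10.0, "bulk")
        assert tt[-1] == (60.0, "surface")

    def test_single_cycle_has_one_pair(self):
        assert len(cycle_pairs(ScanProtocol.chip(n_cycles=1))) == 1

    def test_bulk_start_swaps_roles(self):
        proto = ScanProtocol.chip()
        proto = dataclasses.replace(proto, starts_at_surface=False)
        assert turnaround_times(proto)[0] == (0.0, "bulk")
        assert cycle_pairs(proto)[0] == (0.0, 10.0)


class TestDeltaI:
    @pytest.mark.parametrize("reading", ["extrapolate", "median", "nearest"])
    def test_square_wave_trace_gives_exact_delta_i(self, reading):
        trace = synthetic_trace(ScanProtocol.chip(), surface_nA=-1.6, bulk_nA=-1.7)
        res = compute_delta_i(trace, reading=reading)
        assert res.mean_abs_delta_i_pA == pytest.approx(100.0)
        assert res.sd_delta_i_pA == 0.0
        assert res.n_cycles == 3
        assert res.excluded_initial

    def test_flat_trace_gives_zero(self):
        trace = synthetic_trace(ScanProtocol.chip(), surface_nA=-1.7, bulk_nA=-1.7)
        assert compute_delta_i(trace).mean_abs_delta_i_pA == 0.0

    def test_noiseless_simulated_trace_recovers_analytic_delta_i(
        self, noiseless_config
    ):
        res = compute_delta_i(simulate_z_scan(noiseless_config))
        expected = expected_delta_i(noiseless_config)
        assert res.mean_abs_delta_i_pA == pytest.approx(expected, rel=1e-3)

    def test_noisy_recovery_within_noise_budget(self, noisy_config):
        sigma = noisy_config.noise_sd_pA
        res = compute_delta_i(simulate_z_scan(noisy_config))
        expected = expected_delta_i(noisy_config)
        assert abs(res.mean_abs_delta_i_pA - expected) <= 4 * sigma / np.sqrt(3)

    @settings(max_examples=30, derandomize=True)
    @given(offset=st.floats(min_value=-5.0, max_value=5.0))
    def test_delta_i_invariant_under_current_offset(self, offset):
        cfg = SimulationConfig(
            cell_concentration_per_ml=1.1e6, noise_sd_pA=2.0, seed=4
        )
        trace = simulate_z_scan(cfg)
        shifted = dataclasses.replace(trace, currents_nA=trace.currents_nA + offset)
        assert compute_delta_i(shifted).mean_abs_delta_i_pA == pytest.approx(
            compute_delta_i(trace).mean_abs_delta_i_pA, abs=1e-9
        )

    def test_delta_i_scales_with_depletion_gain(self):
        proto = ScanProtocol.chip()
        n = int(round(proto.total_duration_s / 0.1)) + 1
        times = np.arange(n) * 0.1
        L = proto.leg_duration_s
        phase = np.mod(times, 2 * L) / L
        frac = np.where(phase <= 1, phase, 2 - phase)
        depletion = 0.1 * (1 - frac)  # nA, largest at the surface
        results = []
        for gain in (1.0, 2.5):
            trace = ScanTrace(
                times_s=times, currents_nA=-1.7 + gain * depletion, protocol=proto
            )
            results.append(compute_delta_i(trace).mean_abs_delta_i_pA)
        assert results[1] == pytest.approx(2.5 * results[0], rel=1e-9)

    def test_settling_transient_is_excluded(self, noiseless_config):
        with_transient = dataclasses.replace(noiseless_config, settling_excess=0.2)
        a = compute_delta_i(simulate_z_scan(noiseless_config)).mean_abs_delta_i_pA
        b = compute_delta_i(simulate_z_scan(with_transient)).mean_abs_delta_i_pA
        assert a == b

    def test_trace_shorter_than_one_cycle_raises(self):
        proto = ScanProtocol.chip()
        times = np.arange(0.0, 9.0, 0.1)  # ends before the first surface return
        trace = ScanTrace(
            times_s=times, currents_nA=np.full(times.shape, -1.7), protocol=proto
        )
        with pytest.raises(InsufficientDataError):
            compute_delta_i(trace)

    def test_partial_trace_uses_only_complete_cycles(self, noiseless_config):
        trace = simulate_z_scan(noiseless_config)
        cut = np.flatnonzero(trace.times_s <= 45.0)  # covers 2 of 3 cycles
        short = ScanTrace(
            times_s=trace.times_s[cut],
            currents_nA=trace.currents_nA[cut],
            protocol=trace.protocol,
            heights_um=trace.heights_um[cut],
        )
        assert compute_delta_i(short).n_cycles == 2


class TestNormalize:
    def test_bulk_levels_map_to_zero(self, noisy_config):
        trace = normalize_to_bulk(simulate_z_scan(noisy_config))
        # re-normalising finds an offset of ~0, i.e. bulk is already at 0
        again = normalize_to_bulk(trace)
        assert np.allclose(trace.currents_nA, again.currents_nA, atol=1e-12)

    def test_shape_preserving(self, noiseless_config):
        raw = simulate_z_scan(noiseless_config)
        norm = normalize_to_bulk(raw)
        assert np.allclose(np.diff(raw.currents_nA), np.diff(norm.currents_nA))

    def test_surface_level_becomes_positive_delta(self, noiseless_config):
        # depletion lowers |I|; relative to bulk = 0 the surface reading
        # sits delta-I above zero for a negative reduction current
        norm = normalize_to_bulk(simulate_z_scan(noiseless_config))
        surf_idx = np.argmin(np.abs(norm.times_s - 20.0))
        assert norm.currents_nA[surf_idx] > 0

    def test_no_bulk_point_raises(self):
        proto = ScanProtocol.chip()
        times = np.arange(0.0, 9.0, 0.1)
        trace = ScanTrace(
            times_s=times, currents_nA=np.full(times.shape, -1.7), protocol=proto
        )
        with pytest.raises(InsufficientDataError):
            normalize_to_bulk(trace)


class TestTraceValidation:
    def test_non_monotone_times_rejected(self):
        with pytest.raises(DomainError):
            ScanTrace(
                times_s=np.array([0.0, 0.2, 0.1]),
                currents_nA=np.zeros(3),
                protocol=ScanProtocol.chip(),
            )

    def test_length_mismatch_rejected(self):
        with pytest.raises(DomainError):
            ScanTrace(
                times_s=np.array([0.0, 0.1]),
                currents_nA=np.zeros(3),
                protocol=ScanProtocol.chip(),
            )

    def test_minimum_two_samples(self):
        with pytest.raises(InsufficientDataError):
            ScanTrace(
                times_s=np.array([0.0]),
                currents_nA=np.zeros(1),
                protocol=ScanProtocol.chip(),
            )
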