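"""Generator contracts: determinism, camera model, machine model, conservation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dinolum import synth
from dinolum.datatypes import DecayFit, DepletionParams, PeakModel, PillarSensor


class TestFlashStack:
    def test_empty_stack_has_background_only(self):
        cfg = synth.SyntheticVideoConfig(cell_count=0, frame_count=10, seed=1)
        stack, truth = synth.gen_flash_stack(cfg)
        assert len(truth.cell_positions) == 0
        # nothing close to a flash: background is mean 8, sd 3, clipped
        assert stack.frames[..., 2].max() < 70

    def test_single_cell_appears_at_onset_frame(self):
        cfg = synth.SyntheticVideoConfig(
            cell_count=1, frame_count=30, fps=30, flash_amplitude=200.0,
            onset_times=[0.5], background_mean=0.0, background_sd=0.0, seed=2,
        )
        stack, truth = synth.gen_flash_stack(cfg)
        onset_frame = math.ceil(0.5 * cfg.fps)
        blue = stack.frames[..., 2]
        assert blue[:onset_frame].max() == 0
        assert blue[onset_frame].max() >= 190

    def test_same_seed_is_bit_identical(self):
        cfg = dict(cell_count=20, frame_count=20, height=200, width=200,
                   cell_sigma_px=1.5, seed=42)
        a, _ = synth.gen_flash_stack(synth.SyntheticVideoConfig(**cfg))
        b, _ = synth.gen_flash_stack(synth.SyntheticVideoConfig(**cfg))
        assert np.array_equal(a.frames, b.frames)

    def test_too_close_positions_rejected(self):
        cfg = synth.SyntheticVideoConfig(
            cell_count=2, cell_sigma_px=2.0,
            cell_positions=[(50, 50), (50, 55)],  # 5 px < 4*sigma = 8 px
        )
        with pytest.raises(ValueError, match="closer than"):
            synth.gen_flash_stack(cfg)

    def test_pixels_in_range_and_blob_footprint_bounded(self):
        cfg = synth.SyntheticVideoConfig(
            cell_count=1, frame_count=5, cell_positions=[(60, 60)],
            onset_times=[0.0], background_mean=0.0, background_sd=0.0,
            cell_sigma_px=2.0, seed=3,
        )
        stack, _ = synth.gen_flash_stack(cfg)
        blue = stack.frames[..., 2]
        assert blue.min() >= 0 and blue.max() <= 255
        rr, cc = np.mgrid[0:120, 0:120]
        outside = (rr - 60) ** 2 + (cc - 60) ** 2 > (4 * 2.0) ** 2
        assert blue[:, outside].max() == 0

    def test_reflection_artifacts_sit_outside_mask(self):
        cfg = synth.SyntheticVideoConfig(cell_count=0, frame_count=5,
                                         reflection_artifacts=True, seed=4)
        stack, _ = synth.gen_flash_stack(cfg)
        blue = stack.frames[..., 2]
        assert blue[:, ~stack.mask].max() >= 200
        assert blue[:, stack.mask].max() < 70


class TestForceRecord:
    def test_unbounded_acceleration_reaches_nominal_rate(self):
        m = synth.MachineModel(nominal_rate=2.5, max_acceleration=1e9)
        record, truth = synth.gen_force_record(m, 0.10)
        rates = np.diff(record.displacement) / np.diff(record.time)
        assert truth.peak_velocity_mm_s == pytest.approx(2.5)
        assert rates.max() == pytest.approx(2.5, rel=1e-6)

    def test_acceleration_limited_peak_rate(self):
        # short travel: v_peak = sqrt(a*d) < nominal
        m = synth.MachineModel(nominal_rate=10.0, max_acceleration=50.0,
                               sample_height=12.0)
        record, truth = synth.gen_force_record(m, 0.05)  # d = 0.6 mm
        v_expected = math.sqrt(50.0 * 0.6)
        assert truth.peak_velocity_mm_s == pytest.approx(v_expected)
        rates = np.diff(record.displacement) / np.diff(record.time)
        assert rates.max() < 10.0
        assert rates.max() == pytest.approx(v_expected, rel=0.02)

    def test_effective_rate_never_exceeds_nominal(self):
        for accel in (5.0, 50.0, 1e9):
            m = synth.MachineModel(nominal_rate=5.0, max_acceleration=accel)
            record, _ = synth.gen_force_record(m, 0.10)
            rates = np.diff(record.displacement) / np.diff(record.time)
            assert rates.max() <= 5.0 + 1e-9

    def test_elastic_limit_has_no_hysteresis(self):
        m = synth.MachineModel(maxwell_relaxation_s=1e12)
        record, _ = synth.gen_force_record(m, 0.10)
        # compare force at matched displacements on the two branches
        peak = int(np.argmax(record.displacement))
        x_up, f_up = record.displacement[: peak + 1], record.force[: peak + 1]
        x_dn, f_dn = record.displacement[peak:][::-1], record.force[peak:][::-1]
        grid = np.linspace(0.05, 0.95, 20) * record.displacement.max()
        up = np.interp(grid, x_up, f_up)
        dn = np.interp(grid, x_dn, f_dn)
        assert np.allclose(up, dn, rtol=1e-4, atol=1e-6)

    def test_excessive_travel_raises(self):
        m = synth.MachineModel(travel=20.0, sample_height=12.0)
        with pytest.raises(ValueError, match="travel exceeds"):
            synth.gen_force_record(m, 0.10)


class TestSpectralSeries:
    def test_pure_exponential_windows_decay_geometrically(self):
        peaks = PeakModel(centers=np.array([2.5]), widths=np.array([0.05]),
                          amplitudes=np.array([1.0]))
        decay = DecayFit(i0=1.0, tau_ms=250.0, alpha=1.0)
        ser = synth.gen_spectral_series(peaks, decay, 1e6, integration_ms=125.0,
                                        poisson_noise=False)
        per_window = ser.counts.sum(axis=1)
        ratios = per_window[1:] / per_window[:-1]
        assert np.allclose(ratios, math.exp(-0.125 / 0.25), rtol=1e-6)

    def test_zero_photons_gives_zero_series(self, three_peak_model, colony_decay):
        ser = synth.gen_spectral_series(three_peak_model, colony_decay, 0.0,
                                        seed=1)
        assert ser.counts.sum() == 0

    def test_total_expected_counts_match_budget(self, three_peak_model,
                                                colony_decay):
        ser = synth.gen_spectral_series(three_peak_model, colony_decay, 5e4,
                                        poisson_noise=False)
        assert ser.counts.sum() == pytest.approx(5e4, rel=1e-9)

    def test_seeded_series_reproducible(self, three_peak_model, colony_decay):
        a = synth.gen_spectral_series(three_peak_model, colony_decay, 1e4, seed=9)
        b = synth.gen_spectral_series(three_peak_model, colony_decay, 1e4, seed=9)
        assert np.array_equal(a.counts, b.counts)

    def test_negative_amplitudes_rejected(self, colony_decay):
        peaks = PeakModel(centers=np.array([2.5]), widths=np.array([0.05]),
                          amplitudes=np.array([1.0]))
        peaks.amplitudes = np.array([-1.0])  # bypass constructor check
        with pytest.raises(ValueError, match="non-negative"):
            synth.gen_spectral_series(peaks, colony_decay, 1e4)


class TestCycleCounts:
    def test_empty_pool_emits_nothing(self):
        p = DepletionParams(pool_initial=0.0, rate_half=3.0, rate_slope=1.5)
        counts, _ = synth.gen_cycle_counts(p, [1.0, 5.0, 10.0], seed=1)
        assert np.all(counts == 0)

    def test_saturating_rate_drains_pool_fraction(self):
        p = DepletionParams(pool_initial=1e6, rate_half=2.0, rate_slope=3.0,
                            yield_max=0.8)
        counts, truth = synth.gen_cycle_counts(p, [1e3], seed=2)
        # closed form: one cycle at saturating rate emits pool * yield_max
        assert truth.per_cycle_photons[0] == pytest.approx(8e5, rel=1e-6)
        assert counts[0] == pytest.approx(8e5, rel=0.01)

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.floats(0, 50), min_size=1, max_size=12),
           st.integers(0, 2**31 - 1))
    def test_photon_conservation_any_schedule(self, rates, seed):
        p = DepletionParams(pool_initial=2e4, rate_half=3.0, rate_slope=1.5,
                            yield_max=0.9)
        counts, _ = synth.gen_cycle_counts(p, rates, seed=seed)
        assert counts.sum() <= p.pool_initial + 1e-9


class TestSensorTrial:
    def test_equal_heights_light_simultaneously(self, default_machine):
        sen = PillarSensor(heights=np.array([8.0, 8.0, 8.0]))
        stack, record, truth = synth.gen_sensor_trial(
            sen, default_machine, actuation_strain=0.02, seed=1)
        assert np.allclose(truth.pillar_onset_displacements, 0.02 * 8.0)

    def test_derived_onset_displacement(self, default_machine):
        sen = PillarSensor(heights=np.array([10.0, 8.0]))
        _, _, truth = synth.gen_sensor_trial(sen, default_machine,
                                             actuation_strain=0.02, seed=1)
        # (10 - 8) + 0.02 * 8 = 2.16 mm
        assert truth.pillar_onset_displacements[1] == pytest.approx(2.16)

    def test_zero_threshold_lights_at_first_contact(self, default_machine):
        sen = PillarSensor(heights=np.array([10.0, 7.0, 5.0]))
        _, _, truth = synth.gen_sensor_trial(sen, default_machine,
                                             actuation_strain=0.0, seed=1)
        assert np.allclose(truth.pillar_onset_displacements,
                           10.0 - sen.heights)

    def test_unreachable_pillar_marked_non_actuated(self):
        m = synth.MachineModel(nominal_rate=5.0, travel=3.0, sample_height=10.0)
        sen = PillarSensor(heights=np.array([10.0, 9.0, 2.0]))
        _, _, truth = synth.gen_sensor_trial(sen, m, actuation_strain=0.02,
                                             max_strain=0.3, seed=1)
        assert truth.pillar_actuated[0] and truth.pillar_actuated[1]
        assert not truth.pillar_actuated[2]  # needs 8.04 mm > 3 mm travel
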