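"""Synthetic generators: aperiodic EEG, bursts, oddball, pupil, study."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from burstlab.spectral import welch_psd
from burstlab.stats import wmz_contrast, zscore_outcomes
from burstlab.synth import (
    BurstSpec,
    StudySimulationConfig,
    gen_aperiodic_eeg,
    gen_oddball_sequence,
    gen_pupil_trace,
    gen_study,
    insert_bursts,
    simulate_study_values,
)

from conftest import FS


class TestAperiodicEEG:
    def test_exponent_zero_is_flat_white_noise(self):
        x = gen_aperiodic_eeg(100, FS, exponent=0.0, scale_uV=1.0, seed=1)
        freqs, psd = welch_psd(x[0], FS)
        sel = (freqs >= 1) & (freqs <= 100)
        # flat: log-log slope indistinguishable from zero
        slope = np.polyfit(np.log10(freqs[sel]), np.log10(psd[sel]), 1)[0]
        assert abs(slope) < 0.1

    def test_exponent_two_slope_recovered(self):
        """Least-squares fit on the generator's own Welch PSD, 100 s."""
        x = gen_aperiodic_eeg(100, FS, exponent=2.0, scale_uV=10.0, seed=2)
        freqs, psd = welch_psd(x[0], FS)
        sel = (freqs >= 1) & (freqs <= 30)
        slope = np.polyfit(np.log10(freqs[sel]), np.log10(psd[sel]), 1)[0]
        assert slope == pytest.approx(-2.0, abs=0.3)

    def test_length_arithmetic(self):
        x = gen_aperiodic_eeg(10, 250.0, n_channels=3)
        assert x.shape == (3, 2500)

    def test_rms_matches_scale(self):
        x = gen_aperiodic_eeg(30, FS, exponent=1.0, scale_uV=7.5, seed=0)
        assert np.sqrt(np.mean(x**2)) == pytest.approx(7.5, rel=1e-6)

    def test_seed_determinism(self):
        a = gen_aperiodic_eeg(5, FS, seed=42)
        b = gen_aperiodic_eeg(5, FS, seed=42)
        assert np.array_equal(a, b)

    @pytest.mark.parametrize("kwargs", [dict(duration_s=0), dict(fs_hz=50)])
    def test_invalid_inputs_rejected(self, kwargs):
        full = dict(duration_s=10, fs_hz=250.0)
        full.update(kwargs)
        with pytest.raises(ValueError):
            gen_aperiodic_eeg(**full)


class TestInsertBursts:
    def test_empty_specs_identity(self):
        bg = gen_aperiodic_eeg(10, FS, seed=3)
        sig, truth = insert_bursts(bg, FS, [])
        assert np.array_equal(sig, bg)
        assert truth == []

    def test_noise_free_single_burst_detected_exactly(self, band_filters):
        from burstlab.detect import detect_channel
        from burstlab.filters import DEFAULT_BANDS

        bg = np.zeros((1, int(30 * FS)))
        sig, truth = insert_bursts(bg, FS, [BurstSpec(0, 6.0, 12.0, 10, 20.0)])
        bursts = detect_channel(sig[0], FS, DEFAULT_BANDS, band_filters)
        assert len(bursts) == 1
        assert bursts[0].n_cycles == truth[0].n_cycles == 10
        assert truth[0].band_label == "theta"
        assert bursts[0].start_s == pytest.approx(truth[0].onset_s, abs=2 / FS)
        assert bursts[0].mean_amplitude == pytest.approx(20.0, rel=0.05)

    def test_ground_truth_fields(self):
        bg = np.zeros((2, int(20 * FS)))
        sig, truth = insert_bursts(bg, FS, [BurstSpec(1, 10.0, 5.0, 6, 12.0)])
        t = truth[0]
        assert t.channel == 1
        assert t.n_cycles == 6
        assert t.band_label == "alpha"
        assert t.end_s - t.onset_s == pytest.approx(6 / 10.0)
        assert np.allclose(sig[0], 0)  # other channel untouched

    def test_overlapping_specs_rejected(self):
        bg = np.zeros((1, int(20 * FS)))
        specs = [BurstSpec(0, 6.0, 5.0, 8, 10.0), BurstSpec(0, 8.0, 5.5, 8, 10.0)]
        with pytest.raises(ValueError, match="overlap"):
            insert_bursts(bg, FS, specs)

    def test_burst_outside_recording_rejected(self):
        bg = np.zeros((1, int(5 * FS)))
        with pytest.raises(ValueError, match="fit"):
            insert_bursts(bg, FS, [BurstSpec(0, 6.0, 4.0, 10, 10.0)])

    def test_hann_envelope_breaks_amplitude_consistency(self, band_filters):
        """Under a Hann envelope the edge cycles violate the amplitude-
        consistency criterion, so fewer cycles than requested survive."""
        from burstlab.detect import detect_channel
        from burstlab.filters import DEFAULT_BANDS

        bg = np.zeros((1, int(30 * FS)))
        sig, _ = insert_bursts(
            bg, FS, [BurstSpec(0, 6.0, 12.0, 10, 20.0)], envelope="hann"
        )
        bursts = detect_channel(sig[0], FS, DEFAULT_BANDS, band_filters)
        assert max((b.n_cycles for b in bursts), default=0) < 10

    def test_asymmetry_sharpens_descent(self):
        bg = np.zeros((1, int(20 * FS)))
        sig, truth = insert_bursts(
            bg, FS, [BurstSpec(0, 6.0, 5.0, 8, 20.0)], waveform_asymmetry=0.4
        )
        from burstlab.cycles import parse_cycles
        from burstlab.filters import BandDefinition

        cycles = parse_cycles(sig[0], sig[0], FS, BandDefinition("4-8Hz", 4, 8))
        mid = [c for c in cycles if truth[0].onset_s < c.neg_idx / FS < truth[0].end_s]
        for c in mid:
            desc = c.neg_idx - c.prev_pos_idx
            rise = c.next_pos_idx - c.neg_idx
            assert desc < rise  # compressed descending flank


class TestOddball:
    def test_default_counts(self):
        seq = gen_oddball_sequence(seed=0)
        assert len(seq.onsets_s) == 200
        assert seq.n_target == 40
        assert seq.n_standard == 160

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_invariants_hold_for_random_seeds(self, seed):
        seq = gen_oddball_sequence(seed=seed)
        assert seq.min_gap_between_targets() >= 3
        isis = np.diff(seq.onsets_s)
        assert np.all(isis >= 1.8) and np.all(isis <= 2.4)
        assert seq.n_target == 40 and seq.n_standard == 160

    def test_all_standard_duration_bounds(self):
        seq = gen_oddball_sequence(n_target=0, seed=5)
        assert seq.n_target == 0
        total = seq.onsets_s[-1] - seq.onsets_s[0]
        assert 159 * 1.8 <= total <= 159 * 2.4

    def test_seed_reproducibility(self):
        a = gen_oddball_sequence(seed=9)
        b = gen_oddball_sequence(seed=9)
        assert a.onsets_s == b.onsets_s and a.types == b.types

    def test_infeasible_gap_rejected(self):
        with pytest.raises(ValueError):
            gen_oddball_sequence(n_standard=10, n_target=40, seed=0)

    def test_target_positions_vary_with_seed(self):
        a = gen_oddball_sequence(seed=1)
        b = gen_oddball_sequence(seed=2)
        assert a.types != b.types


class TestPupilTrace:
    def test_blink_count_matches_ground_truth(self):
        trace, closures = gen_pupil_trace(
            360.0, blink_rate_per_min=10.0, seed=4
        )
        n_blinks = (closures["kind"] == "blink").sum()
        # Poisson(60): within 4 sigma
        assert 30 <= n_blinks <= 95
        # every closure is encoded as a low-confidence span
        assert (trace["confidence"] < 0.5).sum() > 0

    def test_microsleep_fraction(self):
        _, closures = gen_pupil_trace(
            360.0, blink_rate_per_min=0.0, microsleep_fraction=0.1, seed=6
        )
        share = closures["duration_s"].sum() / 360.0
        assert share == pytest.approx(0.10, abs=0.02)
        assert (closures["kind"] == "microsleep").all()

    def test_noiseless_trace_constant(self):
        trace, _ = gen_pupil_trace(
            60.0, blink_rate_per_min=0.0, noise_sd=0.0, seed=0
        )
        assert trace["diameter_px"].nunique() == 1

    def test_event_response_dilates(self):
        trace, _ = gen_pupil_trace(
            30.0, blink_rate_per_min=0.0, noise_sd=0.0,
            event_responses=[(10.0, 0.5)], seed=0,
        )
        t = trace["time_s"].to_numpy()
        d = trace["diameter_px"].to_numpy()
        assert d[(t > 10.5) & (t < 11.5)].max() > d[t < 10].max()

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            gen_pupil_trace(60.0, blink_rate_per_min=-1.0)

    def test_seed_determinism(self):
        a, ca = gen_pupil_trace(60.0, seed=7)
        b, cb = gen_pupil_trace(60.0, seed=7)
        assert a.equals(b) and ca.equals(cb)


class TestGenStudy:
    def test_null_dip_noise_free_wmz_zero(self):
        cfg = StudySimulationConfig(wmz_dip=0.0, noise_sd=0.0, between_sd=0.0)
        table, _ = gen_study(cfg)
        amp = table[table["outcome"] == "amplitude"]
        per, test = wmz_contrast(amp, value_col="value")
        # the saturating exponential is not perfectly linear over S5-S8,
        # but the deviation is small and identical for every participant
        assert per["wmz_statistic"].abs().max() < 0.05
        assert per["wmz_statistic"].std() == pytest.approx(0.0, abs=1e-12)

    def test_injected_dip_recovered_noise_free(self):
        cfg = StudySimulationConfig(wmz_dip=1.0, noise_sd=0.0, between_sd=0.0)
        table, _ = gen_study(cfg)
        amp = table[table["outcome"] == "amplitude"]
        _, test = wmz_contrast(amp, value_col="value")
        per, _ = wmz_contrast(amp, value_col="value")
        assert per["wmz_statistic"].mean() == pytest.approx(-1.0, abs=0.05)

    def test_saturation_limit(self):
        cfg = StudySimulationConfig(
            rate_per_h=1e6, noise_sd=0.0, between_sd=0.0, wmz_dip=0.0
        )
        table, _ = gen_study(cfg)
        amp = table[table["outcome"] == "amplitude"]
        sel = amp["session"].isin([f"S{i}" for i in range(3, 9)])
        assert np.allclose(amp.loc[sel, "value"], cfg.asymptote)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            StudySimulationConfig(noise_sd=-1.0)
        with pytest.raises(ValueError):
            StudySimulationConfig(schedule={"S1": 5.0, "S2": 4.0})

    def test_replicates_deterministic_and_distinct(self):
        cfg = StudySimulationConfig(seed=11)
        a = simulate_study_values(cfg, n_replicates=3)
        b = simulate_study_values(cfg, n_replicates=3)
        assert np.array_equal(a, b)
        assert not np.array_equal(a[0], a[1])

    def test_affine_invariance_of_zscores(self):
        cfg = StudySimulationConfig(seed=2)
        table, _ = gen_study(cfg)
        z1 = zscore_outcomes(table)
        shifted = table.copy()
        shifted["value"] = 3.0 * shifted["value"] + 7.0
        z2 = zscore_outcomes(shifted)
        assert np.allclose(z1["z"], z2["z"])
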