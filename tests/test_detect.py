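"""Per-cycle criteria, burst formation, dual polarity, overlap resolution."""

import numpy as np
import pytest

from burstlab.cycles import Cycle, parse_cycles
from burstlab.detect import (
    Burst,
    CriteriaThresholds,
    detect_bursts,
    detect_dual_polarity,
    evaluate_all,
    evaluate_criteria,
    resolve_within_channel,
)
from burstlab.filters import BandDefinition

from conftest import FS, make_sine_cycles

BAND = BandDefinition("6-10Hz", 6, 10)
TH = CriteriaThresholds()


def ideal_cycle(period=0.128, amp=10.0, neg=100):
    half = int(period * FS / 2)
    return Cycle(
        prev_pos_idx=neg - half,
        desc_zc_idx=neg - half // 2,
        neg_idx=neg,
        rise_zc_idx=neg + half // 2,
        next_pos_idx=neg + half,
        rise_amp=amp,
        decay_amp=amp,
        amplitude=amp,
        period_prev_s=period,
        period_next_s=period,
        mono_time_desc=1.0,
        mono_time_rise=1.0,
        mono_amp=1.0,
        is_local_min=True,
    )


class TestEvaluateCriteria:
    def test_ideal_cycle_passes_all(self):
        c = ideal_cycle()
        out = evaluate_criteria(c, ideal_cycle(neg=68), ideal_cycle(neg=132), TH, BAND)
        assert all(out.values())

    def test_rise_decay_ratio_just_below_half_fails_d_only(self):
        c = ideal_cycle()
        c.rise_amp = 4.5
        c.decay_amp = 10.0
        out = evaluate_criteria(c, ideal_cycle(neg=69), ideal_cycle(neg=131), TH, BAND)
        assert not out["D"]
        assert all(v for k, v in out.items() if k != "D")

    def test_alternating_periods_fail_c(self):
        c = ideal_cycle()
        c.period_prev_s = 0.10
        c.period_next_s = 0.20
        out = evaluate_criteria(c, ideal_cycle(neg=75), ideal_cycle(neg=150), TH, BAND)
        assert not out["C"]  # ratio 0.5 < 0.6

    def test_period_outside_band_fails_b(self):
        c = ideal_cycle(period=0.30)  # 3.3 Hz in a 6-10 Hz band
        out = evaluate_criteria(c, ideal_cycle(neg=25), ideal_cycle(neg=175), TH, BAND)
        assert not out["B"]

    def test_missing_neighbor_fails_c_and_e(self):
        c = ideal_cycle()
        out = evaluate_criteria(c, None, None, TH, BAND)
        assert not out["C"] and not out["E"]
        assert out["A"] and out["D"] and out["F"] and out["G"]

    def test_amplitude_inconsistency_fails_e(self):
        small = ideal_cycle(neg=69)
        small.amplitude = 5.0
        out = evaluate_criteria(ideal_cycle(), small, ideal_cycle(neg=131), TH, BAND)
        assert not out["E"]  # ratio 0.5 < 0.6


def _run_chain(pattern, period=0.128):
    """Cycles spaced one period apart; pattern marks which are sabotaged."""
    step = int(period * FS)
    cycles = []
    for i, ok in enumerate(pattern):
        c = ideal_cycle(period=period, neg=200 + i * step)
        c.prev_pos_idx = 200 + i * step - step // 2
        c.next_pos_idx = 200 + i * step + step // 2
        if not ok:
            c.is_local_min = False  # fail criterion A only
        cycles.append(c)
    return cycles


class TestDetectBursts:
    def test_single_run_of_ten(self):
        bursts = detect_bursts(_run_chain([True] * 10), TH, BAND, FS)
        # edge cycles lack neighbours and fail C/E, leaving one 8-cycle run
        assert len(bursts) == 1
        assert bursts[0].n_cycles == 8

    def test_three_passing_cycles_no_burst(self):
        pattern = [False] * 2 + [True] * 3 + [False] * 2
        assert detect_bursts(_run_chain(pattern), TH, BAND, FS) == []

    def test_run_length_formation_matches_boolean_oracle(self, rng):
        """Random pass/fail patterns against a brute-force run-length scan
        (including the PPPPFPPPP split case)."""
        patterns = [[True] * 4 + [False] + [True] * 4] + [
            list(rng.random(20) > 0.4) for _ in range(120)
        ]
        for pattern in patterns:
            padded = [False] + pattern + [False]
            cycles = _run_chain(padded)
            passes = evaluate_all(cycles, TH, BAND)
            # oracle: maximal runs of >= 4 in the boolean vector
            runs, start = [], None
            for i, p in enumerate(list(passes) + [False]):
                if p and start is None:
                    start = i
                elif not p and start is not None:
                    if i - start >= 4:
                        runs.append((start, i))
                    start = None
            bursts = detect_bursts(cycles, TH, BAND, FS)
            assert [(b.cycles[0].neg_idx, b.cycles[-1].neg_idx) for b in bursts] == [
                (cycles[a].neg_idx, cycles[b - 1].neg_idx) for a, b in runs
            ]


class TestDualPolarity:
    def test_symmetric_sinusoid_resolves_to_one(self, band_filters):
        x = make_sine_cycles(8.0, 60, amplitude=10.0)
        from burstlab.filters import apply_band_filter

        filtered, _ = apply_band_filter(x, band_filters["6-10Hz"])
        bursts = detect_dual_polarity(x, filtered, BAND, TH, FS)
        assert any(b.inverted for b in bursts)
        assert any(not b.inverted for b in bursts)
        resolved = resolve_within_channel(bursts)
        assert len(resolved) == 1

    def test_mu_like_waveform_detected_inverted(self, band_filters):
        """Sharp troughs and flat tops: the direct parse fails the
        monotonicity criteria where the inverted one passes."""
        t = np.arange(int(8 * FS)) / FS
        base = np.sin(2 * np.pi * 9.0 * t)
        mu = np.where(base < 0, base, 0.25 * np.sin(2 * np.pi * 27.0 * t))
        mu = 10 * mu
        from burstlab.filters import apply_band_filter

        filtered, _ = apply_band_filter(mu, band_filters["6-10Hz"])
        bursts = detect_dual_polarity(mu, filtered, BAND, TH, FS)
        assert bursts
        assert all(not b.inverted for b in bursts)
        inv = detect_dual_polarity(-mu, -filtered, BAND, TH, FS)
        assert inv and all(b.inverted for b in inv)

    def test_zero_signal_empty(self):
        z = np.zeros(5000)
        assert detect_dual_polarity(z, z, BAND, TH, FS) == []


def _make_burst(start_cycle, n, channel=0, period=0.128, band="6-10Hz"):
    step = int(period * FS)
    cycles = []
    for i in range(n):
        neg = 1000 + (start_cycle + i) * step
        c = ideal_cycle(period=period, neg=neg)
        c.prev_pos_idx = neg - step // 2
        c.next_pos_idx = neg + step // 2
        c.band_label = band
        cycles.append(c)
    return Burst(channel=channel, band_label=band, inverted=False,
                 cycles=cycles, fs_hz=FS)


class TestResolveWithinChannel:
    def test_disjoint_bursts_kept(self):
        a, b = _make_burst(0, 5), _make_burst(10, 6)
        out = resolve_within_channel([a, b])
        assert len(out) == 2
        assert {o.n_cycles for o in out} == {5, 6}

    def test_contained_burst_removed(self):
        big = _make_burst(0, 10, band="4-8Hz")
        small = _make_burst(2, 5, band="8-12Hz")
        out = resolve_within_channel([big, small])
        assert len(out) == 1
        assert out[0].n_cycles == 10

    def test_partial_overlap_trims_to_remnant(self):
        # 9-cycle burst kept; 8-cycle burst overlapping its first 3 cycles
        # is trimmed to a 5-cycle remnant
        long = _make_burst(0, 9)
        short = _make_burst(-5, 8, band="4-8Hz")
        out = resolve_within_channel([long, short])
        assert len(out) == 2
        assert sorted(b.n_cycles for b in out) == [5, 9]
        lo = [b for b in out if b.n_cycles == 5][0]
        hi = [b for b in out if b.n_cycles == 9][0]
        assert lo.cycles[-1].next_pos_idx <= hi.start_idx

    def test_short_remnant_discarded(self):
        long = _make_burst(0, 9)
        short = _make_burst(-3, 6, band="4-8Hz")  # remnant would be 3 cycles
        out = resolve_within_channel([long, short])
        assert len(out) == 1

    def test_output_is_overlap_antichain_and_matches_subtraction_oracle(self, rng):
        """Random burst soups: result must be pairwise non-overlapping and
        each survivor's cycles must be exactly an interval-subtraction
        remnant of some input burst."""
        for _ in range(100):
            bursts = []
            for _k in range(int(rng.integers(2, 7))):
                start = int(rng.integers(-10, 25))
                n = int(rng.integers(4, 12))
                band = str(rng.choice(["2-6Hz", "4-8Hz", "6-10Hz"]))
                bursts.append(_make_burst(start, n, band=band))
            out = resolve_within_channel(bursts)
            spans = sorted((b.start_idx, b.cycles[-1].next_pos_idx) for b in out)
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2  # pairwise non-overlap (peaks may be shared)
            input_negs = [set(c.neg_idx for c in b.cycles) for b in bursts]
            for b in out:
                negs = set(c.neg_idx for c in b.cycles)
                assert any(negs <= s for s in input_negs)
                assert b.n_cycles >= 4


class TestInvariances:
    def test_amplitude_scale_invariance(self, band_filters):
        from burstlab.detect import detect_channel
        from burstlab.filters import DEFAULT_BANDS
        from burstlab.synth import BurstSpec, gen_aperiodic_eeg, insert_bursts
        from burstlab.filters import broadband_filter

        bg = broadband_filter(gen_aperiodic_eeg(30, FS, 1.0, 5.0, 1, 3), FS)
        sig, _ = insert_bursts(bg, FS, [BurstSpec(0, 7.0, 12.0, 8, 40.0)])
        b1 = detect_channel(sig[0], FS, DEFAULT_BANDS, band_filters)
        b2 = detect_channel(3.14 * sig[0], FS, DEFAULT_BANDS, band_filters)
        assert [(b.start_idx, b.end_idx, b.n_cycles) for b in b1] == [
            (b.start_idx, b.end_idx, b.n_cycles) for b in b2
        ]

    def test_dc_offset_invariance(self, band_filters):
        from burstlab.detect import detect_channel
        from burstlab.filters import DEFAULT_BANDS
        from burstlab.synth import BurstSpec, gen_aperiodic_eeg, insert_bursts
        from burstlab.filters import broadband_filter

        bg = broadband_filter(gen_aperiodic_eeg(30, FS, 1.0, 5.0, 1, 3), FS)
        sig, _ = insert_bursts(bg, FS, [BurstSpec(0, 7.0, 12.0, 8, 40.0)])
        b1 = detect_channel(sig[0], FS, DEFAULT_BANDS, band_filters)
        b2 = detect_channel(sig[0] + 100.0, FS, DEFAULT_BANDS, band_filters)
        assert [(b.start_idx, b.end_idx, b.n_cycles) for b in b1] == [
            (b.start_idx, b.end_idx, b.n_cycles) for b in b2
        ]
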