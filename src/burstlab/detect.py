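"""Cycle-criteria evaluation and burst formation.

A burst is a run of at least four consecutive cycles that each satisfy
seven shape/regularity criteria:

A. the negative peak is a local minimum of the raw trace;
B. the mean distance to the neighbouring negative peaks falls inside the
   band's period range (e.g. 0.1-0.17 s for the 6-10 Hz band);
C. the ratio of consecutive periods, min/max, is at least 0.6;
D. the rise and decay amplitudes have a min/max ratio of at least 0.5;
E. the cycle amplitude is within a min/max ratio of 0.6 of both
   neighbouring cycles' amplitudes;
F. each flank moves monotonically in time for at least 60% of its samples;
G. at least 60% of the traversed voltage along the flanks moves in the
   expected direction (averaged over the two flanks).

All criteria are ratios of amplitudes, periods or sample counts, so
detection is invariant to signal gain and DC offset; this is what
dissociates the amplitude of detected oscillations from their quantity.
Detection runs on both the signal and its inverse (mu-shaped rhythms with
sharp troughs only are caught on the inverted polarity); overlapping
detections within a channel are then resolved by keeping the largest burst
intact and trimming the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cycles import Cycle, parse_cycles
from .filters import BandDefinition, BandFilter, band_period_range

__all__ = [
    "CriteriaThresholds",
    "Burst",
    "evaluate_criteria",
    "evaluate_all",
    "detect_bursts",
    "detect_dual_polarity",
    "resolve_within_channel",
    "detect_channel",
]

CRITERIA = "ABCDEFG"


@dataclass(frozen=True)
class CriteriaThresholds:
    """Thresholds of the per-cycle criteria and the run-length rule."""

    min_cycles: int = 4
    period_consistency: float = 0.6  # C
    rise_decay_ratio: float = 0.5  # D
    amplitude_consistency: float = 0.6  # E
    monotonicity_time: float = 0.6  # F
    monotonicity_amplitude: float = 0.6  # G
    require_local_min: bool = True  # A
    # F applied to each flank separately (stricter) or to their mean
    monotonicity_per_flank: bool = True

    def __post_init__(self) -> None:
        for name in (
            "period_consistency",
            "rise_decay_ratio",
            "amplitude_consistency",
            "monotonicity_time",
            "monotonicity_amplitude",
        ):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.min_cycles < 2:
            raise ValueError("min_cycles must be >= 2")


@dataclass
class Burst:
    """A detected run of criterion-passing cycles in one channel and band."""

    channel: int
    band_label: str
    inverted: bool
    cycles: list[Cycle]
    fs_hz: float

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    @property
    def start_idx(self) -> int:
        return self.cycles[0].start_idx

    @property
    def end_idx(self) -> int:
        return self.cycles[-1].end_idx

    @property
    def start_s(self) -> float:
        return self.start_idx / self.fs_hz

    @property
    def end_s(self) -> float:
        return self.end_idx / self.fs_hz

    @property
    def duration_s(self) -> float:
        return (self.end_idx - self.start_idx) / self.fs_hz

    def negative_peak_indices(self) -> np.ndarray:
        return np.array([c.neg_idx for c in self.cycles])

    @property
    def mean_frequency_hz(self) -> float:
        """Reciprocal of the mean inter-negative-peak distance."""
        negs = self.negative_peak_indices()
        if len(negs) < 2:
            return float("nan")
        return self.fs_hz / float(np.mean(np.diff(negs)))

    @property
    def mean_amplitude(self) -> float:
        """Mean over cycles of the rise/decay-averaged amplitude."""
        return float(np.mean([c.amplitude for c in self.cycles]))


def _minmax_ratio(a: float, b: float) -> float:
    hi = max(a, b)
    if hi <= 0:
        return 0.0
    return min(a, b) / hi


def evaluate_criteria(
    cycle: Cycle,
    prev_cycle: Cycle | None,
    next_cycle: Cycle | None,
    thresholds: CriteriaThresholds,
    band: BandDefinition,
) -> dict[str, bool]:
    """Evaluate criteria A-G for one cycle given its neighbours.

    A missing neighbour fails C and E by definition: period and amplitude
    consistency are undefined at the edges of a trace.
    """
    t = thresholds
    out: dict[str, bool] = {}
    out["A"] = cycle.is_local_min or not t.require_local_min

    p_prev, p_next = cycle.period_prev_s, cycle.period_next_s
    if np.isnan(p_prev) or np.isnan(p_next):
        out["B"] = False
        out["C"] = False
    else:
        lo, hi = band_period_range(band)
        mean_p = 0.5 * (p_prev + p_next)
        out["B"] = lo <= mean_p <= hi
        out["C"] = (
            prev_cycle is not None
            and next_cycle is not None
            and _minmax_ratio(p_prev, p_next) >= t.period_consistency
        )

    out["D"] = _minmax_ratio(cycle.rise_amp, cycle.decay_amp) >= t.rise_decay_ratio

    if prev_cycle is None or next_cycle is None:
        out["E"] = False
    else:
        r1 = _minmax_ratio(cycle.amplitude, prev_cycle.amplitude)
        r2 = _minmax_ratio(cycle.amplitude, next_cycle.amplitude)
        out["E"] = min(r1, r2) >= t.amplitude_consistency

    if t.monotonicity_per_flank:
        out["F"] = (
            cycle.mono_time_desc >= t.monotonicity_time
            and cycle.mono_time_rise >= t.monotonicity_time
        )
    else:
        out["F"] = (
            0.5 * (cycle.mono_time_desc + cycle.mono_time_rise)
            >= t.monotonicity_time
        )
    out["G"] = cycle.mono_amp >= t.monotonicity_amplitude
    return out


def evaluate_all(
    cycles: list[Cycle],
    thresholds: CriteriaThresholds,
    band: BandDefinition,
) -> np.ndarray:
    """Boolean pass vector (all seven criteria jointly) over a cycle list."""
    passes = np.zeros(len(cycles), dtype=bool)
    for i, c in enumerate(cycles):
        prev_c = cycles[i - 1] if i > 0 else None
        next_c = cycles[i + 1] if i + 1 < len(cycles) else None
        # neighbours must be temporally adjacent (shared positive peaks)
        if prev_c is not None and prev_c.next_pos_idx != c.prev_pos_idx:
            prev_c = None
        if next_c is not None and next_c.prev_pos_idx != c.next_pos_idx:
            next_c = None
        crit = evaluate_criteria(c, prev_c, next_c, thresholds, band)
        passes[i] = all(crit.values())
    return passes


def detect_bursts(
    cycles: list[Cycle],
    thresholds: CriteriaThresholds,
    band: BandDefinition,
    fs_hz: float,
    channel: int = 0,
    inverted: bool = False,
    valid_mask: np.ndarray | None = None,
) -> list[Burst]:
    """Form bursts from maximal runs of consecutive passing cycles.

    ``valid_mask``, when given, marks reliable samples (away from filter
    edges); cycles touching unreliable samples are excluded before run
    formation.
    """
    if valid_mask is not None:
        cycles = [
            c
            for c in cycles
            if valid_mask[c.start_idx] and valid_mask[c.end_idx - 1]
        ]
    passes = evaluate_all(cycles, thresholds, band)
    bursts: list[Burst] = []
    run_start: int | None = None
    for i in range(len(cycles) + 1):
        contiguous = (
            i < len(cycles)
            and passes[i]
            and (
                run_start is None
                or i == 0
                or cycles[i - 1].next_pos_idx == cycles[i].prev_pos_idx
            )
        )
        if contiguous:
            if run_start is None:
                run_start = i
            continue
        if run_start is not None and i - run_start >= thresholds.min_cycles:
            bursts.append(
                Burst(
                    channel=channel,
                    band_label=band.label,
                    inverted=inverted,
                    cycles=cycles[run_start:i],
                    fs_hz=fs_hz,
                )
            )
        run_start = i if (i < len(cycles) and passes[i]) else None
    return bursts


def detect_dual_polarity(
    raw: np.ndarray,
    filtered: np.ndarray,
    band: BandDefinition,
    thresholds: CriteriaThresholds,
    fs_hz: float,
    channel: int = 0,
    valid_mask: np.ndarray | None = None,
) -> list[Burst]:
    """Detect bursts on the signal and on its inverse.

    Inverted-polarity cycles are parsed from ``-raw`` / ``-filtered``; their
    sample coordinates refer to the original time axis, so downstream
    overlap resolution treats both polarities uniformly.
    """
    out = detect_bursts(
        parse_cycles(raw, filtered, fs_hz, band, inverted=False),
        thresholds,
        band,
        fs_hz,
        channel=channel,
        inverted=False,
        valid_mask=valid_mask,
    )
    out += detect_bursts(
        parse_cycles(-np.asarray(raw, float), -np.asarray(filtered, float),
                     fs_hz, band, inverted=True),
        thresholds,
        band,
        fs_hz,
        channel=channel,
        inverted=True,
        valid_mask=valid_mask,
    )
    return out


def _burst_order_key(b: Burst) -> tuple[int, int, int]:
    # largest first: most cycles, then longest duration, then earliest start
    return (-b.n_cycles, -(b.end_idx - b.start_idx), b.start_idx)


def resolve_within_channel(
    bursts: list[Burst],
    min_cycles: int = 4,
) -> list[Burst]:
    """Resolve overlapping detections (across bands/polarities) in a channel.

    Iteratively the largest burst (by cycle count, then duration, then
    earlier start) is kept intact; every burst overlapping it is trimmed to
    the cycles outside the kept interval, and each contiguous trimmed
    remnant survives as a new candidate only if it still has at least
    ``min_cycles`` cycles.  The output is pairwise non-overlapping.
    """
    pending = sorted(bursts, key=_burst_order_key)
    kept: list[Burst] = []
    while pending:
        best = pending.pop(0)
        kept.append(best)
        # peak-to-peak interval; a cycle sharing only a boundary positive
        # peak with the kept burst does not overlap it
        lo, hi = best.start_idx, best.cycles[-1].next_pos_idx
        survivors: list[Burst] = []
        for b in pending:
            if b.cycles[-1].next_pos_idx <= lo or b.start_idx >= hi:
                survivors.append(b)
                continue
            outside = [
                c
                for c in b.cycles
                if c.next_pos_idx <= lo or c.prev_pos_idx >= hi
            ]
            for run in _contiguous_runs(outside):
                if len(run) >= min_cycles:
                    survivors.append(replace(b, cycles=run))
        pending = sorted(survivors, key=_burst_order_key)
    return sorted(kept, key=lambda b: b.start_idx)


def _contiguous_runs(cycles: list[Cycle]) -> list[list[Cycle]]:
    runs: list[list[Cycle]] = []
    for c in cycles:
        if runs and runs[-1][-1].next_pos_idx == c.prev_pos_idx:
            runs[-1].append(c)
        else:
            runs.append([c])
    return runs


def detect_channel(
    raw: np.ndarray,
    fs_hz: float,
    bands: tuple[BandDefinition, ...],
    filters: dict[str, BandFilter],
    thresholds: CriteriaThresholds | None = None,
    channel: int = 0,
) -> list[Burst]:
    """Full single-channel pipeline: all bands, both polarities, resolved."""
    from .filters import apply_band_filter

    thresholds = thresholds or CriteriaThresholds()
    candidates: list[Burst] = []
    for band in bands:
        filt = filters[band.label]
        filtered, valid = apply_band_filter(raw, filt)
        candidates += detect_dual_polarity(
            raw, filtered, band, thresholds, fs_hz,
            channel=channel, valid_mask=valid,
        )
    return resolve_within_channel(candidates, thresholds.min_cycles)
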