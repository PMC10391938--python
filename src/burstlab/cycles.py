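"""Parse a filtered/raw signal pair into oscillation cycles.

Zero-crossings are found on the narrowband-filtered trace; peaks are then
located as extrema of the broadband ("raw", 0.5-40 Hz) trace inside the
crossing spans.  A cycle runs from one positive peak through the negative
peak to the next positive peak, and carries all the per-cycle waveform
features that the detection criteria consume.

Conventions: 0-based sample indices, half-open spans ``[start, end)``.  A
zero-crossing index is the first sample carrying the new sign; samples that
are exactly zero inherit the preceding sign.  Ties inside a peak-search span
resolve to the earliest sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .filters import BandDefinition

__all__ = [
    "Cycle",
    "find_zero_crossings",
    "locate_peaks",
    "build_cycles",
    "parse_cycles",
]


@dataclass
class Cycle:
    """One oscillation cycle (positive peak -> negative peak -> positive peak).

    Amplitudes are voltages in the raw-signal units (uV for EEG); periods in
    seconds; monotonicity fractions in [0, 1].
    """

    prev_pos_idx: int
    desc_zc_idx: int
    neg_idx: int
    rise_zc_idx: int
    next_pos_idx: int
    rise_amp: float
    decay_amp: float
    amplitude: float
    period_prev_s: float  # distance to previous negative peak
    period_next_s: float  # distance to next negative peak
    mono_time_desc: float
    mono_time_rise: float
    mono_amp: float
    is_local_min: bool
    band_label: str = ""
    inverted: bool = False

    @property
    def start_idx(self) -> int:
        return self.prev_pos_idx

    @property
    def end_idx(self) -> int:
        """Half-open end: one past the closing positive peak."""
        return self.next_pos_idx + 1


def find_zero_crossings(filtered: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Descending and rising zero-crossing indices of a filtered trace.

    Returns ``(descending, rising)`` index arrays.  Crossings alternate by
    construction; a constant-sign signal yields two empty arrays.
    """
    x = np.asarray(filtered, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("filtered signal must be finite")
    if len(x) == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    sign = np.where(x > 0, 1, np.where(x < 0, -1, 0))
    # zero samples inherit the previous sign; leading zeros take the first
    # nonzero sign so they never register as a crossing
    nonzero = sign != 0
    if not nonzero.any():
        return np.array([], dtype=int), np.array([], dtype=int)
    first = np.argmax(nonzero)
    sign[:first] = sign[first]
    idx = np.arange(len(sign))
    carried = np.maximum.accumulate(np.where(nonzero, idx, 0))
    sign = sign[carried]
    flips = np.nonzero(np.diff(sign))[0] + 1
    descending = flips[sign[flips] < 0]
    rising = flips[sign[flips] > 0]
    return descending, rising


def locate_peaks(
    raw: np.ndarray,
    descending: np.ndarray,
    rising: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Locate peaks on the raw trace between zero-crossings of the filtered.

    The negative peak is the argmin of ``raw`` over each half-open span
    ``[descending, next rising)``; the positive peak is the argmax over
    ``[rising, next descending)``.  Returns ``(positive, negative)`` index
    arrays, each strictly increasing; the alternation positive/negative is
    inherited from the crossing alternation.
    """
    raw = np.asarray(raw, dtype=float)
    neg_peaks = []
    pos_peaks = []
    for d in descending:
        nxt = rising[rising > d]
        end = nxt[0] if len(nxt) else len(raw)
        if end > d:
            neg_peaks.append(d + int(np.argmin(raw[d:end])))
    for r in rising:
        nxt = descending[descending > r]
        end = nxt[0] if len(nxt) else len(raw)
        if end > r:
            pos_peaks.append(r + int(np.argmax(raw[r:end])))
    return np.asarray(pos_peaks, dtype=int), np.asarray(neg_peaks, dtype=int)


def _flank_monotonicity_time(flank: np.ndarray, downward: bool) -> float:
    """Fraction of sample steps moving in the expected direction."""
    d = np.diff(flank)
    if len(d) == 0:
        return 1.0
    good = d <= 0 if downward else d >= 0
    return float(np.mean(good))


def _flank_monotonicity_amp(flank: np.ndarray, downward: bool) -> float:
    """Correctly-signed voltage change over total absolute voltage change."""
    d = np.diff(flank)
    total = np.abs(d).sum()
    if total == 0:
        return 1.0
    correct = -d[d < 0].sum() if downward else d[d > 0].sum()
    return float(correct / total)


def build_cycles(
    raw: np.ndarray,
    pos_peaks: np.ndarray,
    neg_peaks: np.ndarray,
    descending: np.ndarray,
    rising: np.ndarray,
    fs_hz: float,
    band: BandDefinition | None = None,
    inverted: bool = False,
) -> list[Cycle]:
    """Assemble cycles with all per-cycle features populated.

    One cycle is produced per negative peak that has a positive peak on each
    side; the first and last negative peaks of a trace therefore never form
    cycles.  Requires at least one negative peak and two positive peaks.
    """
    raw = np.asarray(raw, dtype=float)
    cycles: list[Cycle] = []
    band_label = band.label if band is not None else ""
    for k, neg in enumerate(neg_peaks):
        before = pos_peaks[pos_peaks < neg]
        after = pos_peaks[pos_peaks > neg]
        if len(before) == 0 or len(after) == 0:
            continue
        prev_pos = int(before[-1])
        next_pos = int(after[0])
        d_in = descending[(descending > prev_pos) & (descending <= neg)]
        r_in = rising[(rising > neg) & (rising <= next_pos)]
        desc_zc = int(d_in[-1]) if len(d_in) else neg
        rise_zc = int(r_in[0]) if len(r_in) else neg
        rise_amp = float(raw[prev_pos] - raw[neg])
        decay_amp = float(raw[next_pos] - raw[neg])
        period_prev = (neg - neg_peaks[k - 1]) / fs_hz if k > 0 else np.nan
        period_next = (neg_peaks[k + 1] - neg) / fs_hz if k + 1 < len(neg_peaks) else np.nan
        desc_flank = raw[prev_pos : neg + 1]
        rise_flank = raw[neg : next_pos + 1]
        local_min = bool(
            0 < neg < len(raw) - 1
            and raw[neg] <= raw[neg - 1]
            and raw[neg] <= raw[neg + 1]
        )
        cycles.append(
            Cycle(
                prev_pos_idx=prev_pos,
                desc_zc_idx=desc_zc,
                neg_idx=int(neg),
                rise_zc_idx=rise_zc,
                next_pos_idx=next_pos,
                rise_amp=rise_amp,
                decay_amp=decay_amp,
                amplitude=0.5 * (rise_amp + decay_amp),
                period_prev_s=period_prev,
                period_next_s=period_next,
                mono_time_desc=_flank_monotonicity_time(desc_flank, downward=True),
                mono_time_rise=_flank_monotonicity_time(rise_flank, downward=False),
                mono_amp=0.5
                * (
                    _flank_monotonicity_amp(desc_flank, downward=True)
                    + _flank_monotonicity_amp(rise_flank, downward=False)
                ),
                is_local_min=local_min,
                band_label=band_label,
                inverted=inverted,
            )
        )
    return cycles


def parse_cycles(
    raw: np.ndarray,
    filtered: np.ndarray,
    fs_hz: float,
    band: BandDefinition | None = None,
    inverted: bool = False,
) -> list[Cycle]:
    """Full parse: crossings on the filtered trace, peaks on the raw, cycles."""
    descending, rising = find_zero_crossings(filtered)
    pos_peaks, neg_peaks = locate_peaks(raw, descending, rising)
    return build_cycles(
        raw, pos_peaks, neg_peaks, descending, rising, fs_hz, band, inverted
    )
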