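"""Cross-channel burst aggregation and recording-level metrics.

Bursts detected independently per channel are grouped into aggregates when
they overlap a reference burst by at least 50% of their own duration and
their mean frequency over the overlapping cycles is within 1 Hz of the
reference's.  The longest burst of each group is the reference; it carries
the aggregate's cycle count.  Recording-level metrics per frequency band:

* amplitude (uV): three-level mean — rise/decay averaged per cycle, then
  averaged over all cycles of the aggregate pooled across member channels,
  then averaged over aggregates in the band;
* cycles per minute: total reference-burst cycles / recording minutes
  (the "quantity" measure, independent of amplitude by construction);
* occupancy: fraction of the recording covered by reference bursts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detect import Burst

__all__ = [
    "AggregateBurst",
    "RecordingBurstMetrics",
    "aggregate_across_channels",
    "burst_frequency",
    "band_assign",
    "recording_metrics",
    "bursts_to_frame",
    "aggregates_to_frame",
]


def burst_frequency(burst: Burst) -> float:
    """Mean frequency: reciprocal of the mean inter-negative-peak distance."""
    negs = burst.negative_peak_indices()
    if len(negs) < 2:
        return float("nan")
    return burst.fs_hz / float(np.mean(np.diff(negs)))


def _overlap_frequency(burst: Burst, lo: int, hi: int) -> float:
    """Mean frequency over the cycles overlapping sample span [lo, hi)."""
    cyc = [c for c in burst.cycles if c.start_idx < hi and c.end_idx > lo]
    negs = np.array([c.neg_idx for c in cyc])
    if len(negs) < 2:
        return burst_frequency(burst)
    return burst.fs_hz / float(np.mean(np.diff(negs)))


@dataclass
class AggregateBurst:
    """A reference burst plus temporally matched bursts in other channels."""

    reference: Burst
    members: list[Burst] = field(default_factory=list)

    @property
    def all_bursts(self) -> list[Burst]:
        return [self.reference] + self.members

    @property
    def n_cycles(self) -> int:
        """Cycle count of the reference burst only (no double counting)."""
        return self.reference.n_cycles

    @property
    def mean_frequency_hz(self) -> float:
        return float(np.mean([burst_frequency(b) for b in self.all_bursts]))

    @property
    def mean_amplitude(self) -> float:
        """Mean over all cycles pooled across member channels."""
        amps = [c.amplitude for b in self.all_bursts for c in b.cycles]
        return float(np.mean(amps))

    @property
    def band(self) -> str:
        return band_assign(self.mean_frequency_hz)


def band_assign(freq_hz: float, theta=(4.0, 8.0), alpha=(8.0, 12.0)) -> str:
    """Assign theta / alpha / other by mean frequency; bands half-open [lo, hi)."""
    if theta[0] <= freq_hz < theta[1]:
        return "theta"
    if alpha[0] <= freq_hz < alpha[1]:
        return "alpha"
    return "other"


def aggregate_across_channels(
    per_channel_bursts: list[list[Burst]],
    min_overlap: float = 0.5,
    max_freq_diff_hz: float = 1.0,
    overlap_cycles_only: bool = True,
) -> list[AggregateBurst]:
    """Greedily group per-channel bursts into cross-channel aggregates.

    Seeded by the longest unassigned burst; a candidate from another channel
    joins when its overlap with the reference covers at least
    ``min_overlap`` of the candidate's own duration and the two mean
    frequencies (computed over the overlapping cycles when
    ``overlap_cycles_only``) differ by at most ``max_freq_diff_hz``.  Each
    burst belongs to exactly one aggregate.
    """
    pool = [b for bursts in per_channel_bursts for b in bursts]
    pool.sort(key=lambda b: (-b.n_cycles, -(b.end_idx - b.start_idx), b.start_idx))
    assigned = [False] * len(pool)
    aggregates: list[AggregateBurst] = []
    for i, ref in enumerate(pool):
        if assigned[i]:
            continue
        assigned[i] = True
        agg = AggregateBurst(reference=ref)
        for j in range(i + 1, len(pool)):
            if assigned[j]:
                continue
            cand = pool[j]
            if cand.channel == ref.channel:
                continue
            lo = max(ref.start_idx, cand.start_idx)
            hi = min(ref.end_idx, cand.end_idx)
            overlap = max(0, hi - lo)
            if overlap / (cand.end_idx - cand.start_idx) < min_overlap:
                continue
            if overlap_cycles_only:
                f_ref = _overlap_frequency(ref, lo, hi)
                f_cand = _overlap_frequency(cand, lo, hi)
            else:
                f_ref = burst_frequency(ref)
                f_cand = burst_frequency(cand)
            if abs(f_ref - f_cand) > max_freq_diff_hz:
                continue
            agg.members.append(cand)
            assigned[j] = True
        aggregates.append(agg)
    aggregates.sort(key=lambda a: a.reference.start_idx)
    return aggregates


@dataclass
class RecordingBurstMetrics:
    """Per-band summary of one recording; None marks an empty band."""

    band: str
    n_bursts: int
    mean_amplitude: float | None
    cycles_per_minute: float | None
    occupancy: float | None


def recording_metrics(
    aggregates: list[AggregateBurst],
    duration_s: float,
    bands: tuple[str, ...] = ("theta", "alpha"),
) -> dict[str, RecordingBurstMetrics]:
    """Recording-level amplitude / quantity / occupancy metrics per band."""
    if duration_s <= 0:
        raise ValueError("recording duration must be positive")
    out: dict[str, RecordingBurstMetrics] = {}
    for band in bands:
        in_band = [a for a in aggregates if a.band == band]
        if not in_band:
            out[band] = RecordingBurstMetrics(band, 0, None, None, None)
            continue
        amplitude = float(np.mean([a.mean_amplitude for a in in_band]))
        total_cycles = sum(a.n_cycles for a in in_band)
        ref_seconds = sum(a.reference.duration_s for a in in_band)
        out[band] = RecordingBurstMetrics(
            band=band,
            n_bursts=len(in_band),
            mean_amplitude=amplitude,
            cycles_per_minute=total_cycles / (duration_s / 60.0),
            occupancy=ref_seconds / duration_s,
        )
    return out


def bursts_to_frame(bursts: list[Burst]) -> pd.DataFrame:
    """One row per burst, ready for CSV export."""
    return pd.DataFrame(
        {
            "channel": [b.channel for b in bursts],
            "band": [b.band_label for b in bursts],
            "polarity": ["inverted" if b.inverted else "direct" for b in bursts],
            "start_s": [b.start_s for b in bursts],
            "end_s": [b.end_s for b in bursts],
            "n_cycles": [b.n_cycles for b in bursts],
            "mean_freq_hz": [burst_frequency(b) for b in bursts],
            "mean_amp_uV": [b.mean_amplitude for b in bursts],
        }
    )


def aggregates_to_frame(aggregates: list[AggregateBurst]) -> pd.DataFrame:
    """One row per aggregate, ready for CSV export."""
    return pd.DataFrame(
        {
            "ref_channel": [a.reference.channel for a in aggregates],
            "member_channels": [
                ";".join(str(m.channel) for m in a.members) for a in aggregates
            ],
            "band": [a.band for a in aggregates],
            "start_s": [a.reference.start_s for a in aggregates],
            "end_s": [a.reference.end_s for a in aggregates],
            "n_cycles": [a.n_cycles for a in aggregates],
            "mean_freq_hz": [a.mean_frequency_hz for a in aggregates],
            "mean_amp_uV": [a.mean_amplitude for a in aggregates],
        }
    )
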