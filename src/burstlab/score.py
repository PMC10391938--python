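"""Score detector output against synthetic ground truth.

Intervals match when the overlap covers at least half of the shorter of
the two intervals.  Sensitivity is the fraction of ground-truth bursts
matched by any detection in the same channel; precision the fraction of
detections matched by any ground-truth burst.
"""

from __future__ import annotations

from dataclasses import dataclass

from .detect import Burst
from .synth import GroundTruthBurst

__all__ = ["DetectionScore", "match_score"]


@dataclass(frozen=True)
class DetectionScore:
    n_truth: int
    n_detected: int
    n_truth_matched: int
    n_detected_matched: int

    @property
    def sensitivity(self) -> float:
        return self.n_truth_matched / self.n_truth if self.n_truth else float("nan")

    @property
    def precision(self) -> float:
        return (
            self.n_detected_matched / self.n_detected
            if self.n_detected
            else float("nan")
        )


def _matched(t0: float, t1: float, b0: float, b1: float, frac: float) -> bool:
    overlap = min(t1, b1) - max(t0, b0)
    return overlap >= frac * min(t1 - t0, b1 - b0)


def match_score(
    truth: list[GroundTruthBurst],
    detected: list[Burst],
    min_overlap: float = 0.5,
) -> DetectionScore:
    """Match detected bursts to ground truth by >= 50% interval overlap."""
    truth_hit = sum(
        any(
            b.channel == t.channel
            and _matched(t.onset_s, t.end_s, b.start_s, b.end_s, min_overlap)
            for b in detected
        )
        for t in truth
    )
    det_hit = sum(
        any(
            b.channel == t.channel
            and _matched(t.onset_s, t.end_s, b.start_s, b.end_s, min_overlap)
            for t in truth
        )
        for b in detected
    )
    return DetectionScore(
        n_truth=len(truth),
        n_detected=len(detected),
        n_truth_matched=truth_hit,
        n_detected_matched=det_hit,
    )
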