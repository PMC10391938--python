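"""Pupillometry: eye-closure detection, calibration, cleaning, oddball responses.

Eye closures are read off the pupil model's confidence trace: confidence
below 0.5 means closed, with 50 ms hysteresis in both directions (short
confident gaps inside a closure stay closed, then short isolated dips stay
open).  Closures shorter than 1 s are blinks; longer ones are ocular
microsleeps.  Pixel diameters are converted to millimetres by anchoring the
participant's imaged iris to the 12 mm human mean iris.  Oddball pupil
responses are baseline-corrected epochs around tone onsets; the response is
the area under the target-minus-standard difference curve from 0.5 to 2 s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ClosureEvent",
    "IrisCalibration",
    "OddballResponse",
    "detect_closures",
    "classify_closures",
    "px_to_mm",
    "clean_trace",
    "resample_trace",
    "oddball_response",
    "participant_responses",
]


@dataclass(frozen=True)
class ClosureEvent:
    start_s: float
    duration_s: float
    kind: str = ""  # "blink" | "microsleep" after classification


@dataclass(frozen=True)
class IrisCalibration:
    """Pixel-to-millimetre anchor for one eye video."""

    video_width_px: float
    video_width_cm: float
    iris_cm: float
    standard_iris_mm: float = 12.0

    def __post_init__(self) -> None:
        if min(
            self.video_width_px,
            self.video_width_cm,
            self.iris_cm,
            self.standard_iris_mm,
        ) <= 0:
            raise ValueError("all calibration fields must be positive")


def px_to_mm(diameter_px, cal: IrisCalibration):
    """mm = px * width_cm * standard_iris_mm / (iris_cm * width_px)."""
    return (
        np.asarray(diameter_px, dtype=float)
        * cal.video_width_cm
        * cal.standard_iris_mm
        / (cal.iris_cm * cal.video_width_px)
    )


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) index runs where mask is True."""
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[::2], edges[1::2]))


def detect_closures(
    confidence: np.ndarray,
    fs_hz: float,
    threshold: float = 0.5,
    hysteresis_s: float = 0.05,
) -> list[ClosureEvent]:
    """Detect eye closures from a uniformly sampled confidence trace.

    Below-threshold runs are closures.  Hysteresis is applied in the
    quoted order: confident interruptions shorter than ``hysteresis_s``
    inside a closure are merged into it first, then remaining closures
    shorter than ``hysteresis_s`` are discarded as still-open.
    """
    conf = np.asarray(confidence, dtype=float)
    closed = conf < threshold
    min_run = hysteresis_s * fs_hz  # compare run lengths in samples
    # pass 1: short open runs between closures become closed
    for start, end in _runs(~closed):
        if end - start < min_run and start > 0 and end < len(closed):
            closed[start:end] = True
    # pass 2: short closed runs are discarded
    for start, end in _runs(closed):
        if end - start < min_run:
            closed[start:end] = False
    return [
        ClosureEvent(start_s=start / fs_hz, duration_s=(end - start) / fs_hz)
        for start, end in _runs(closed)
    ]


def classify_closures(
    events: list[ClosureEvent],
    recording_duration_s: float,
    blink_cutoff_s: float = 1.0,
) -> tuple[list[ClosureEvent], float, float]:
    """Split closures into blinks (< 1 s) and microsleeps (>= 1 s).

    Returns ``(labelled events, blink rate per minute, microsleep
    fraction)`` where the fraction is the share of the recording spent in
    microsleep closures.
    """
    if recording_duration_s <= 0:
        raise ValueError("recording duration must be positive")
    labelled = [
        ClosureEvent(
            e.start_s,
            e.duration_s,
            "blink" if e.duration_s < blink_cutoff_s else "microsleep",
        )
        for e in events
    ]
    n_blinks = sum(1 for e in labelled if e.kind == "blink")
    ms_time = sum(e.duration_s for e in labelled if e.kind == "microsleep")
    return (
        labelled,
        n_blinks / (recording_duration_s / 60.0),
        ms_time / recording_duration_s,
    )


def resample_trace(trace: pd.DataFrame, fs_out: float = 50.0) -> pd.DataFrame:
    """Linearly resample a (possibly irregular) trace onto a uniform grid."""
    t = trace["time_s"].to_numpy()
    grid = np.arange(t[0], t[-1], 1.0 / fs_out)
    out = {"time_s": grid}
    for col in trace.columns:
        if col != "time_s":
            out[col] = np.interp(grid, t, trace[col].to_numpy())
    return pd.DataFrame(out)


def clean_trace(
    trace: pd.DataFrame,
    fs_hz: float,
    gap_s: float = 0.5,
    confidence_threshold: float = 0.5,
) -> pd.DataFrame:
    """Handle low-confidence gaps in a uniformly sampled diameter trace.

    First pass: invalid (low-confidence) gaps shorter than ``gap_s`` are
    linearly interpolated from their valid endpoints.  Second pass: valid
    islands shorter than ``gap_s`` that survive between remaining gaps are
    deleted.  Deleted samples carry NaN diameters in the returned copy.
    A fully invalid trace comes back all-NaN.
    """
    out = trace.copy()
    diam = out["diameter_px"].to_numpy(dtype=float).copy()
    valid = out["confidence"].to_numpy() >= confidence_threshold
    max_gap = int(round(gap_s * fs_hz))
    if not valid.any():
        out["diameter_px"] = np.nan
        return out
    idx = np.arange(len(diam))
    # pass 1: interpolate short invalid gaps (interior only)
    for start, end in _runs(~valid):
        if end - start < max_gap and start > 0 and end < len(diam):
            diam[start:end] = np.interp(
                idx[start:end], [start - 1, end], [diam[start - 1], diam[end]]
            )
            valid[start:end] = True
    # pass 2: remove short isolated valid islands
    for start, end in _runs(valid):
        if end - start < max_gap:
            valid[start:end] = False
    diam[~valid] = np.nan
    out["diameter_px"] = diam
    return out


@dataclass
class OddballResponse:
    """Averaged target/standard pupil time courses for one session."""

    times_s: np.ndarray
    target_mean: np.ndarray  # baseline-corrected, diameter units (or z)
    standard_mean: np.ndarray
    n_target_trials: int
    n_standard_trials: int
    excluded: bool
    exclusion_reason: str = ""

    def auc(self, lo_s: float = 0.5, hi_s: float = 2.0) -> float:
        """Trapezoidal area of (target - standard) over [lo_s, hi_s]."""
        sel = (self.times_s >= lo_s) & (self.times_s <= hi_s)
        diff = self.target_mean[sel] - self.standard_mean[sel]
        return float(np.trapezoid(diff, self.times_s[sel]))


def _epoch(
    time: np.ndarray,
    diam: np.ndarray,
    onsets: np.ndarray,
    fs_hz: float,
    pre_s: float,
    post_s: float,
) -> tuple[np.ndarray, np.ndarray]:
    n_pre = int(round(pre_s * fs_hz))
    n_post = int(round(post_s * fs_hz))
    offsets = np.arange(-n_pre, n_post + 1)
    rel_t = offsets / fs_hz
    trials = np.full((len(onsets), len(offsets)), np.nan)
    for i, onset in enumerate(onsets):
        center = int(round((onset - time[0]) * fs_hz))
        lo, hi = center - n_pre, center + n_post + 1
        if lo < 0 or hi > len(diam):
            continue
        trials[i] = diam[lo:hi]
    return rel_t, trials


def oddball_response(
    trace: pd.DataFrame,
    events: pd.DataFrame,
    fs_hz: float = 50.0,
    pre_s: float = 0.5,
    post_s: float = 2.0,
    min_clean_fraction: float = 2.0 / 3.0,
    min_trials: int = 15,
    min_trials_per_timepoint: int = 10,
) -> OddballResponse:
    """Per-session oddball pupil response with the standard exclusion rules.

    Epochs all target tones plus the standard immediately preceding each
    target, baseline-corrects each trial by its mean over [-pre_s, 0),
    drops trials with fewer than ``min_clean_fraction`` clean timepoints,
    and marks the whole session excluded when either tone type retains
    fewer than ``min_trials`` trials or any averaged timepoint would pool
    fewer than ``min_trials_per_timepoint``.  Averages are in the trace's
    diameter units; z-scoring happens at the participant level.
    """
    time = trace["time_s"].to_numpy()
    diam = trace["diameter_px"].to_numpy(dtype=float)
    is_target = events["type"].to_numpy() == "target"
    target_onsets = events.loc[is_target, "onset_s"].to_numpy()
    target_pos = np.flatnonzero(is_target)
    prior_std_pos = [p - 1 for p in target_pos if p > 0 and not is_target[p - 1]]
    standard_onsets = events["onset_s"].to_numpy()[prior_std_pos]

    rel_t, tgt = _epoch(time, diam, target_onsets, fs_hz, pre_s, post_s)
    _, std = _epoch(time, diam, standard_onsets, fs_hz, pre_s, post_s)

    baseline_sel = rel_t < 0

    def _clean(trials: np.ndarray) -> np.ndarray:
        keep = []
        for row in trials:
            if np.mean(np.isfinite(row)) < min_clean_fraction:
                continue
            base = np.nanmean(row[baseline_sel])
            if not np.isfinite(base):
                continue
            keep.append(row - base)
        return np.asarray(keep) if keep else np.empty((0, len(rel_t)))

    tgt_c, std_c = _clean(tgt), _clean(std)
    reason = ""
    if len(tgt_c) < min_trials or len(std_c) < min_trials:
        reason = f"fewer than {min_trials} usable trials for a tone type"
    else:
        for name, arr in (("target", tgt_c), ("standard", std_c)):
            per_tp = np.sum(np.isfinite(arr), axis=0)
            if per_tp.min() < min_trials_per_timepoint:
                reason = (
                    f"a {name} timepoint pools fewer than "
                    f"{min_trials_per_timepoint} trials"
                )
                break
    with np.errstate(invalid="ignore"):
        tgt_mean = np.nanmean(tgt_c, axis=0) if len(tgt_c) else np.full_like(rel_t, np.nan)
        std_mean = np.nanmean(std_c, axis=0) if len(std_c) else np.full_like(rel_t, np.nan)
    return OddballResponse(
        times_s=rel_t,
        target_mean=tgt_mean,
        standard_mean=std_mean,
        n_target_trials=len(tgt_c),
        n_standard_trials=len(std_c),
        excluded=bool(reason),
        exclusion_reason=reason,
    )


def participant_responses(
    sessions: dict[str, OddballResponse],
    min_sessions: int = 6,
    expected_sessions: int = 12,
) -> tuple[pd.DataFrame, bool]:
    """Participant-level z-scoring and AUC responses across sessions.

    Non-excluded session courses are z-scored jointly across timepoints,
    tone types and sessions within the participant, then each session's
    response is the trapezoidal area of (target - standard) over 0.5-2 s,
    in z·s.  Returns ``(table, participant_excluded)``; the participant is
    excluded when fewer than ``min_sessions`` of ``expected_sessions``
    sessions survive.
    """
    usable = {k: r for k, r in sessions.items() if not r.excluded}
    participant_excluded = len(usable) < min_sessions
    if not usable:
        return pd.DataFrame(columns=["session", "response_zs"]), True
    pooled = np.concatenate(
        [np.concatenate([r.target_mean, r.standard_mean]) for r in usable.values()]
    )
    mu = np.nanmean(pooled)
    sd = np.nanstd(pooled, ddof=1)
    rows = []
    for name, r in usable.items():
        z = OddballResponse(
            times_s=r.times_s,
            target_mean=(r.target_mean - mu) / sd,
            standard_mean=(r.standard_mean - mu) / sd,
            n_target_trials=r.n_target_trials,
            n_standard_trials=r.n_standard_trials,
            excluded=False,
        )
        rows.append({"session": name, "response_zs": z.auc()})
    return pd.DataFrame(rows), participant_excluded
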