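"""Synthetic EEG, oddball, pupil, and study-level fixtures with ground truth.

Every generator here is a pure function of its seed and emulates one layer
of the data the detection and statistics pipelines assume:

* a 1/f aperiodic EEG background (spectral shaping of white noise, so the
  target log-log PSD slope is exact and there are no filter transients);
* narrowband oscillation bursts of known channel, frequency, cycle count
  and peak-to-peak amplitude inserted into that background;
* auditory oddball tone sequences (160 standards / 40 targets, inter-onset
  intervals uniform on 1.8-2.4 s, at least 3 standards between targets);
* pupil diameter/confidence traces with blinks, prolonged eye closures
  ("ocular microsleeps") and event-locked dilations;
* session-level outcome tables following a saturating-exponential build-up
  with an evening dip (the wake-maintenance-zone signature) plus noise.

Ground-truth tables exactly describe the emitted signal, so detector and
pipeline outputs can be scored against them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GroundTruthBurst",
    "BurstSpec",
    "OddballSequence",
    "StudySimulationConfig",
    "DEFAULT_SCHEDULE",
    "gen_aperiodic_eeg",
    "insert_bursts",
    "gen_oddball_sequence",
    "gen_pupil_trace",
    "gen_study",
    "simulate_study_values",
    "gen_burst_recording",
]


# ---------------------------------------------------------------------------
# aperiodic background


def gen_aperiodic_eeg(
    duration_s: float,
    fs_hz: float,
    exponent: float = 1.0,
    scale_uV: float = 10.0,
    n_channels: int = 1,
    seed: int = 0,
) -> np.ndarray:
    """Generate 1/f^exponent background EEG, shape (n_channels, n_samples).

    White Gaussian noise is shaped in the frequency domain by
    ``f**(-exponent/2)`` (power slope ``-exponent`` in log-log) and scaled
    to an RMS of ``scale_uV`` per channel.  ``exponent=0`` gives white
    noise.
    """
    if duration_s <= 0:
        raise ValueError(f"duration_s must be positive, got {duration_s}")
    if fs_hz < 100:
        raise ValueError(f"fs_hz must be >= 100, got {fs_hz}")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs_hz))
    white = rng.standard_normal((n_channels, n))
    spectrum = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs_hz)
    shaping = np.ones_like(freqs)
    nonzero = freqs > 0
    shaping[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC
    shaped = np.fft.irfft(spectrum * shaping, n=n, axis=-1)
    rms = np.sqrt(np.mean(shaped**2, axis=-1, keepdims=True))
    rms[rms == 0] = 1.0
    return shaped / rms * scale_uV


# ---------------------------------------------------------------------------
# burst insertion


@dataclass(frozen=True)
class BurstSpec:
    """Request for one inserted burst.

    ``n_cycles`` counts the detectable interior cycles; the rendered
    waveform adds one full-amplitude shoulder cycle on each side (plus
    quarter-cycle onset/offset ramps) because the outermost cycles of any
    finite burst necessarily fail the neighbour-pairwise amplitude
    criterion and would otherwise be lost from the count.
    """

    channel: int
    freq_hz: float
    onset_s: float
    n_cycles: int
    amplitude_uV: float

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.amplitude_uV <= 0:
            raise ValueError("amplitude must be positive")
        if self.freq_hz <= 0:
            raise ValueError("frequency must be positive")

    @property
    def rendered_duration_s(self) -> float:
        """Physical footprint: n + 2 shoulder cycles + two quarter ramps."""
        return (self.n_cycles + 2 + 0.5) / self.freq_hz


@dataclass(frozen=True)
class GroundTruthBurst:
    """What the detector should recover for one inserted burst."""

    channel: int
    band_label: str
    onset_s: float
    n_cycles: int
    amplitude_uV: float
    freq_hz: float

    @property
    def end_s(self) -> float:
        return self.onset_s + self.n_cycles / self.freq_hz


def _render_burst(
    spec: BurstSpec, fs_hz: float, asymmetry: float, envelope: str = "flat"
) -> tuple[np.ndarray, float]:
    """Render one burst waveform; returns (samples, counted-run onset offset).

    The carrier is a sinusoid whose phase is piecewise-linearly time-warped
    so that each descending flank (positive to negative peak) takes a
    fraction ``(1 - asymmetry) / 2`` of the cycle; ``asymmetry > 0`` gives
    mu-like sharp descents.  The envelope ramps up over the leading quarter
    cycle, is flat across all full cycles, and ramps down over the trailing
    quarter cycle, so every interior cycle has the full requested
    peak-to-peak amplitude.
    """
    if not (0.0 <= asymmetry < 1.0):
        raise ValueError("asymmetry must be in [0, 1)")
    T = 1.0 / spec.freq_hz
    m = spec.n_cycles + 2  # physical cycles incl. shoulders
    # phase breakpoints: ascending zero, then alternating pos/neg peaks,
    # ending at the descending zero after the last positive peak
    bp_phase = [0.0, math.pi / 2]
    bp_time = [0.0, T / 4]
    t = T / 4
    for _ in range(m):
        t += (1.0 - asymmetry) * T / 2
        bp_time.append(t)
        bp_phase.append(bp_phase[-1] + math.pi)  # negative peak
        t += (1.0 + asymmetry) * T / 2
        bp_time.append(t)
        bp_phase.append(bp_phase[-1] + math.pi)  # positive peak
    t_end = t + (1.0 - asymmetry) * T / 4
    bp_time.append(t_end)
    bp_phase.append(bp_phase[-1] + math.pi / 2)

    n_samp = int(round(t_end * fs_hz))
    tt = np.arange(n_samp) / fs_hz
    phase = np.interp(tt, bp_time, bp_phase)
    if envelope == "hann":
        # tapers every cycle; neighbouring cycle amplitudes then violate
        # the amplitude-consistency criterion near the edges, which is
        # exactly what this envelope is kept around to demonstrate
        wave = 0.5 * spec.amplitude_uV * np.sin(phase)
        wave *= np.hanning(n_samp)
        return wave, bp_time[3]
    if envelope != "flat":
        raise ValueError(f"unknown envelope {envelope!r}")
    env = np.ones(n_samp)
    ramp_in = tt < bp_time[1]
    env[ramp_in] = np.sin(0.5 * math.pi * tt[ramp_in] / bp_time[1]) ** 2
    t_last_pos = bp_time[-2]
    ramp_out = tt > t_last_pos
    env[ramp_out] = (
        np.sin(0.5 * math.pi * (t_end - tt[ramp_out]) / (t_end - t_last_pos)) ** 2
    )
    # One-sided notch at the second positive peak (start of the counted
    # run): without it the inverted-polarity parse, whose cycles sit half a
    # period offset, finds one more full-amplitude cycle than requested.
    # Dipping this peak to 0.15 of full scale breaks the inverted run's
    # amplitude-consistency chain by exactly one cycle while the direct
    # run keeps its rise/decay ratio above threshold.
    # (the notch scales the whole positive lobe, phase 2pi..3pi, so the
    # raw-trace argmax cannot escape to the lobe's shoulders)
    lobe = (phase > 2 * math.pi) & (phase < 3 * math.pi)
    env = np.where(lobe, 0.15 * env, env)
    wave = 0.5 * spec.amplitude_uV * np.sin(phase) * env
    # counted run starts at the second positive peak (after one shoulder)
    counted_onset = bp_time[3]
    return wave, counted_onset


def insert_bursts(
    background: np.ndarray,
    fs_hz: float,
    burst_specs: list[BurstSpec],
    waveform_asymmetry: float = 0.0,
    envelope: str = "flat",
    band_label_of: dict[int, str] | None = None,
) -> tuple[np.ndarray, list[GroundTruthBurst]]:
    """Add burst waveforms to a (channels, samples) background.

    Burst footprints must fit inside the recording and must not overlap
    within a channel.  Returns the summed signal and the ground-truth
    table; ground-truth onsets refer to the first counted cycle, not to the
    start of the physical footprint (see :class:`BurstSpec`).
    """
    background = np.atleast_2d(np.asarray(background, dtype=float))
    n_channels, n_samples = background.shape
    spans: dict[int, list[tuple[float, float]]] = {}
    for spec in burst_specs:
        if not 0 <= spec.channel < n_channels:
            raise ValueError(f"channel {spec.channel} outside signal")
        end = spec.onset_s + spec.rendered_duration_s
        if spec.onset_s < 0 or end > n_samples / fs_hz:
            raise ValueError(
                f"burst at {spec.onset_s:.3f}s does not fit inside the recording"
            )
        for lo, hi in spans.setdefault(spec.channel, []):
            if spec.onset_s < hi and end > lo:
                raise ValueError(
                    f"overlapping burst specs in channel {spec.channel}"
                )
        spans[spec.channel].append((spec.onset_s, end))

    signal = background.copy()
    truth: list[GroundTruthBurst] = []
    for spec in burst_specs:
        wave, counted_onset = _render_burst(spec, fs_hz, waveform_asymmetry, envelope)
        start = int(round(spec.onset_s * fs_hz))
        signal[spec.channel, start : start + len(wave)] += wave
        label = ""
        if band_label_of is not None:
            label = band_label_of.get(spec.channel, "")
        truth.append(
            GroundTruthBurst(
                channel=spec.channel,
                band_label=label or _default_band_label(spec.freq_hz),
                onset_s=spec.onset_s + counted_onset,
                n_cycles=spec.n_cycles,
                amplitude_uV=spec.amplitude_uV,
                freq_hz=spec.freq_hz,
            )
        )
    return signal, truth


def _default_band_label(freq_hz: float) -> str:
    if 4 <= freq_hz < 8:
        return "theta"
    if 8 <= freq_hz < 12:
        return "alpha"
    return "other"


# ---------------------------------------------------------------------------
# oddball sequences


@dataclass(frozen=True)
class OddballSequence:
    """Tone onsets and types for one oddball session."""

    onsets_s: tuple[float, ...]
    types: tuple[str, ...]  # "standard" | "target"
    seed: int

    @property
    def n_standard(self) -> int:
        return sum(1 for t in self.types if t == "standard")

    @property
    def n_target(self) -> int:
        return sum(1 for t in self.types if t == "target")

    def min_gap_between_targets(self) -> int:
        """Minimum number of standards between consecutive targets."""
        target_pos = [i for i, t in enumerate(self.types) if t == "target"]
        if len(target_pos) < 2:
            return len(self.types)
        return min(b - a - 1 for a, b in zip(target_pos, target_pos[1:]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"onset_s": self.onsets_s, "type": self.types})


def gen_oddball_sequence(
    n_standard: int = 160,
    n_target: int = 40,
    isi_min: float = 1.8,
    isi_max: float = 2.4,
    min_gap: int = 3,
    seed: int = 0,
) -> OddballSequence:
    """Generate an oddball tone sequence.

    Target positions are drawn uniformly over all arrangements with at
    least ``min_gap`` standards between consecutive targets (no constraint
    before the first or after the last target); inter-onset intervals are
    i.i.d. uniform on ``[isi_min, isi_max]``; the first tone is at t=0.
    """
    if n_target > 0 and n_standard < min_gap * (n_target - 1):
        raise ValueError(
            f"cannot place {n_target} targets with {min_gap} standards "
            f"between them using only {n_standard} standards"
        )
    if isi_min > isi_max or isi_min <= 0:
        raise ValueError("need 0 < isi_min <= isi_max")
    rng = np.random.default_rng(seed)
    n_total = n_standard + n_target
    if n_target == 0:
        types = ["standard"] * n_total
    elif n_target == n_total:
        types = ["target"] * n_total
    else:
        # uniform composition of the spare standards into the n_target + 1
        # gaps around targets (interior gaps already hold min_gap each)
        spare = n_standard - min_gap * (n_target - 1)
        n_gaps = n_target + 1
        # stars and bars: choose bar positions among spare + n_gaps - 1 slots
        bars = np.sort(
            rng.choice(spare + n_gaps - 1, size=n_gaps - 1, replace=False)
        )
        extras = np.diff(np.concatenate(([-1], bars, [spare + n_gaps - 1]))) - 1
        types = []
        for g in range(n_gaps):
            base = min_gap if 1 <= g <= n_gaps - 2 else 0
            types.extend(["standard"] * (base + int(extras[g])))
            if g < n_gaps - 1:
                types.append("target")
    isis = rng.uniform(isi_min, isi_max, size=n_total - 1)
    onsets = np.concatenate(([0.0], np.cumsum(isis)))
    return OddballSequence(tuple(onsets), tuple(types), seed)


# ---------------------------------------------------------------------------
# pupil traces


def gen_pupil_trace(
    duration_s: float,
    fs_hz: float = 50.0,
    baseline_mm: float = 4.0,
    blink_rate_per_min: float = 10.0,
    microsleep_fraction: float = 0.0,
    event_responses: list[tuple[float, float]] | None = None,
    noise_sd: float = 0.0,
    px_per_mm: float = 256.0 / 45.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a pupil trace and its ground-truth closure table.

    Returns ``(trace, closures)``: ``trace`` has columns time_s,
    diameter_px, confidence (50 Hz by default); ``closures`` has start_s,
    duration_s, kind ("blink" < 1 s, "microsleep" >= 1 s), snapped to the
    sample grid so downstream counts are exactly recoverable.  Closures are
    encoded as confidence 0.05 spans (0.95 when open).  ``event_responses``
    is a list of (onset_s, amplitude_mm) transient dilations with a gamma-
    like kernel peaking ~0.9 s after onset.  The default ``px_per_mm``
    matches a 192 px / 4.5 cm video frame with a 1.2 cm iris under the
    12 mm standard-iris convention.
    """
    if duration_s <= 0 or fs_hz <= 0:
        raise ValueError("duration and sampling rate must be positive")
    if blink_rate_per_min < 0 or noise_sd < 0:
        raise ValueError("rates and noise must be non-negative")
    if not (0.0 <= microsleep_fraction < 1.0):
        raise ValueError("microsleep_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs_hz))
    time = np.arange(n) / fs_hz

    # draw closure durations: blinks then microsleeps
    n_blinks = rng.poisson(blink_rate_per_min * duration_s / 60.0)
    durations = list(rng.uniform(0.1, 0.8, size=n_blinks))
    kinds = ["blink"] * n_blinks
    if microsleep_fraction > 0:
        target = microsleep_fraction * duration_s
        n_ms = max(1, int(round(target / 2.0)))
        raw_d = rng.uniform(1.0, 3.0, size=n_ms)
        raw_d *= target / raw_d.sum()
        raw_d = np.maximum(raw_d, 1.02)  # stay microsleeps after snapping
        durations += list(raw_d)
        kinds += ["microsleep"] * n_ms

    # place without overlap, keeping >= 0.2 s open time between closures
    placed: list[tuple[int, int, str]] = []  # (start_idx, n_samp, kind)
    occupied: list[tuple[float, float]] = []
    order = rng.permutation(len(durations))
    for k in order:
        dur = durations[k]
        for _ in range(200):
            start = rng.uniform(0.5, duration_s - dur - 0.5)
            if not any(
                start < hi + 0.2 and start + dur + 0.2 > lo for lo, hi in occupied
            ):
                occupied.append((start, start + dur))
                s_idx = int(round(start * fs_hz))
                n_samp = max(1, int(round(dur * fs_hz)))
                placed.append((s_idx, n_samp, kinds[k]))
                break

    confidence = np.full(n, 0.95)
    for s_idx, n_samp, _ in placed:
        confidence[s_idx : s_idx + n_samp] = 0.05

    diameter_mm = np.full(n, baseline_mm)
    if event_responses:
        tau = 0.9
        for onset, amp in event_responses:
            rel = time - onset
            mask = rel > 0
            diameter_mm[mask] += amp * (rel[mask] / tau) * np.exp(1 - rel[mask] / tau)
    if noise_sd > 0:
        diameter_mm = diameter_mm + rng.normal(0.0, noise_sd, size=n)

    trace = pd.DataFrame(
        {
            "time_s": time,
            "diameter_px": diameter_mm * px_per_mm,
            "confidence": confidence,
        }
    )
    placed.sort()
    closures = pd.DataFrame(
        {
            "start_s": [s / fs_hz for s, _, _ in placed],
            "duration_s": [m / fs_hz for _, m, _ in placed],
            "kind": [
                "blink" if m / fs_hz < 1.0 else "microsleep" for _, m, _ in placed
            ],
        }
    )
    return trace, closures


# ---------------------------------------------------------------------------
# study-level session tables


#: Session clock times in decimal hours on a continuous axis (next-day
#: sessions offset by +24 h); S5-S8 are the wake-maintenance-zone anchors.
DEFAULT_SCHEDULE: dict[str, float] = {
    "S1": 4.0,
    "S2": 7.0,
    "S3": 10.0,
    "S4": 13.5,
    "S5": 17.5,
    "S6": 20.0,
    "S7": 23.0,
    "S8": 26.0 + 40.0 / 60.0,
}


@dataclass(frozen=True)
class StudySimulationConfig:
    """Parameters of the session-level outcome simulation.

    Amplitude-like outcomes follow a saturating exponential of time awake,
    ``asymptote * (1 - exp(-rate * hours_awake))``, minus ``wmz_dip`` during
    the two evening sessions (S6, S7); quantity-like outcomes follow a
    linear trend.  Values are in z-like units; participants get an i.i.d.
    offset with SD ``between_sd`` and sessions i.i.d. noise ``noise_sd``.
    """

    n_participants: int = 18
    schedule: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SCHEDULE)
    )
    wake_time_h: float = 3.5
    asymptote: float = 2.0
    rate_per_h: float = 0.15
    wmz_dip: float = 1.0
    wmz_sessions: tuple[str, str] = ("S6", "S7")
    quantity_slope_per_h: float = 0.05
    between_sd: float = 0.5
    noise_sd: float = 0.5
    condition: str = "Fixation"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.between_sd < 0 or self.noise_sd < 0:
            raise ValueError("variances must be >= 0")
        times = list(self.schedule.values())
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("schedule times must be strictly increasing")
        if self.n_participants < 1:
            raise ValueError("need at least one participant")


def simulate_study_values(
    config: StudySimulationConfig,
    n_replicates: int = 1,
    seed: int | None = None,
) -> np.ndarray:
    """Amplitude-outcome values, shape (replicates, participants, sessions).

    Vectorized core shared by :func:`gen_study` and Monte-Carlo power /
    type-I simulations, so large replicate counts stay cheap.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sessions = list(config.schedule)
    t_awake = np.array([config.schedule[s] - config.wake_time_h for s in sessions])
    mean = config.asymptote * (1.0 - np.exp(-config.rate_per_h * t_awake))
    dip = np.array(
        [config.wmz_dip if s in config.wmz_sessions else 0.0 for s in sessions]
    )
    shape = (n_replicates, config.n_participants, len(sessions))
    offsets = rng.normal(0.0, config.between_sd, size=shape[:2])[..., None]
    noise = rng.normal(0.0, config.noise_sd, size=shape)
    return mean - dip + offsets + noise


def gen_study(
    config: StudySimulationConfig,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """One simulated study as a long-format session table.

    Returns ``(table, truth)``: ``table`` has columns participant,
    condition, session, clock_time_h, outcome, value with outcomes
    "amplitude" (saturating exponential + WMZ dip) and "quantity" (linear
    trend); ``truth`` records the generating parameters.
    """
    sessions = list(config.schedule)
    amp = simulate_study_values(config, n_replicates=1)[0]
    rng = np.random.default_rng(config.seed + 1)
    t_awake = np.array([config.schedule[s] - config.wake_time_h for s in sessions])
    qty_mean = config.quantity_slope_per_h * t_awake
    qty = (
        qty_mean
        + rng.normal(0.0, config.between_sd, size=(config.n_participants, 1))
        + rng.normal(0.0, config.noise_sd, size=(config.n_participants, len(sessions)))
    )
    rows = []
    for p in range(config.n_participants):
        for j, s in enumerate(sessions):
            for outcome, vals in (("amplitude", amp), ("quantity", qty)):
                rows.append(
                    {
                        "participant": f"P{p + 1:02d}",
                        "condition": config.condition,
                        "session": s,
                        "clock_time_h": config.schedule[s],
                        "outcome": outcome,
                        "value": vals[p, j],
                    }
                )
    truth = {
        "asymptote": config.asymptote,
        "rate_per_h": config.rate_per_h,
        "wmz_dip": config.wmz_dip,
        "quantity_slope_per_h": config.quantity_slope_per_h,
    }
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# full detection fixture


def gen_burst_recording(
    duration_s: float = 60.0,
    fs_hz: float = 250.0,
    n_bursts: int = 20,
    snr: float = 5.0,
    freq_range: tuple[float, float] = (4.5, 11.5),
    n_cycles_range: tuple[int, int] = (6, 12),
    exponent: float = 1.0,
    scale_uV: float = 10.0,
    n_channels: int = 1,
    margin_s: float = 5.5,
    min_gap_s: float = 0.5,
    seed: int = 0,
) -> tuple[np.ndarray, list[GroundTruthBurst]]:
    """A detector-validation recording: 1/f background plus known bursts.

    The background is band-limited to the conventional 0.5-40 Hz EEG range
    (the "minimally filtered" trace the detector expects).  Burst
    amplitudes are set per burst to ``snr`` times twice the background SD
    inside the narrowband covering the burst frequency, the stated
    signal-to-noise convention of this package.  Bursts are placed
    uniformly at random without overlap, ``margin_s`` clear of the
    recording edges (the detector discards filter-transient cycles there),
    and assigned round-robin to channels.  Defaults emulate a taxing-wake
    recording: ~45% of the analyzable window covered by theta/alpha bursts
    of 6-12 cycles.
    """
    from .filters import DEFAULT_BANDS, apply_band_filter, broadband_filter, design_band_filter

    rng = np.random.default_rng(seed)
    background = gen_aperiodic_eeg(
        duration_s, fs_hz, exponent, scale_uV, n_channels, seed=seed
    )
    background = broadband_filter(background, fs_hz)
    filters = {b.label: design_band_filter(b, fs_hz) for b in DEFAULT_BANDS}
    band_sds = {
        b.label: float(np.std(apply_band_filter(background[0], filters[b.label])[0]))
        for b in DEFAULT_BANDS
    }

    def _sd_for(freq: float) -> float:
        for b in DEFAULT_BANDS:
            if b.low_hz + 1 <= freq <= b.high_hz - 1:
                return band_sds[b.label]
        return float(np.std(background[0]))

    specs: list[BurstSpec] = []
    occupied: dict[int, list[tuple[float, float]]] = {}
    tries = 0
    while len(specs) < n_bursts and tries < 200 * n_bursts:
        tries += 1
        ch = len(specs) % n_channels
        freq = float(rng.uniform(*freq_range))
        n_cyc = int(rng.integers(n_cycles_range[0], n_cycles_range[1] + 1))
        onset = float(rng.uniform(margin_s, duration_s - margin_s - 2.0))
        spec = BurstSpec(ch, freq, onset, n_cyc, snr * 2.0 * _sd_for(freq))
        end = onset + spec.rendered_duration_s
        if end > duration_s - margin_s:
            continue
        if any(
            onset < hi + min_gap_s and end + min_gap_s > lo
            for lo, hi in occupied.get(ch, [])
        ):
            continue
        occupied.setdefault(ch, []).append((onset, end))
        specs.append(spec)
    if len(specs) < n_bursts:
        raise ValueError(
            f"could only place {len(specs)} of {n_bursts} bursts; "
            "reduce the count or lengthen the recording"
        )
    return insert_bursts(background, fs_hz, specs)
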