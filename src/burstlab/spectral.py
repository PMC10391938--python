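"""Welch power spectral density with pooled z-scoring and band averaging.

Power is computed per channel with Welch's method (8 s Hann windows, 75%
overlap, density scaling, 0.125 Hz resolution at the default window).  For
each participant and frequency bin, power is z-scored pooling over all
sessions, conditions and channels, which absorbs inter-individual
differences in absolute power; band summaries then average the z-scores
over retained channels (outer-edge electrodes excluded) and over the
frequency bins inside the band.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "EDGE_CHANNELS",
    "welch_psd",
    "spectra_to_frame",
    "zscore_power",
    "band_average",
]

#: Outer-edge electrodes excluded from channel averages (1-based labels of
#: a 129-electrode geodesic net).
EDGE_CHANNELS: tuple[int, ...] = (48, 63, 68, 73, 81, 88, 94, 99, 119)


def welch_psd(
    x: np.ndarray,
    fs_hz: float,
    window_s: float = 8.0,
    overlap: float = 0.75,
) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD of a 1-D or (channels, samples) signal.

    Hann-tapered modified periodograms with constant detrending and density
    normalization, so the PSD integrates to the signal variance.  Returns
    ``(freqs, psd)`` with psd shaped like the input channels.
    """
    x = np.asarray(x, dtype=float)
    nperseg = int(round(window_s * fs_hz))
    if x.shape[-1] < nperseg:
        raise ValueError(
            f"signal of {x.shape[-1]} samples shorter than one "
            f"{window_s} s window ({nperseg} samples)"
        )
    freqs, psd = sps.welch(
        x,
        fs=fs_hz,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(nperseg * overlap)),
        detrend="constant",
        scaling="density",
        axis=-1,
    )
    return freqs, psd


def spectra_to_frame(
    freqs: np.ndarray,
    psd: np.ndarray,
    participant: str,
    condition: str,
    session: str,
    channels: list[int] | None = None,
) -> pd.DataFrame:
    """Long-format PSD table: participant, condition, session, channel, freq, psd."""
    psd = np.atleast_2d(psd)
    n_channels = psd.shape[0]
    if channels is None:
        channels = list(range(1, n_channels + 1))
    rows = {
        "participant": np.repeat(participant, n_channels * len(freqs)),
        "condition": np.repeat(condition, n_channels * len(freqs)),
        "session": np.repeat(session, n_channels * len(freqs)),
        "channel": np.repeat(channels, len(freqs)),
        "freq_hz": np.tile(freqs, n_channels),
        "psd": psd.ravel(),
    }
    return pd.DataFrame(rows)


def zscore_power(spectra: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Z-score PSD per participant and frequency bin.

    The mean and SD pool over everything else — sessions, conditions and
    channels — so the transform is invariant to a global gain applied to
    all of a participant's recordings.  Frequency bins whose pooled SD is
    zero get NaN z-scores.  Adds a ``z`` column; input is not modified.
    """
    out = spectra.copy()

    def _z(g: pd.Series) -> pd.Series:
        sd = g.std(ddof=ddof)
        if not np.isfinite(sd) or sd == 0:
            return pd.Series(np.nan, index=g.index)
        return (g - g.mean()) / sd

    out["z"] = out.groupby(["participant", "freq_hz"])["psd"].transform(_z)
    return out


def band_average(
    zscored: pd.DataFrame,
    band: tuple[float, float],
    excluded_channels: tuple[int, ...] = EDGE_CHANNELS,
    value_col: str = "z",
) -> pd.DataFrame:
    """Band-average z-scored power per participant x session x condition.

    Retained channels are averaged first, then the frequency bins inside
    ``[low, high)``.  Raises if the band lies outside the frequency axis.
    """
    lo, hi = band
    fmin, fmax = zscored["freq_hz"].min(), zscored["freq_hz"].max()
    if lo >= fmax or hi <= fmin:
        raise ValueError(f"band {band} outside frequency axis [{fmin}, {fmax}]")
    sel = zscored[
        (~zscored["channel"].isin(excluded_channels))
        & (zscored["freq_hz"] >= lo)
        & (zscored["freq_hz"] < hi)
    ]
    keys = ["participant", "condition", "session"]
    per_freq = sel.groupby(keys + ["freq_hz"])[value_col].mean()
    return per_freq.groupby(keys).mean().rename("band_power").reset_index()
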