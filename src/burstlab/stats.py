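"""Session-level statistics: pooled z-scoring, paired tests, the
wake-maintenance-zone contrast, FDR, and power analysis.

All group tests are paired t-tests on values z-scored within participant
(pooling sessions and conditions), reported with Hedge's g, the
small-sample-corrected standardized mean difference of the paired
differences: g = J * mean(d) / SD(d) with J = 1 - 3 / (4*df - 1), df = n-1.

The wake-maintenance-zone (WMZ) contrast quantifies the evening dip of an
otherwise monotone trajectory: values at S5 (17:30) and S8 (02:40, next
day, i.e. 26:40 on a continuous axis) are linearly interpolated to 21:30
and compared against the observed mean of S6 (20:00) and S7 (23:00).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as spstats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PairedTestResult",
    "WMZ_TIMES",
    "zscore_outcomes",
    "paired_test",
    "wmz_contrast",
    "fdr_bh",
    "min_detectable_g",
    "hedges_correction",
]

#: Clock times (decimal hours, continuous axis) of the WMZ anchor sessions
#: and the interpolation target.
WMZ_TIMES: dict[str, float] = {
    "S5": 17.5,
    "S6": 20.0,
    "S7": 23.0,
    "S8": 26.0 + 40.0 / 60.0,
    "target": 21.5,
}


def hedges_correction(df: int) -> float:
    """Small-sample correction J = 1 - 3/(4*df - 1)."""
    return 1.0 - 3.0 / (4.0 * df - 1.0)


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    df: int
    p: float
    g: float
    degenerate: bool = False

    @property
    def n(self) -> int:
        return self.df + 1


def zscore_outcomes(
    table: pd.DataFrame,
    value_col: str = "value",
    participant_col: str = "participant",
    outcome_col: str = "outcome",
    ddof: int = 1,
) -> pd.DataFrame:
    """Z-score outcome values per participant, pooling sessions and conditions.

    Adds a ``z`` column.  A participant/outcome cell with zero pooled SD
    gets NaN (flagged missing rather than infinite).
    """
    out = table.copy()

    def _z(g: pd.Series) -> pd.Series:
        sd = g.std(ddof=ddof)
        if not np.isfinite(sd) or sd == 0:
            return pd.Series(np.nan, index=g.index)
        return (g - g.mean()) / sd

    keys = [participant_col]
    if outcome_col in table.columns:
        keys.append(outcome_col)
    out["z"] = out.groupby(keys)[value_col].transform(_z)
    return out


def paired_test(x: np.ndarray, y: np.ndarray) -> PairedTestResult:
    """Two-sided paired t-test with Hedge's g on pairwise-complete data."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 complete pairs")
    d = x - y
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0:
        return PairedTestResult(
            t=np.nan, df=df, p=np.nan, g=0.0 if d.mean() == 0 else np.nan,
            degenerate=True,
        )
    t_stat, p = spstats.ttest_rel(x, y)
    g = hedges_correction(df) * d.mean() / sd
    return PairedTestResult(t=float(t_stat), df=df, p=float(p), g=float(g))


def wmz_contrast(
    table: pd.DataFrame,
    value_col: str = "z",
    session_col: str = "session",
    participant_col: str = "participant",
    times: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, PairedTestResult]:
    """Per-participant WMZ dip statistic and its group paired test.

    For each participant with all four anchor sessions, the expected
    21:30 value is interpolated on the S5-S8 chord,
    ``expected = S5 + w * (S8 - S5)`` with
    ``w = (21.5 - 17.5) / (26.667 - 17.5)``, and the statistic is
    ``mean(S6, S7) - expected`` (negative = dip).  The group test pairs
    observed mean(S6, S7) against the expected value.  Participants with a
    missing anchor session are dropped.
    """
    times = times or WMZ_TIMES
    w = (times["target"] - times["S5"]) / (times["S8"] - times["S5"])
    wide = table.pivot_table(
        index=participant_col, columns=session_col, values=value_col
    )
    needed = ["S5", "S6", "S7", "S8"]
    missing_cols = [s for s in needed if s not in wide.columns]
    if missing_cols:
        raise ValueError(f"sessions missing from table: {missing_cols}")
    wide = wide.dropna(subset=needed)
    expected = wide["S5"] + w * (wide["S8"] - wide["S5"])
    observed = 0.5 * (wide["S6"] + wide["S7"])
    per_participant = pd.DataFrame(
        {
            "expected": expected,
            "observed": observed,
            "wmz_statistic": observed - expected,
        }
    )
    # the group test needs at least two participants with complete anchors
    test = (
        paired_test(observed.to_numpy(), expected.to_numpy())
        if len(per_participant) >= 2
        else None
    )
    return per_participant, test


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at FDR level q."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return np.zeros(0, dtype=bool)
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def _paired_power(d: float, n: int, alpha: float) -> float:
    """Power of a two-sided paired t-test at effect size d (Cohen's d_z)."""
    df = n - 1
    ncp = d * np.sqrt(n)
    t_crit = spstats.t.ppf(1.0 - alpha / 2.0, df)
    power = spstats.nct.sf(t_crit, df, ncp) + spstats.nct.cdf(-t_crit, df, ncp)
    if not np.isfinite(power):  # saturated noncentrality
        return 1.0
    return float(power)


def min_detectable_g(n: int, alpha: float = 0.05, power: float = 0.8) -> float:
    """Smallest detectable effect (Hedge's g) of a paired t-test.

    Inverts the noncentral-t power function for the smallest Cohen's d_z
    with two-sided power >= ``power`` at level ``alpha``, then applies the
    small-sample correction to express the bound on the g scale.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    hi = 0.5
    while _paired_power(hi, n, alpha) < power:
        hi *= 2.0
        if hi > 1e4:
            raise RuntimeError("power function failed to reach target")
    d = optimize.brentq(
        lambda d_: _paired_power(d_, n, alpha) - power, 1e-9, hi, xtol=1e-10
    )
    return hedges_correction(n - 1) * d
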