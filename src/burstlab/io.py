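"""File I/O and run configuration.

EEG travels as plain CSV numeric tables (one column per channel, optional
``time_s`` column); derived tables are CSV with a JSON sidecar schema; run
configuration is TOML.  All time fields in output tables are seconds from
recording start in 6-decimal fixed format so repeated runs diff cleanly.
"""

from __future__ import annotations

import hashlib
import json
import sys
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .detect import CriteriaThresholds
from .filters import DEFAULT_BANDS, BandDefinition, FilterSpec
from .spectral import EDGE_CHANNELS

__all__ = [
    "RunConfig",
    "load_config",
    "read_eeg_csv",
    "write_eeg_csv",
    "write_table",
    "write_manifest",
]


@dataclass
class RunConfig:
    """All tunable constants of a pipeline run, with defaults as published."""

    fs_hz: float = 250.0
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    thresholds: CriteriaThresholds = field(default_factory=CriteriaThresholds)
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    welch_window_s: float = 8.0
    welch_overlap: float = 0.75
    edge_channels: tuple[int, ...] = EDGE_CHANNELS
    pupil_confidence_threshold: float = 0.5
    pupil_hysteresis_s: float = 0.05
    blink_cutoff_s: float = 1.0
    pupil_gap_s: float = 0.5
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bands"] = [asdict(b) for b in self.bands]
        return d


def load_config(path: str | Path) -> RunConfig:
    """Load a TOML config, rejecting unknown keys with a clear message."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "bands" in data:
        data["bands"] = tuple(BandDefinition(**b) for b in data["bands"])
    if "thresholds" in data:
        data["thresholds"] = CriteriaThresholds(**data["thresholds"])
    if "filter_spec" in data:
        data["filter_spec"] = FilterSpec(**data["filter_spec"])
    if "edge_channels" in data:
        data["edge_channels"] = tuple(data["edge_channels"])
    return RunConfig(**data)


def read_eeg_csv(path: str | Path) -> tuple[np.ndarray, float | None]:
    """Read a channels-as-columns CSV; returns (channels x samples, fs or None).

    The sampling rate is inferred from a ``time_s`` column when present.
    """
    df = pd.read_csv(path)
    fs = None
    if "time_s" in df.columns:
        t = df.pop("time_s").to_numpy()
        if len(t) > 1:
            fs = 1.0 / float(np.median(np.diff(t)))
    return df.to_numpy(dtype=float).T, fs


def write_eeg_csv(path: str | Path, signal: np.ndarray, fs_hz: float) -> None:
    signal = np.atleast_2d(signal)
    df = pd.DataFrame(
        signal.T, columns=[f"ch{i}" for i in range(signal.shape[0])]
    )
    df.insert(0, "time_s", np.arange(signal.shape[1]) / fs_hz)
    df.to_csv(path, index=False, float_format="%.6f")


def write_table(path: str | Path, table: pd.DataFrame) -> None:
    """Write a derived table as CSV plus a JSON sidecar schema."""
    path = Path(path)
    table.to_csv(path, index=False, float_format="%.6f")
    schema = {
        "columns": {c: str(t) for c, t in table.dtypes.items()},
        "n_rows": int(len(table)),
    }
    path.with_suffix(path.suffix + ".schema.json").write_text(
        json.dumps(schema, indent=1)
    )


def write_manifest(out_dir: str | Path, config: RunConfig, command: str) -> Path:
    """Write a reproducibility manifest next to the results."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = config.to_dict()
    digest = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = {
        "command": command,
        "config": cfg,
        "config_sha256": digest,
        "seed": config.seed,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, default=str))
    return path
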