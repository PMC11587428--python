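"""Reading EEG (EDF/EDF+ or delimited text) and writing result tables.

EDF is the PSG interchange standard and is read through MNE; a plain
delimited fallback (one column per channel, or time+value pairs) keeps the
toolchain free of binary formats for testing and simulation output.  All
result files are delimited text with explicit headers; numeric formatting
uses full repr precision so read -> write -> read round-trips are
lossless.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig, normalize_channel_label
from .records import SignalRecord

__all__ = [
    "read_eeg",
    "write_pattern_table",
    "read_pattern_table",
    "write_report",
    "read_report",
    "write_run_metadata",
]

PATTERN_TABLE_COLUMNS = [
    "subject", "channel", "band", "epoch_index", "N_normalized", "T_mean",
]

REPORT_COLUMNS = [
    "channel", "band", "metric",
    "mean_a", "median_a", "sd_a", "q1_a", "q3_a",
    "whisker_lo_a", "whisker_hi_a", "n_outliers_a", "n_a",
    "mean_b", "median_b", "sd_b", "q1_b", "q3_b",
    "whisker_lo_b", "whisker_hi_b", "n_outliers_b", "n_b",
    "U", "p_value", "method", "percent_difference", "significant",
]


def _is_edf(path: Path) -> bool:
    if path.suffix.lower() in (".edf", ".bdf", ".rec"):
        return True
    try:
        with open(path, "rb") as fh:
            head = fh.read(8)
        return head[:1] in (b"0", b"\xff")
    except OSError:
        return False


def read_eeg(
    path,
    channels: Optional[Sequence[str]] = None,
    sampling_rate: Optional[float] = None,
) -> List[SignalRecord]:
    """Read EEG channels from an EDF/EDF+ file or delimited numeric text.

    Channel matching is case-insensitive and montage-robust: labels like
    ``"EEG O1-M2"`` match a request for ``"O1"``.  For delimited files the
    sampling rate is inferred from a ``time`` column when present,
    otherwise ``sampling_rate`` must be given.  With ``channels=None``
    every channel in the file is returned.

    Raises ``FileNotFoundError``/``OSError`` for unreadable files and
    ``KeyError`` (listing available labels) for absent channels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such EEG file: {path}")
    if _is_edf(path):
        return _read_edf(path, channels)
    return _read_delimited(path, channels, sampling_rate)


def _select(available: Dict[str, int], requested) -> List[str]:
    """Map requested canonical labels onto available normalized labels."""
    if requested is None:
        return list(available)
    out = []
    missing = []
    for ch in requested:
        key = normalize_channel_label(ch)
        if key in available:
            out.append(key)
        else:
            missing.append(ch)
    if missing:
        raise KeyError(
            f"channel(s) {missing} not found; available: "
            f"{sorted(available)}"
        )
    return out


def _read_edf(path: Path, channels) -> List[SignalRecord]:
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises various types for corrupt files
        raise OSError(f"could not read EDF file {path}: {exc}") from exc
    fs = float(raw.info["sfreq"])
    if fs <= 0:
        raise ValueError(f"non-positive sampling rate in {path}")
    norm_map: Dict[str, int] = {}
    for i, name in enumerate(raw.ch_names):
        norm_map.setdefault(normalize_channel_label(name), i)
    picks = _select(norm_map, channels)
    data = raw.get_data()  # volts
    meas_t = None
    return [
        SignalRecord(
            channel_label=ch,
            sampling_rate=fs,
            samples=data[norm_map[ch]] * 1e6,  # microvolts
            start_time=meas_t,
        )
        for ch in picks
    ]


def _read_delimited(path: Path, channels, sampling_rate) -> List[SignalRecord]:
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:
        raise OSError(f"could not parse delimited file {path}: {exc}") from exc
    # headerless numeric file? re-read without header
    try:
        [float(c) for c in df.columns]
        df = pd.read_csv(path, sep=None, engine="python", header=None)
        if df.shape[1] == 2:
            df.columns = ["time", "value"]
        else:
            df.columns = [f"ch{i + 1}" for i in range(df.shape[1])]
    except ValueError:
        pass

    cols = {normalize_channel_label(c): c for c in df.columns}
    fs = sampling_rate
    if "TIME" in cols:
        t = df[cols.pop("TIME")].to_numpy(dtype=float)
        if t.size < 2:
            raise ValueError(f"{path}: need at least 2 samples")
        dt = np.diff(t)
        if np.ptp(dt) > 1e-6 * np.mean(dt):
            raise ValueError(f"{path}: time column is not uniformly sampled")
        fs = 1.0 / float(np.mean(dt))
    if fs is None or fs <= 0:
        raise ValueError(
            f"{path}: sampling rate unknown; provide sampling_rate or a "
            "time column"
        )
    if channels is None and "VALUE" in cols and len(cols) == 1:
        picks = ["VALUE"]
    else:
        picks = _select(cols, channels)
    return [
        SignalRecord(
            channel_label=("EEG" if ch == "VALUE" else ch),
            sampling_rate=fs,
            samples=df[cols[ch]].to_numpy(dtype=float),
        )
        for ch in picks
    ]


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def write_pattern_table(table: pd.DataFrame, path) -> None:
    """Write an epoch-normalized pattern table (long CSV).

    Expects columns ``subject, channel, band, epoch_index, N_normalized,
    T_mean``; extra columns are preserved.  An empty table produces a
    header-only file.
    """
    missing = [c for c in PATTERN_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"pattern table missing columns: {missing}")
    ordered = table[
        PATTERN_TABLE_COLUMNS
        + [c for c in table.columns if c not in PATTERN_TABLE_COLUMNS]
    ]
    ordered.to_csv(path, index=False)


def read_pattern_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_report(result, path) -> None:
    """Write a group-comparison report (long CSV, one row per
    channel x band x metric)."""
    table = result.table if hasattr(result, "table") else result
    cols = [c for c in REPORT_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    table[cols].to_csv(path, index=False)


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_run_metadata(
    path, config: AnalysisConfig, extra: Optional[dict] = None
) -> None:
    """JSON echo of the run configuration (plus software version and any
    extra keys) for provenance."""
    from . import __version__

    meta = {"software": "oscipat", "version": __version__,
            "config": config.to_dict()}
    if extra:
        meta.update(extra)
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
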