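"""On-disk formats and in-memory containers for LFP, spike trains and events.

All times are seconds (float64) internally; interfaces that take windows in
milliseconds convert once at the boundary.  Time windows are half-open
``[a, b)`` and sample ``i`` of an LFP trace sits at ``t0 + i / fs``.

File formats
------------
* Spike trains: CSV with header ``unit_id,channel_id,time_s``.
* Events: CSV with header
  ``channel_id,peak_time_s,onset_s,offset_s,peak_amplitude_uv``.
* LFP: EDF (16-bit, physical unit uV) or a plain-text format of leading
  ``key=value`` lines (``fs_hz`` mandatory, ``channel_id``/``t0_s`` optional)
  followed by one sample per line, in uV.
* Reports: a JSON summary; any tabular section is written as a CSV file next
  to the JSON and referenced from it by filename.
"""

from __future__ import annotations

import json
import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("iedflow")

TEXT_DECIMALS = 6  # round-trip precision of all delimited-text output


class FormatError(ValueError):
    """Raised when an input file does not match its declared format."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class LfpSignal:
    """Uniformly sampled voltage trace in microvolts."""

    channel_id: str
    fs: float
    samples: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-d sequence")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs


@dataclass
class SpikeTrain:
    """A sorted unit's spike times over a known recording span."""

    unit_id: str
    channel_id: str
    times: np.ndarray
    span: tuple[float, float]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("spike times must be strictly increasing")
        lo, hi = self.span
        if not hi > lo:
            raise ValueError("span length must be > 0")
        if self.times.size and (self.times[0] < lo or self.times[-1] > hi):
            raise ValueError("all spike times must lie within span")

    @property
    def n_spikes(self) -> int:
        return self.times.size

    @property
    def mean_rate(self) -> float:
        lo, hi = self.span
        return self.n_spikes / (hi - lo)


@dataclass
class EventSet:
    """Detected or imported discharge events, aligned on their sharpest peak.

    ``onset <= peak <= offset`` for every event and peaks are strictly
    increasing.  An empty set is valid.
    """

    peak_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    onsets: np.ndarray = field(default_factory=lambda: np.empty(0))
    offsets: np.ndarray = field(default_factory=lambda: np.empty(0))
    amplitudes: np.ndarray = field(default_factory=lambda: np.empty(0))
    channel_ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))
    source: str = "detected"

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.channel_ids = np.asarray(self.channel_ids, dtype=object)
        n = self.peak_times.size
        for arr in (self.onsets, self.offsets, self.amplitudes, self.channel_ids):
            if arr.size != n:
                raise ValueError("all event fields must have equal length")
        if n:
            if np.any(self.onsets > self.peak_times) or np.any(self.peak_times > self.offsets):
                raise ValueError("need onset <= peak <= offset for every event")
            if np.any(np.diff(self.peak_times) <= 0):
                raise ValueError("event peaks must be strictly increasing")
        if self.source not in ("detected", "imported"):
            raise ValueError("source must be 'detected' or 'imported'")

    def __len__(self) -> int:
        return int(self.peak_times.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "channel_id": self.channel_ids,
                "peak_time_s": self.peak_times,
                "onset_s": self.onsets,
                "offset_s": self.offsets,
                "peak_amplitude_uv": self.amplitudes,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, source: str = "imported") -> "EventSet":
        _require_columns(df, ["channel_id", "peak_time_s", "onset_s", "offset_s",
                              "peak_amplitude_uv"], "event file")
        df = df.sort_values("peak_time_s", kind="stable")
        return cls(
            peak_times=df["peak_time_s"].to_numpy(float),
            onsets=df["onset_s"].to_numpy(float),
            offsets=df["offset_s"].to_numpy(float),
            amplitudes=df["peak_amplitude_uv"].to_numpy(float),
            channel_ids=df["channel_id"].to_numpy(object),
            source=source,
        )


# ---------------------------------------------------------------------------
# Spike-train CSV
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing column(s) {missing}")


def read_spike_trains(path, span: tuple[float, float] | None = None) -> list[SpikeTrain]:
    """Read one :class:`SpikeTrain` per distinct unit from a spike CSV.

    Times are sorted per unit; exact duplicate timestamps within a unit are
    collapsed with a warning.  When *span* is omitted it is inferred as
    ``[0, max time]`` over the whole file.
    """
    df = pd.read_csv(path)
    _require_columns(df, ["unit_id", "channel_id", "time_s"], "spike file")
    if len(df) == 0:
        return []
    if (df["time_s"] < 0).any():
        raise FormatError("spike file: negative spike times")
    if span is None:
        span = (0.0, float(df["time_s"].max()) or 1.0)
    trains = []
    for unit_id, grp in df.groupby("unit_id", sort=True):
        times = np.sort(grp["time_s"].to_numpy(float), kind="stable")
        uniq = np.unique(times)
        if uniq.size < times.size:
            logger.warning(
                "unit %s: collapsed %d duplicate spike timestamps",
                unit_id, times.size - uniq.size,
            )
        channel = str(grp["channel_id"].iloc[0])
        trains.append(SpikeTrain(str(unit_id), channel, uniq, span))
    return trains


def write_spike_trains(trains: Sequence[SpikeTrain], path) -> None:
    rows = []
    for tr in trains:
        rows.append(pd.DataFrame({
            "unit_id": tr.unit_id, "channel_id": tr.channel_id,
            "time_s": np.round(tr.times, TEXT_DECIMALS),
        }))
    df = (pd.concat(rows, ignore_index=True) if rows
          else pd.DataFrame(columns=["unit_id", "channel_id", "time_s"]))
    df.to_csv(path, index=False, float_format=f"%.{TEXT_DECIMALS}f")


# ---------------------------------------------------------------------------
# Event CSV
# ---------------------------------------------------------------------------

def read_events(path, source: str = "imported") -> EventSet:
    return EventSet.from_frame(pd.read_csv(path), source=source)


def write_events(events: EventSet, path) -> None:
    events.to_frame().to_csv(path, index=False, float_format=f"%.{TEXT_DECIMALS}f")


# ---------------------------------------------------------------------------
# LFP: delimited text and EDF
# ---------------------------------------------------------------------------

def read_lfp(path, channel: str | None = None) -> LfpSignal:
    """Read an LFP trace from EDF or header+samples text (uV)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".edf":
        return _read_edf(path, channel)
    if suffix in (".csv", ".txt", ".tsv"):
        return _read_lfp_text(path, channel)
    raise FormatError(f"unknown LFP file extension {suffix!r} (expect .edf/.csv/.txt)")


def write_lfp(lfp: LfpSignal, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".edf":
        write_edf(lfp, path)
    else:
        _write_lfp_text(lfp, path)


def _read_lfp_text(path: Path, channel: str | None) -> LfpSignal:
    meta: dict[str, str] = {}
    samples: list[float] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if "=" in line:
                key, _, val = line.partition("=")
                meta[key.strip()] = val.strip()
            else:
                samples.append(float(line))
    if "fs_hz" not in meta:
        raise FormatError("LFP text file: missing 'fs_hz' header line")
    if not samples:
        raise FormatError("LFP text file: empty sample section")
    channel_id = meta.get("channel_id", channel or "lfp")
    if channel is not None and channel_id != channel:
        raise FormatError(
            f"channel {channel!r} not in file (available: [{channel_id!r}])")
    return LfpSignal(channel_id, float(meta["fs_hz"]),
                     np.asarray(samples), float(meta.get("t0_s", 0.0)))


def _write_lfp_text(lfp: LfpSignal, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"fs_hz={lfp.fs:.6g}\n")
        fh.write(f"channel_id={lfp.channel_id}\n")
        fh.write(f"t0_s={lfp.t0:.6f}\n")
        np.savetxt(fh, lfp.samples, fmt=f"%.{TEXT_DECIMALS}f")


def write_edf(lfp: LfpSignal, path) -> None:
    """Write a single-channel 16-bit EDF file (1-s data records, unit uV).

    The sampling rate must be a positive integer and the trace is zero-padded
    to a whole number of seconds (EDF stores fixed-length records).
    """
    fs = int(round(lfp.fs))
    if abs(fs - lfp.fs) > 1e-9 or fs <= 0:
        raise ValueError("EDF writer requires an integer sampling rate")
    x = lfp.samples
    n_rec = int(np.ceil(x.size / fs))
    pad = n_rec * fs - x.size
    if pad:
        x = np.concatenate([x, np.zeros(pad)])
    pmax = float(np.max(np.abs(x))) or 1.0
    pmin = -pmax
    dmax, dmin = 32767, -32767
    gain = (pmax - pmin) / (dmax - dmin)
    digital = np.clip(np.round((x - pmin) / gain) + dmin, dmin, dmax).astype("<i2")

    def pad_field(val, width) -> bytes:
        s = str(val)[:width]
        return s.ljust(width).encode("ascii")

    label = lfp.channel_id[:16]
    header = b"".join([
        pad_field("0", 8),                       # version
        pad_field("X X X X", 80),                # patient id (anonymous)
        pad_field("Startdate X X X X", 80),      # recording id
        pad_field("01.01.00", 8),                # start date
        pad_field("00.00.00", 8),                # start time
        pad_field(256 + 256, 8),                 # header bytes
        pad_field("", 44),                       # reserved
        pad_field(n_rec, 8),                     # number of data records
        pad_field("1", 8),                       # record duration, seconds
        pad_field(1, 4),                         # number of signals
        pad_field(label, 16),                    # signal label
        pad_field("", 80),                       # transducer
        pad_field("uV", 8),                      # physical dimension
        pad_field(f"{pmin:.6g}"[:8], 8),         # physical min
        pad_field(f"{pmax:.6g}"[:8], 8),         # physical max
        pad_field(dmin, 8),                      # digital min
        pad_field(dmax, 8),                      # digital max
        pad_field("", 80),                       # prefiltering
        pad_field(fs, 8),                        # samples per record
        pad_field("", 32),                       # reserved
    ])
    assert len(header) == 512
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(struct.pack(f"<{digital.size}h", *digital.tolist()))


def _read_edf(path: Path, channel: str | None) -> LfpSignal:
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    names = list(raw.ch_names)
    if channel is None:
        idx = 0
    else:
        if channel not in names:
            raise FormatError(f"channel {channel!r} not in file (available: {names})")
        idx = names.index(channel)
    data = raw.get_data(picks=[idx])[0] * 1e6  # mne holds EEG data in volts
    return LfpSignal(names[idx], float(raw.info["sfreq"]), data)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return round(float(obj), TEXT_DECIMALS)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, float):
        return round(obj, TEXT_DECIMALS)
    return obj


def write_report(results: Mapping, path) -> dict:
    """Write a pipeline report: JSON summary plus CSV side files for tables.

    Any value that is a :class:`pandas.DataFrame` is written to
    ``<stem>_<key>.csv`` next to *path* and replaced in the JSON by that
    filename.  Returns the JSON-serializable dict that was written.
    """
    path = Path(path)
    summary: dict = {}
    for key, val in results.items():
        if isinstance(val, pd.DataFrame):
            side = path.with_name(f"{path.stem}_{key}.csv")
            val.to_csv(side, index=False, float_format=f"%.{TEXT_DECIMALS}f")
            summary[key] = side.name
        else:
            summary[key] = _jsonable(val)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def read_report(path) -> dict:
    """Re-read a report written by :func:`write_report` (tables as DataFrames)."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        summary = json.load(fh)
    for key, val in list(summary.items()):
        if isinstance(val, str) and val.endswith(".csv"):
            side = path.with_name(val)
            if side.exists():
                summary[key] = pd.read_csv(side)
    return summary
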