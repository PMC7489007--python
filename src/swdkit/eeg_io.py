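"""Reading and writing EEG recordings and event tables.

The in-memory model is :class:`EEGRecording`: per-channel voltage arrays in
microvolts with a common sampling rate. Time is expressed in seconds from the
start of the recording, 0-based; event intervals are half-open ``[start, end)``
so that merging and overlap arithmetic is unambiguous.

Two on-disk formats are supported for recordings: 16-bit EDF (the standard
interchange format for electrophysiology) and plain CSV with one time column
plus one column per channel. Event tables travel as TSV.

EDF files are read through :mod:`mne`; writing uses a small built-in encoder
(16-bit, one data record per second, physical dimension fixed to uV).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Raised when a file cannot be parsed as the requested format."""


@dataclass
class EEGRecording:
    """Multichannel sampled voltage trace.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Voltages in microvolts.
    sampling_rate : float
        Samples per second, > 0.
    channel_labels : list of str
        Unique channel names (e.g. frontal/parietal montage labels).
    reference_label : str, optional
        Name of the reference electrode, purely informational.
    """

    samples: np.ndarray
    sampling_rate: float
    channel_labels: list[str] = field(default_factory=list)
    reference_label: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i + 1}" for i in range(self.samples.shape[0])]
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def channel(self, label: str) -> np.ndarray:
        return self.samples[self.channel_labels.index(label)]


EVENT_COLUMNS = ["start_s", "end_s", "kind", "channel", "component_times"]


@dataclass
class EventTable:
    """Table of timed events: half-open intervals ``[start, end)`` in seconds.

    ``component_times`` holds per-event lists of seconds (used for the spike
    components of spike-and-wave discharges); empty for point-like events.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col in EVENT_COLUMNS:
            if col not in df.columns:
                df[col] = [] if len(df) == 0 else ""
        if len(df):
            if (df["end_s"] < df["start_s"]).any():
                raise ValueError("event end precedes start")
            if not df["start_s"].is_monotonic_increasing:
                warnings.warn("events not sorted by start; sorting", stacklevel=2)
                df = df.sort_values("start_s", kind="stable")
        self.df = df.reset_index(drop=True)[EVENT_COLUMNS]

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_events(
        cls,
        events: Sequence[tuple],
    ) -> "EventTable":
        """Build from tuples ``(start, end, kind, channel, component_times)``."""
        rows = []
        for ev in events:
            start, end, kind, channel = ev[:4]
            comps = ev[4] if len(ev) > 4 else []
            rows.append(
                {
                    "start_s": float(start),
                    "end_s": float(end),
                    "kind": str(kind),
                    "channel": str(channel),
                    "component_times": list(comps),
                }
            )
        return cls(pd.DataFrame(rows, columns=EVENT_COLUMNS))

    def of_kind(self, kind: str) -> "EventTable":
        return EventTable(self.df[self.df["kind"] == kind])

    def intervals(self) -> np.ndarray:
        """(n, 2) array of [start, end) in seconds."""
        if len(self.df) == 0:
            return np.empty((0, 2))
        return self.df[["start_s", "end_s"]].to_numpy(dtype=float)


def write_events(events: EventTable, path: str | Path) -> None:
    """Write an event table to TSV.

    ``component_times`` lists are semicolon-joined; the round trip through
    :func:`read_events` is exact to float repr precision.
    """
    df = events.df.copy()
    df["component_times"] = [
        ";".join(repr(float(t)) for t in comps) for comps in df["component_times"]
    ]
    df.to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> EventTable:
    df = pd.read_csv(path, sep="\t", dtype={"kind": str, "channel": str})
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"event TSV missing columns {missing} in {path}")
    comps = []
    for raw in df["component_times"].fillna(""):
        raw = str(raw).strip()
        comps.append([float(x) for x in raw.split(";")] if raw else [])
    df["component_times"] = comps
    return EventTable(df)


# ---------------------------------------------------------------------------
# CSV recordings
# ---------------------------------------------------------------------------

def _write_csv(rec: EEGRecording, path: Path) -> None:
    data = {"time_s": rec.times()}
    for lab, x in zip(rec.channel_labels, rec.samples):
        data[lab] = x
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.6f")


def _read_csv(path: Path) -> EEGRecording:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise FormatError(f"{path}: CSV recording requires a 'time_s' column")
    if len(df) < 2:
        raise FormatError(f"{path}: need at least 2 samples to infer sampling rate")
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise FormatError(f"{path}: time column is not uniformly sampled")
    labels = [c for c in df.columns if c != "time_s"]
    samples = df[labels].to_numpy(dtype=float).T
    return EEGRecording(samples, 1.0 / dt[0], labels)


# ---------------------------------------------------------------------------
# EDF recordings
# ---------------------------------------------------------------------------

def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _write_edf(rec: EEGRecording, path: Path) -> None:
    """Minimal EDF encoder: 16-bit, uV, one data record per second.

    The trace is zero-padded to a whole number of 1 s records; per-channel
    physical min/max are taken from the data so the quantization step is
    (max - min) / 65535.
    """
    fs = rec.sampling_rate
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise FormatError("EDF writer requires an integer sampling rate")
    ns = rec.n_channels
    n_rec = int(np.ceil(rec.n_samples / spr))
    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field("X X X X", 80),
            _edf_field("Startdate X X X X", 80),
            _edf_field("01.01.00", 8),
            _edf_field("00.00.00", 8),
            _edf_field(256 * (ns + 1), 8),
            _edf_field("", 44),
            _edf_field(n_rec, 8),
            _edf_field(1, 8),
            _edf_field(ns, 4),
        ]
    )
    dig_min, dig_max = -32768, 32767
    phys_mins, phys_maxs = [], []
    for x in rec.samples:
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi <= lo:
            hi = lo + 1.0
        # widen slightly so rounding never clips
        span = hi - lo
        phys_mins.append(lo - 1e-6 * span)
        phys_maxs.append(hi + 1e-6 * span)

    def col(fmt_vals, width):
        return b"".join(_edf_field(v, width) for v in fmt_vals)

    header += col(rec.channel_labels, 16)
    header += col(["" for _ in range(ns)], 80)  # transducer
    header += col(["uV"] * ns, 8)
    header += col([f"{v:.8g}"[:8] for v in phys_mins], 8)
    header += col([f"{v:.8g}"[:8] for v in phys_maxs], 8)
    header += col([dig_min] * ns, 8)
    header += col([dig_max] * ns, 8)
    header += col(["" for _ in range(ns)], 80)  # prefiltering
    header += col([spr] * ns, 8)
    header += col(["" for _ in range(ns)], 32)

    padded = np.zeros((ns, n_rec * spr))
    padded[:, : rec.n_samples] = rec.samples
    # re-read physical extremes as written (8-char decimal) so scaling matches
    pmin = np.array([float(f"{v:.8g}"[:8]) for v in phys_mins])
    pmax = np.array([float(f"{v:.8g}"[:8]) for v in phys_maxs])
    scale = (pmax - pmin) / (dig_max - dig_min)
    digital = np.round((padded - pmin[:, None]) / scale[:, None]) + dig_min
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())


def _read_edf(path: Path) -> EEGRecording:
    import mne

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # noqa: BLE001 - surfaced as format error
        raise FormatError(f"cannot parse {path} as EDF: {exc}") from exc
    fs_set = {raw.info["sfreq"]}
    if len(fs_set) != 1:
        raise FormatError(f"{path}: channels with differing sampling rates")
    data = raw.get_data() * 1e6  # mne loads volts; internal unit is uV
    return EEGRecording(data, float(raw.info["sfreq"]), list(raw.ch_names))


def write_recording(rec: EEGRecording, path: str | Path, format: str | None = None) -> None:
    """Write a recording as EDF or CSV (inferred from the suffix by default)."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "edf":
        _write_edf(rec, path)
    elif fmt == "csv":
        _write_csv(rec, path)
    else:
        raise FormatError(f"unknown recording format {fmt!r}")


def read_recording(path: str | Path, format: str | None = None) -> EEGRecording:
    """Read an EDF or CSV recording into microvolts."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "edf":
        return _read_edf(path)
    if fmt == "csv":
        return _read_csv(path)
    raise FormatError(f"unknown recording format {fmt!r}")
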