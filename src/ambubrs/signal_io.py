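"""Reading and writing multichannel physiologic recordings and event annotations.

Record formats
--------------
CSV (native dialect)
    One column per channel, first row a header of channel names. Sampling
    rate, units, channel roles and the record start time live in a YAML
    sidecar named ``<record>.meta.yaml`` next to the data file. All channels
    in one CSV share a sampling rate; records with per-channel rates must be
    written as one CSV per rate.
EDF
    Read through :mod:`mne` when it is installed (read-only).
Events
    CSV with header ``kind,label,start,end``; times in seconds from record
    start.

Time convention: seconds from record start, ``t0 = 0`` unless the metadata
says otherwise. Sample ``i`` of channel ``c`` occurs at ``t0 + i / fs_c``.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .errors import ConfigurationError, SignalIOError, ValidationError

#: Channel roles recognised downstream. Anything else is kept under "other".
KNOWN_ROLES = ("ECG", "PPG", "ABP", "VCP")

_ROLE_HINTS = {
    "ECG": ("ecg", "ekg", "lead"),
    "PPG": ("ppg", "pleth", "spo2"),
    "ABP": ("abp", "art", "aline", "pressure"),
    "VCP": ("vcp", "fin", "nova", "clamp"),
}


def infer_role(name: str) -> str:
    """Map a channel name to a role using conventional substrings."""
    low = name.lower()
    for role, hints in _ROLE_HINTS.items():
        if any(h in low for h in hints):
            return role
    return "other"


@dataclass
class MultiChannelRecord:
    """Synchronised raw signals with per-channel sampling metadata.

    ``channels`` maps a channel *role* (ECG, PPG, ABP, VCP, other) to a 1-D
    sample array. ``fs`` and ``units`` are per-role.
    """

    channels: dict[str, np.ndarray]
    fs: dict[str, float]
    units: dict[str, str] = field(default_factory=dict)
    t0: float = 0.0
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.channels:
            raise ValidationError("record has no channels")
        for role, x in self.channels.items():
            x = np.asarray(x, dtype=float)
            self.channels[role] = x
            if x.ndim != 1 or x.size == 0:
                raise ValidationError(f"channel {role!r} must be a nonempty 1-D array")
            if role not in self.fs:
                raise ConfigurationError(f"missing sampling rate for channel {role!r}")
            if not self.fs[role] > 0:
                raise ConfigurationError(f"fs must be positive for channel {role!r}")
            self.units.setdefault(role, "au")

    def duration(self, role: str) -> float:
        """Length of one channel in seconds."""
        return self.channels[role].size / self.fs[role]

    def time(self, role: str) -> np.ndarray:
        """Sample times of one channel in seconds."""
        return self.t0 + np.arange(self.channels[role].size) / self.fs[role]


EVENT_KINDS = ("cuff_inflation", "intervention", "activity")


@dataclass(frozen=True)
class Event:
    kind: str
    label: str
    start: float
    end: float


@dataclass
class EventList:
    """Sorted annotation intervals (cuff inflations, interventions, activities)."""

    events: list[Event] = field(default_factory=list)

    def __post_init__(self):
        for ev in self.events:
            if ev.end < ev.start:
                raise ValidationError(f"event {ev} has end < start")
        self.events = sorted(self.events, key=lambda e: (e.start, e.end))

    def of_kind(self, kind: str) -> list[Event]:
        return [e for e in self.events if e.kind == kind]

    def __iter__(self):
        return iter(self.events)

    def __len__(self):
        return len(self.events)


# ---------------------------------------------------------------------------
# record I/O


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.yaml")


def read_record(
    path,
    format: str = "csv",
    fs: float | None = None,
    units: Mapping[str, str] | None = None,
    roles: Mapping[str, str] | None = None,
) -> MultiChannelRecord:
    """Read a multichannel record.

    Parameters
    ----------
    path : path-like
        Data file.
    format : {"csv", "edf"}
        ``"wfdb"`` is not supported by this build and raises
        :class:`SignalIOError`.
    fs : float, optional
        Common sampling rate override (CSV only); required when no metadata
        sidecar is present.
    roles : mapping, optional
        Explicit column-name → role mapping; otherwise roles are inferred
        from channel names.
    """
    path = Path(path)
    if not path.exists():
        raise SignalIOError(f"record file not found: {path}")
    if format == "csv":
        return _read_csv_record(path, fs=fs, units=units, roles=roles)
    if format == "edf":
        return _read_edf_record(path, roles=roles)
    if format == "wfdb":
        raise SignalIOError("WFDB support is not available in this build; convert to CSV or EDF")
    raise ConfigurationError(f"unknown record format {format!r}")


def _read_csv_record(path: Path, fs=None, units=None, roles=None) -> MultiChannelRecord:
    meta: dict = {}
    side = _sidecar_path(path)
    if side.exists():
        with open(side) as fh:
            meta = yaml.safe_load(fh) or {}
    try:
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader, None)
            if header is None:
                raise SignalIOError(f"empty record file: {path}")
            rows = [row for row in reader if row]
    except OSError as exc:
        raise SignalIOError(f"cannot read {path}: {exc}") from exc
    if not rows:
        raise SignalIOError(f"record file has a header but no samples: {path}")
    try:
        data = np.array(rows, dtype=float)
    except ValueError as exc:
        raise SignalIOError(f"garbled numeric data in {path}: {exc}") from exc
    if data.shape[1] != len(header):
        raise SignalIOError(f"ragged CSV in {path}")

    meta_channels = meta.get("channels", {})
    channels, fs_map, unit_map, names = {}, {}, {}, {}
    for j, name in enumerate(header):
        cmeta = meta_channels.get(name, {})
        role = (roles or {}).get(name) or cmeta.get("role") or infer_role(name)
        if role in channels:  # keep duplicate roles distinguishable
            role = f"{role}:{name}"
        ch_fs = cmeta.get("fs", fs if fs is not None else meta.get("fs"))
        if ch_fs is None:
            raise ConfigurationError(
                f"no sampling rate for column {name!r}: supply fs= or a {side.name} sidecar"
            )
        channels[role] = data[:, j]
        fs_map[role] = float(ch_fs)
        unit_map[role] = cmeta.get("units", (units or {}).get(name, "au"))
        names[role] = name
    return MultiChannelRecord(
        channels=channels, fs=fs_map, units=unit_map,
        t0=float(meta.get("t0", 0.0)), names=names,
    )


def _read_edf_record(path: Path, roles=None) -> MultiChannelRecord:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise SignalIOError("EDF reading requires the optional 'mne' dependency") from exc
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:
        raise SignalIOError(f"cannot read EDF {path}: {exc}") from exc
    channels, fs_map, unit_map, names = {}, {}, {}, {}
    fs = float(raw.info["sfreq"])
    for name in raw.ch_names:
        role = (roles or {}).get(name) or infer_role(name)
        if role in channels:
            role = f"{role}:{name}"
        channels[role] = raw.get_data(picks=name)[0]
        fs_map[role] = fs
        unit_map[role] = "au"
        names[role] = name
    return MultiChannelRecord(channels=channels, fs=fs_map, units=unit_map, names=names)


def write_record(record: MultiChannelRecord, path) -> Path:
    """Write a record to the native CSV dialect plus its YAML sidecar.

    All channels must share one sampling rate and length (the dialect is a
    rectangular table); other layouts must be split across files first.
    """
    path = Path(path)
    lengths = {x.size for x in record.channels.values()}
    rates = {record.fs[r] for r in record.channels}
    if len(lengths) != 1 or len(rates) != 1:
        raise ConfigurationError(
            "CSV dialect requires equal length and sampling rate across channels"
        )
    roles = list(record.channels)
    header = [record.names.get(r, r) for r in roles]
    data = np.column_stack([record.channels[r] for r in roles])
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for row in data:
            writer.writerow([f"{v:.10g}" for v in row])
    meta = {
        "t0": float(record.t0),
        "channels": {
            record.names.get(r, r): {
                "role": r, "fs": float(record.fs[r]), "units": record.units.get(r, "au"),
            }
            for r in roles
        },
    }
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh)
    return path


# ---------------------------------------------------------------------------
# event I/O


def read_events(path) -> EventList:
    """Read a ``kind,label,start,end`` CSV into a sorted, validated EventList."""
    path = Path(path)
    if not path.exists():
        raise SignalIOError(f"event file not found: {path}")
    events = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise SignalIOError(f"empty event file: {path}")
        for i, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 4:
                raise ValidationError(f"{path}:{i}: expected kind,label,start,end")
            kind, label = row[0].strip(), row[1].strip()
            try:
                start, end = float(row[2]), float(row[3])
            except ValueError as exc:
                raise ValidationError(f"{path}:{i}: non-numeric time: {exc}") from exc
            if end < start:
                raise ValidationError(f"{path}:{i}: end < start ({end} < {start})")
            events.append(Event(kind=kind, label=label, start=start, end=end))
    return EventList(events=events)


def write_events(events: EventList, path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["kind", "label", "start", "end"])
        for ev in events:
            writer.writerow([ev.kind, ev.label, f"{ev.start:.10g}", f"{ev.end:.10g}"])
    return path


def write_beat_table(table, path) -> Path:
    """Export a beat table (one row per beat) to CSV."""
    path = Path(path)
    table.to_csv(path, index=False, float_format="%.10g")
    return path
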