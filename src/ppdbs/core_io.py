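"""Domain types and readers/writers shared by every pipeline stage.

Conventions used throughout the package:

* amplitudes are **millivolts** internally; the EDF container stores
  microvolts (explicit x1000 conversion at the I/O boundary);
* event times are **seconds** from recording start; per-epoch time is
  milliseconds with t=0 at pulse onset; inter-stimulus intervals (ISI)
  are milliseconds, onset to onset;
* stimulus events live in a CSV sidecar next to the EDF file because
  EDF annotations cannot carry structured pair metadata losslessly.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._edf import EdfSignal, decode_transducer, encode_transducer, read_edf, write_edf

EVENT_COLUMNS = ["time_s", "channel_set", "polarity", "pair_id", "pulse_role", "isi_ms", "block"]


class RecordingError(ValueError):
    """Structural problem with a recording or its event table."""


class ChannelRole(str, enum.Enum):
    STIM_ANODE = "stim_anode"
    STIM_CATHODE = "stim_cathode"
    RING_RECORD = "ring_record"
    SEGMENT_RECORD = "segment_record"
    UNUSED = "unused"


@dataclass(frozen=True)
class ChannelInfo:
    """One contact of the lead montage."""

    label: str
    role: ChannelRole = ChannelRole.UNUSED
    row: int = 0  # lead row index (0 = most ventral)
    scale: float = 1.0  # acquisition volts-per-count, provenance only


@dataclass(frozen=True)
class StimEvent:
    """A single stimulus pulse.

    ``isi`` (ms, onset-to-onset) is defined for the test pulse of a pair
    and copied onto its conditioning partner.
    """

    time: float  # seconds from recording start
    polarity: int  # +1 / -1: anode/cathode assignment vs. reference orientation
    pair_id: int
    pulse_role: str  # "conditioning" | "test"
    isi: float  # ms
    block: int = 0
    channel_set: str = ""

    def __post_init__(self) -> None:
        if self.polarity not in (1, -1):
            raise RecordingError(f"polarity must be +1 or -1, got {self.polarity}")
        if self.pulse_role not in ("conditioning", "test"):
            raise RecordingError(f"bad pulse_role {self.pulse_role!r}")


@dataclass
class TimeSeriesRecording:
    """Multichannel recording (mV) with stimulus events and channel metadata."""

    sample_rate: float
    signals: np.ndarray  # (n_channels, n_samples), millivolts
    channels: list[ChannelInfo]
    events: list[StimEvent] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def channel_index(self, label: str) -> int:
        for i, ch in enumerate(self.channels):
            if ch.label == label:
                return i
        raise RecordingError(f"no channel labelled {label!r}")

    def channels_with_role(self, *roles: ChannelRole) -> list[ChannelInfo]:
        return [ch for ch in self.channels if ch.role in roles]

    def validate(self, stimulation_session: bool | None = None) -> None:
        if self.sample_rate <= 0:
            raise RecordingError("sample_rate must be positive")
        if self.signals.ndim != 2 or self.signals.shape[0] != len(self.channels):
            raise RecordingError(
                f"signals shape {self.signals.shape} does not match "
                f"{len(self.channels)} channels"
            )
        labels = [ch.label for ch in self.channels]
        if len(set(labels)) != len(labels):
            raise RecordingError("channel labels must be unique")
        if stimulation_session is None:
            stimulation_session = bool(self.events)
        if stimulation_session:
            if not self.channels_with_role(ChannelRole.STIM_ANODE):
                raise RecordingError("stimulation session needs >=1 stim_anode channel")
            if not self.channels_with_role(ChannelRole.STIM_CATHODE):
                raise RecordingError("stimulation session needs >=1 stim_cathode channel")
        dur = self.duration
        for ev in self.events:
            if not (0.0 <= ev.time < dur):
                raise RecordingError(
                    f"event of pair {ev.pair_id} at t={ev.time:g}s lies outside "
                    f"the recording (duration {dur:g}s)"
                )
        validate_event_pairing(self.events, self.sample_rate)


def validate_event_pairing(events: list[StimEvent], sample_rate: float) -> None:
    """Check the conditioning/test pairing invariants of an event list."""
    pairs: dict[int, dict[str, StimEvent]] = {}
    for ev in events:
        slot = pairs.setdefault(ev.pair_id, {})
        if ev.pulse_role in slot:
            raise RecordingError(f"pair {ev.pair_id} has duplicate {ev.pulse_role} events")
        slot[ev.pulse_role] = ev
    dt = 1.0 / sample_rate
    for pid, slot in pairs.items():
        if set(slot) != {"conditioning", "test"}:
            missing = {"conditioning", "test"} - set(slot)
            raise RecordingError(f"pair {pid} lacks a {missing.pop()} pulse")
        cond, test = slot["conditioning"], slot["test"]
        if cond.polarity != test.polarity:
            raise RecordingError(f"pair {pid} has mismatched polarities")
        if abs(cond.isi - test.isi) > 1e-9:
            raise RecordingError(f"pair {pid} has mismatched isi values")
        if abs((test.time - cond.time) - test.isi / 1000.0) > dt:
            raise RecordingError(
                f"pair {pid}: test-conditioning spacing "
                f"{(test.time - cond.time) * 1000:.4f} ms differs from isi "
                f"{test.isi:.4f} ms by more than one sample period"
            )


# ---------------------------------------------------------------------------
# Feature tables


@dataclass
class FeatureTable:
    """Long-format feature records with named numeric columns.

    ``units`` maps column name -> unit string ("ms", "mV", "mV*ms", "").
    """

    frame: pd.DataFrame
    key: tuple[str, ...]
    units: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        missing = [k for k in self.key if k not in self.frame.columns]
        if missing:
            raise RecordingError(f"key columns missing from table: {missing}")
        if len(self.frame) and self.frame.duplicated(subset=list(self.key)).any():
            dups = self.frame[self.frame.duplicated(subset=list(self.key), keep=False)]
            raise RecordingError(
                f"duplicate key rows in feature table:\n{dups[list(self.key)].to_string()}"
            )


def export_table(tbl: FeatureTable, path: str | Path) -> None:
    """Write a feature table as CSV with a leading ``# units:`` comment."""
    tbl.validate()
    path = Path(path)
    cols = list(tbl.frame.columns)
    units_line = "# units: " + ",".join(f"{c}={tbl.units.get(c, '')}" for c in cols)
    with open(path, "w", newline="") as fh:
        fh.write(units_line + "\n")
        tbl.frame.to_csv(fh, index=False)


def read_table(path: str | Path, key: tuple[str, ...]) -> FeatureTable:
    path = Path(path)
    units: dict[str, str] = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# units:"):
            for part in first[len("# units:") :].strip().split(","):
                if "=" in part:
                    k, v = part.split("=", 1)
                    units[k] = v
            frame = pd.read_csv(fh)
        else:
            fh.seek(0)
            frame = pd.read_csv(fh)
    tbl = FeatureTable(frame=frame, key=key, units=units)
    tbl.validate()
    return tbl


# ---------------------------------------------------------------------------
# Recording I/O (EDF + events sidecar)

_MV_TO_UV = 1000.0


def write_recording(
    rec: TimeSeriesRecording, path_edf: str | Path, path_events: str | Path
) -> None:
    """Write an EDF file (physical dimension uV) plus a lossless event sidecar."""
    rec.validate()
    signals = [
        EdfSignal(
            label=ch.label,
            physical=rec.signals[i] * _MV_TO_UV,
            dimension="uV",
            transducer=encode_transducer(role=ch.role.value, row=ch.row, scale=ch.scale),
        )
        for i, ch in enumerate(rec.channels)
    ]
    write_edf(path_edf, signals, rec.sample_rate)
    events_to_frame(rec.events).to_csv(path_events, index=False)


def events_to_frame(events: list[StimEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "time_s": ev.time,
                "channel_set": ev.channel_set,
                "polarity": ev.polarity,
                "pair_id": ev.pair_id,
                "pulse_role": ev.pulse_role,
                "isi_ms": ev.isi,
                "block": ev.block,
            }
            for ev in events
        ],
        columns=EVENT_COLUMNS,
    )


def frame_to_events(frame: pd.DataFrame) -> list[StimEvent]:
    missing = [c for c in EVENT_COLUMNS if c not in frame.columns]
    if missing:
        raise RecordingError(f"event table lacks columns {missing}")
    events = [
        StimEvent(
            time=float(r.time_s),
            polarity=int(r.polarity),
            pair_id=int(r.pair_id),
            pulse_role=str(r.pulse_role),
            isi=float(r.isi_ms),
            block=int(r.block),
            channel_set="" if pd.isna(r.channel_set) else str(r.channel_set),
        )
        for r in frame.itertuples()
    ]
    return sorted(events, key=lambda e: e.time)


def read_recording(path_edf: str | Path, path_events: str | Path) -> TimeSeriesRecording:
    signals, fs = read_edf(path_edf)
    channels = []
    for sig in signals:
        kv = decode_transducer(sig.transducer)
        channels.append(
            ChannelInfo(
                label=sig.label,
                role=ChannelRole(kv.get("role", "unused")),
                row=int(kv.get("row", 0)),
                scale=float(kv.get("scale", 1.0)),
            )
        )
    data = np.vstack([sig.physical for sig in signals]) / _MV_TO_UV
    events = frame_to_events(pd.read_csv(path_events, float_precision="round_trip"))
    rec = TimeSeriesRecording(sample_rate=fs, signals=data, channels=channels, events=events)
    rec.validate()
    return rec


def with_channels(
    rec: TimeSeriesRecording, signals: np.ndarray, channels: list[ChannelInfo]
) -> TimeSeriesRecording:
    """Derived recording sharing sample rate, events, and meta."""
    return TimeSeriesRecording(
        sample_rate=rec.sample_rate,
        signals=signals,
        channels=channels,
        events=list(rec.events),
        meta=dict(rec.meta),
    )


__all__ = [
    "ChannelInfo",
    "ChannelRole",
    "FeatureTable",
    "RecordingError",
    "StimEvent",
    "TimeSeriesRecording",
    "events_to_frame",
    "export_table",
    "frame_to_events",
    "read_recording",
    "read_table",
    "validate_event_pairing",
    "with_channels",
    "write_recording",
]
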