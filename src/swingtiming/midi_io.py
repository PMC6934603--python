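"""Standard MIDI File (SMF) input/output on a canonical 960-ticks-per-quarter timeline.

All timing inside the package is expressed in *ticks*, 1/960 of a quarter
note, regardless of the resolution declared by the source file.  Onsets are
kept as floats internally (manipulation produces fractional ticks) and are
integerised, half-away-from-zero, only when a file is written.

Only the minimal subset of the SMF spec needed for solo keyboard recordings
is interpreted: note-on/note-off pairs become :class:`NoteEvent` objects and
every other event (tempo, control change including CC64 sustain, program
change, sysex, other meta events) is carried through opaquely so that a
read/modify/write cycle leaves dynamics, pedalling and metadata untouched.
"""

from __future__ import annotations

import math
import os
import struct
import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import BinaryIO, Iterable, List, Optional, Sequence, Tuple, Union

import pandas as pd

__all__ = [
    "NoteEvent",
    "PassthroughEvent",
    "Performance",
    "MidiFormatError",
    "read_performance",
    "write_performance",
    "ticks_to_ms",
    "ms_to_ticks",
    "notes_to_frame",
    "CANONICAL_TPQ",
]

#: Canonical resolution: ticks per quarter note.
CANONICAL_TPQ = 960

DEFAULT_BPM = 120.0


class MidiFormatError(ValueError):
    """Raised when a file is not a parsable SMF type 0/1."""


@dataclass(frozen=True, order=True)
class NoteEvent:
    """One note onset.

    Parameters
    ----------
    onset : float
        Onset time in canonical ticks (960 per quarter note); may be
        fractional internally.
    pitch : int
        MIDI note number, 0-127.
    velocity : int
        Note-on velocity, 1-127.
    duration : float
        Sounding length in ticks, > 0.
    channel : int
        MIDI channel, 0-15.
    """

    onset: float
    pitch: int
    velocity: int = 64
    duration: float = 240.0
    channel: int = 0

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError(f"onset must be >= 0, got {self.onset}")
        if not 0 <= self.pitch <= 127:
            raise ValueError(f"pitch must be in 0..127, got {self.pitch}")
        if not 1 <= self.velocity <= 127:
            raise ValueError(f"velocity must be in 1..127, got {self.velocity}")
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if not 0 <= self.channel <= 15:
            raise ValueError(f"channel must be in 0..15, got {self.channel}")


@dataclass(frozen=True)
class PassthroughEvent:
    """A non-note MIDI event preserved verbatim (timestamp rescaled).

    ``kind`` is ``"meta"`` (status 0xFF: ``meta_type`` set), ``"sysex"``
    (status 0xF0/0xF7) or ``"channel"`` (any other channel voice message,
    e.g. control change / program change).  ``data`` holds the raw payload
    bytes; for channel messages ``status`` is the full status byte.
    """

    tick: float
    kind: str
    data: bytes
    status: int = 0
    meta_type: int = 0

    def is_tempo(self) -> bool:
        return self.kind == "meta" and self.meta_type == 0x51

    def is_sustain(self) -> bool:
        return (
            self.kind == "channel"
            and self.status & 0xF0 == 0xB0
            and len(self.data) >= 1
            and self.data[0] == 64
        )


@dataclass
class Performance:
    """An ordered sequence of note events at a fixed nominal tempo.

    The note list is kept sorted by ``(onset, pitch)``.  ``tpq`` is always
    the canonical 960 after reading; ``bpm`` is the single nominal tempo
    used for tick/millisecond conversion (performances are assumed
    metronomic).
    """

    notes: List[NoteEvent] = field(default_factory=list)
    bpm: float = DEFAULT_BPM
    tpq: int = CANONICAL_TPQ
    passthrough_events: List[PassthroughEvent] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        if self.bpm <= 0:
            raise ValueError(f"bpm must be positive, got {self.bpm}")
        self.notes = sorted(self.notes, key=lambda n: (n.onset, n.pitch, n.channel))

    def __len__(self) -> int:
        return len(self.notes)

    def onsets(self) -> List[float]:
        return [n.onset for n in self.notes]

    def with_notes(self, notes: Sequence[NoteEvent]) -> "Performance":
        """Copy of this performance with a replaced (re-sorted) note list."""
        return Performance(
            notes=list(notes),
            bpm=self.bpm,
            tpq=self.tpq,
            passthrough_events=list(self.passthrough_events),
            name=self.name,
        )


# ---------------------------------------------------------------------------
# tick <-> millisecond conversion


def ticks_to_ms(ticks, bpm: float):
    """Convert canonical ticks to milliseconds at a given tempo.

    One quarter note is 960 ticks and lasts 60000/bpm ms, so
    ``ms = ticks / 960 * 60000 / bpm``.  Accepts scalars or arrays.
    """
    if bpm <= 0:
        raise ValueError(f"bpm must be positive, got {bpm}")
    return ticks * (60000.0 / (CANONICAL_TPQ * bpm))


def ms_to_ticks(ms, bpm: float):
    """Inverse of :func:`ticks_to_ms`."""
    if bpm <= 0:
        raise ValueError(f"bpm must be positive, got {bpm}")
    return ms * (CANONICAL_TPQ * bpm / 60000.0)


# ---------------------------------------------------------------------------
# SMF reading

_CHANNEL_DATA_LEN = {0x80: 2, 0x90: 2, 0xA0: 2, 0xB0: 2, 0xC0: 1, 0xD0: 1, 0xE0: 2}


def _read_varlen(data: bytes, pos: int) -> Tuple[int, int]:
    value = 0
    while True:
        if pos >= len(data):
            raise MidiFormatError("truncated variable-length quantity")
        byte = data[pos]
        pos += 1
        value = (value << 7) | (byte & 0x7F)
        if not byte & 0x80:
            return value, pos


def _parse_track(data: bytes) -> List[Tuple[int, str, int, int, bytes]]:
    """Parse one MTrk payload into (abs_tick, kind, status, meta_type, data)."""
    events = []
    pos = 0
    tick = 0
    running_status: Optional[int] = None
    while pos < len(data):
        delta, pos = _read_varlen(data, pos)
        tick += delta
        if pos >= len(data):
            raise MidiFormatError("truncated track event")
        status = data[pos]
        if status >= 0x80:
            pos += 1
        else:  # running status
            if running_status is None:
                raise MidiFormatError("data byte without running status")
            status = running_status
        if status == 0xFF:
            running_status = None
            if pos >= len(data):
                raise MidiFormatError("truncated meta event")
            meta_type = data[pos]
            pos += 1
            length, pos = _read_varlen(data, pos)
            payload = data[pos : pos + length]
            pos += length
            if meta_type == 0x2F:  # end of track
                break
            events.append((tick, "meta", 0xFF, meta_type, payload))
        elif status in (0xF0, 0xF7):
            running_status = None
            length, pos = _read_varlen(data, pos)
            payload = data[pos : pos + length]
            pos += length
            events.append((tick, "sysex", status, 0, payload))
        elif status >= 0x80:
            running_status = status
            nbytes = _CHANNEL_DATA_LEN[status & 0xF0]
            payload = data[pos : pos + nbytes]
            if len(payload) < nbytes:
                raise MidiFormatError("truncated channel message")
            pos += nbytes
            events.append((tick, "channel", status, 0, payload))
        else:
            raise MidiFormatError(f"unexpected status byte 0x{status:02x}")
    return events


def read_performance(path: Union[str, "os.PathLike"], bpm_override: Optional[float] = None) -> Performance:
    """Read an SMF type 0/1 file into a :class:`Performance`.

    Onsets and durations are rescaled from the file's declared
    ticks-per-quarter resolution to the canonical 960 by exact rational
    scaling.  The tempo is taken from the first ``set_tempo`` meta event
    (default 120 BPM if absent); further tempo events are preserved as
    passthrough but ignored for conversion, with a warning, since the
    target material is metronomic.

    Note-on events with velocity 0 count as note-offs; overlapping
    same-pitch notes are matched first-in-first-out.  A note-on left
    dangling at end of track is closed there with a warning.
    """
    with open(path, "rb") as fh:
        blob = fh.read()
    if len(blob) < 14 or blob[:4] != b"MThd":
        raise MidiFormatError(f"{path}: not a Standard MIDI File (missing MThd)")
    header_len, smf_format, ntracks, division = struct.unpack(">IHHH", blob[4:14])
    if header_len < 6:
        raise MidiFormatError("malformed MThd chunk")
    if smf_format not in (0, 1):
        raise MidiFormatError(f"unsupported SMF format {smf_format} (only 0/1)")
    if division & 0x8000:
        raise MidiFormatError("SMPTE time division is not supported")
    if division == 0:
        raise MidiFormatError("zero ticks-per-quarter division")

    pos = 8 + header_len
    events: List[Tuple[int, int, str, int, int, bytes]] = []  # + track index for stable order
    tracks_read = 0
    while pos + 8 <= len(blob) and tracks_read < ntracks:
        chunk_id = blob[pos : pos + 4]
        (chunk_len,) = struct.unpack(">I", blob[pos + 4 : pos + 8])
        payload = blob[pos + 8 : pos + 8 + chunk_len]
        pos += 8 + chunk_len
        if chunk_id != b"MTrk":
            continue  # alien chunks are legal and skipped
        for tick, kind, status, meta_type, data in _parse_track(payload):
            events.append((tick, tracks_read, kind, status, meta_type, data))
        tracks_read += 1
    if tracks_read == 0:
        raise MidiFormatError(f"{path}: no MTrk chunk found")

    events.sort(key=lambda e: (e[0], e[1]))
    scale = Fraction(CANONICAL_TPQ, division)

    notes: List[NoteEvent] = []
    passthrough: List[PassthroughEvent] = []
    pending: dict = {}  # (channel, pitch) -> list of (tick, velocity) FIFO
    tempi: List[Tuple[int, float]] = []
    last_tick = 0

    def to_canonical(t: int) -> float:
        return float(t * scale)

    for tick, _tr, kind, status, meta_type, data in events:
        last_tick = max(last_tick, tick)
        if kind == "channel" and status & 0xF0 in (0x80, 0x90):
            channel = status & 0x0F
            pitch, vel = data[0], data[1]
            is_on = status & 0xF0 == 0x90 and vel > 0
            key = (channel, pitch)
            if is_on:
                pending.setdefault(key, []).append((tick, vel))
            else:
                queue = pending.get(key)
                if queue:
                    on_tick, on_vel = queue.pop(0)
                    dur = tick - on_tick
                    if dur <= 0:
                        dur = 1  # zero-length notes get the minimum duration
                    notes.append(
                        NoteEvent(
                            onset=to_canonical(on_tick),
                            pitch=pitch,
                            velocity=on_vel,
                            duration=float(dur * scale),
                            channel=channel,
                        )
                    )
                # unmatched note-off: ignore (common in loosely written files)
        else:
            if kind == "meta" and meta_type == 0x51 and len(data) == 3:
                usec_per_quarter = (data[0] << 16) | (data[1] << 8) | data[2]
                tempi.append((tick, 60_000_000.0 / usec_per_quarter))
            passthrough.append(
                PassthroughEvent(
                    tick=to_canonical(tick),
                    kind=kind,
                    data=bytes(data),
                    status=status,
                    meta_type=meta_type,
                )
            )

    for (channel, pitch), queue in pending.items():
        for on_tick, on_vel in queue:
            warnings.warn(
                f"note-on (pitch {pitch}, ch {channel}) without note-off; closing at end of track",
                stacklevel=2,
            )
            dur = max(last_tick - on_tick, 1)
            notes.append(
                NoteEvent(
                    onset=to_canonical(on_tick),
                    pitch=pitch,
                    velocity=on_vel,
                    duration=float(dur * scale),
                    channel=channel,
                )
            )

    if not notes:
        raise MidiFormatError(f"{path}: file contains no notes")

    if bpm_override is not None:
        bpm = float(bpm_override)
    elif tempi:
        bpm = tempi[0][1]
        if len({round(t[1], 6) for t in tempi}) > 1:
            warnings.warn(
                f"multiple tempi found; using the first ({bpm:.3f} BPM) for ms conversion",
                stacklevel=2,
            )
    else:
        bpm = DEFAULT_BPM

    return Performance(
        notes=notes,
        bpm=bpm,
        tpq=CANONICAL_TPQ,
        passthrough_events=passthrough,
        name=str(path),
    )


# ---------------------------------------------------------------------------
# SMF writing


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _write_varlen(value: int) -> bytes:
    if value < 0:
        raise ValueError("negative delta time")
    chunks = [value & 0x7F]
    value >>= 7
    while value:
        chunks.append(0x80 | (value & 0x7F))
        value >>= 7
    return bytes(reversed(chunks))


def _tempo_meta(bpm: float) -> bytes:
    usec = int(round(60_000_000.0 / bpm))
    return bytes([(usec >> 16) & 0xFF, (usec >> 8) & 0xFF, usec & 0xFF])


def write_performance(perf: Performance, path: Union[str, "os.PathLike"]) -> None:
    """Write a :class:`Performance` as an SMF format-0 file at 960 tpq.

    Fractional onsets/durations are rounded half-away-from-zero to integer
    ticks here and only here.  Passthrough events (tempo, CC, sysex, other
    meta) are emitted verbatim at their (rounded) ticks; if the performance
    carries no tempo event at all, one is synthesised from ``perf.bpm`` at
    tick 0 so the tempo survives a round trip.
    """
    # (tick, order_class, seq, status_bytes, payload); order within a tick:
    # meta/CC first, then note-offs, then note-ons — keeps FIFO matching stable.
    records: List[Tuple[int, int, int, bytes, bytes]] = []
    seq = 0

    has_tempo = any(ev.is_tempo() for ev in perf.passthrough_events)
    if not has_tempo:
        records.append((0, 0, seq, bytes([0xFF, 0x51, 0x03]), _tempo_meta(perf.bpm)))
        seq += 1

    for ev in perf.passthrough_events:
        tick = _round_half_away(ev.tick)
        if ev.kind == "meta":
            head = bytes([0xFF, ev.meta_type]) + _write_varlen(len(ev.data))
        elif ev.kind == "sysex":
            head = bytes([ev.status]) + _write_varlen(len(ev.data))
        else:
            head = bytes([ev.status])
        records.append((max(tick, 0), 0, seq, head, ev.data))
        seq += 1

    for note in perf.notes:
        on_tick = max(_round_half_away(note.onset), 0)
        off_tick = max(_round_half_away(note.onset + note.duration), on_tick + 1)
        status_on = bytes([0x90 | note.channel])
        status_off = bytes([0x80 | note.channel])
        records.append((on_tick, 2, seq, status_on, bytes([note.pitch, note.velocity])))
        records.append((off_tick, 1, seq, status_off, bytes([note.pitch, 0x40])))
        seq += 1

    records.sort(key=lambda r: (r[0], r[1], r[2]))

    body = bytearray()
    prev_tick = 0
    for tick, _cls, _seq, head, payload in records:
        body += _write_varlen(tick - prev_tick)
        body += head + payload
        prev_tick = tick
    body += _write_varlen(0) + bytes([0xFF, 0x2F, 0x00])  # end of track

    with open(path, "wb") as fh:
        fh.write(b"MThd" + struct.pack(">IHHH", 6, 0, 1, CANONICAL_TPQ))
        fh.write(b"MTrk" + struct.pack(">I", len(body)) + bytes(body))


# ---------------------------------------------------------------------------
# tabular export


def notes_to_frame(perf: Performance) -> pd.DataFrame:
    """Note table with columns onset_ticks, pitch, velocity, duration_ticks, channel."""
    return pd.DataFrame(
        {
            "onset_ticks": [n.onset for n in perf.notes],
            "pitch": [n.pitch for n in perf.notes],
            "velocity": [n.velocity for n in perf.notes],
            "duration_ticks": [n.duration for n in perf.notes],
            "channel": [n.channel for n in perf.notes],
        }
    )
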