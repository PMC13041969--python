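"""Standard MIDI File serialization and parsing.

The writer emits format-1 files: a conductor track carrying the tempo
meta-event (where the playback slow-down lives), then one track chunk per
distinct note-table track.  Time is quantized to the configured grid and
realized in ticks; under the defaults (120 BPM, 5000 ticks per quarter)
one tick is exactly 100 microseconds, i.e. one grid step at 1e4 points
per second.  Serialization is a pure function of (notes, config): the same
inputs always yield byte-identical files.

The parser accepts any format-0 or format-1 SMF, pairs each note-on with
the next matching note-off, and reconstructs the six-column note table in
real (tempo-honoring) seconds — used for round-trip verification and by
the ``inspect`` command.
"""

from __future__ import annotations

import math
import re
import struct
from dataclasses import replace

import numpy as np
import pandas as pd

from neuromidi.config import PERCUSSION, PERCUSSION_CHANNEL, SonificationConfig
from neuromidi.errors import ConfigError, SMFError
from neuromidi.pitch import NOTE_COLUMNS, NoteTable

__all__ = ["quantize_onset", "notes_to_smf", "apply_slowdown", "parse_smf"]

_META_TRACK_NAME = 0x03
_META_SET_TEMPO = 0x51
_META_END_OF_TRACK = 0x2F


def quantize_onset(t: float, grid_per_s: float = 1e4) -> int:
    """Index of the nearest grid point to time ``t`` (seconds).

    Rounds to the nearest integer, ties away from zero.
    """
    if t < 0:
        raise SMFError(f"cannot quantize negative time {t}")
    if not grid_per_s > 0:
        raise ConfigError(f"grid_per_s must be > 0, got {grid_per_s}")
    return int(math.floor(t * grid_per_s + 0.5))


def apply_slowdown(config: SonificationConfig, factor: float) -> SonificationConfig:
    """Scale playback ``factor`` times slower than real time.

    Implemented by scaling the tempo meta-event only: the tempo written to
    the file becomes ``factor`` times larger while every note's tick value
    is unchanged, so the file's real playback duration scales by exactly
    ``factor``.
    """
    if factor < 1:
        raise ConfigError(f"slow-down factor must be >= 1, got {factor}")
    return replace(config, slowdown=config.slowdown * factor)


def _vlq(value: int) -> bytes:
    """Variable-length-quantity encoding of a non-negative integer."""
    if value < 0:
        raise SMFError(f"negative delta time {value}")
    out = [value & 0x7F]
    value >>= 7
    while value:
        out.append(0x80 | (value & 0x7F))
        value >>= 7
    return bytes(reversed(out))


def _meta(meta_type: int, payload: bytes) -> bytes:
    return bytes([0xFF, meta_type]) + _vlq(len(payload)) + payload


def _chunk(tag: bytes, payload: bytes) -> bytes:
    return tag + struct.pack(">I", len(payload)) + payload


def _note_ticks(t: float, config: SonificationConfig) -> int:
    """Grid-quantize ``t`` then express it in ticks of the base tempo."""
    grid_index = quantize_onset(t, config.grid_per_s)
    seconds = grid_index / config.grid_per_s
    return int(math.floor(seconds / config.seconds_per_tick + 0.5))


# sort keys at equal ticks: note-offs first so re-struck pitches never merge,
# program changes before the note-ons they configure
_OFF, _PROGRAM, _ON = 0, 1, 2


def notes_to_smf(notes: NoteTable, config: SonificationConfig | None = None) -> bytes:
    """Serialize a :class:`NoteTable` to format-1 Standard MIDI File bytes.

    One track chunk per distinct note-table track (ascending), preceded by
    a conductor track holding the slow-down-scaled tempo.  Each note
    becomes a note-on/note-off pair; tracks flagged ``"percussion"`` in
    ``config.track_instruments`` are routed to the General-MIDI drum
    channel, others get a program-change for their instrument.
    """
    config = config or SonificationConfig()
    tempo = config.playback_tempo_us_per_quarter
    conductor = _vlq(0) + _meta(_META_SET_TEMPO, struct.pack(">I", tempo)[1:])
    conductor += _vlq(0) + _meta(_META_END_OF_TRACK, b"")
    chunks = [_chunk(b"MTrk", conductor)]

    for track_id in notes.tracks:
        rows = notes.frame[notes.frame["track"] == track_id]
        instrument = config.track_instruments.get(int(track_id), 0)
        percussive = instrument == PERCUSSION
        events: list[tuple[int, int, int, int, bytes]] = []  # (tick, kind, ch, pitch, msg)
        if not percussive:
            # constant channel 0 unless the notes say otherwise; the program
            # change configures whichever channels the track uses
            for ch in sorted(rows["channel"].unique()):
                events.append(
                    (0, _PROGRAM, int(ch), 0, bytes([0xC0 | int(ch), int(instrument)]))
                )
        for row in rows.itertuples(index=False):
            ch = PERCUSSION_CHANNEL if percussive else int(row.channel)
            if not 0 <= row.pitch <= 127:
                raise SMFError(f"pitch {row.pitch} outside [0,127]")
            if not 1 <= row.velocity <= 127:
                raise SMFError(f"velocity {row.velocity} outside [1,127]")
            on_tick = _note_ticks(float(row.onset_s), config)
            off_tick = max(on_tick + 1, _note_ticks(float(row.offset_s), config))
            events.append(
                (on_tick, _ON, ch, int(row.pitch),
                 bytes([0x90 | ch, int(row.pitch), int(row.velocity)]))
            )
            events.append(
                (off_tick, _OFF, ch, int(row.pitch),
                 bytes([0x80 | ch, int(row.pitch), 0]))
            )
        events.sort(key=lambda e: e[:4])
        name = f"track {int(track_id)}".encode("ascii")
        payload = _vlq(0) + _meta(_META_TRACK_NAME, name)
        last_tick = 0
        for tick, _, _, _, msg in events:
            payload += _vlq(tick - last_tick) + msg
            last_tick = tick
        payload += _vlq(0) + _meta(_META_END_OF_TRACK, b"")
        chunks.append(_chunk(b"MTrk", payload))

    header = struct.pack(">HHH", 1, len(chunks), config.ppq)
    return _chunk(b"MThd", header) + b"".join(chunks)


class _ByteReader:
    def __init__(self, data: bytes):
        self.data = data
        self.pos = 0

    def read(self, n: int) -> bytes:
        if self.pos + n > len(self.data):
            raise SMFError("truncated MIDI data")
        out = self.data[self.pos : self.pos + n]
        self.pos += n
        return out

    def u8(self) -> int:
        return self.read(1)[0]

    def vlq(self) -> int:
        value = 0
        for _ in range(4):
            b = self.u8()
            value = (value << 7) | (b & 0x7F)
            if not b & 0x80:
                return value
        raise SMFError("variable-length quantity longer than 4 bytes")

    @property
    def exhausted(self) -> bool:
        return self.pos >= len(self.data)


def _parse_track(
    payload: bytes,
) -> tuple[list[tuple[int, int, int, int, int]], str | None, int | None]:
    """Decode one MTrk payload.

    Returns (note events as (tick, kind, channel, pitch, velocity) with
    kind in {_ON, _OFF}), the track name if present, and the first tempo
    found (us per quarter) if any.
    """
    r = _ByteReader(payload)
    tick = 0
    running_status: int | None = None
    notes: list[tuple[int, int, int, int, int]] = []
    name: str | None = None
    tempo: int | None = None
    while not r.exhausted:
        tick += r.vlq()
        status = r.u8()
        if status == 0xFF:
            meta_type = r.u8()
            data = r.read(r.vlq())
            if meta_type == _META_SET_TEMPO and tempo is None:
                if len(data) != 3:
                    raise SMFError("tempo meta-event must have 3 data bytes")
                tempo = int.from_bytes(data, "big")
            elif meta_type == _META_TRACK_NAME and name is None:
                name = data.decode("latin-1")
            elif meta_type == _META_END_OF_TRACK:
                break
            continue
        if status in (0xF0, 0xF7):  # sysex
            r.read(r.vlq())
            running_status = None
            continue
        if status & 0x80:
            running_status = status
            first_data = r.u8()
        else:  # running status: this byte is data
            if running_status is None:
                raise SMFError("data byte with no running status")
            first_data = status
            status = running_status
        kind = status & 0xF0
        channel = status & 0x0F
        if kind in (0x80, 0x90, 0xA0, 0xB0, 0xE0):
            second_data = r.u8()
        elif kind in (0xC0, 0xD0):
            second_data = 0
        else:
            raise SMFError(f"unexpected status byte 0x{status:02X}")
        if kind == 0x90 and second_data > 0:
            notes.append((tick, _ON, channel, first_data, second_data))
        elif kind == 0x80 or (kind == 0x90 and second_data == 0):
            notes.append((tick, _OFF, channel, first_data, second_data))
    return notes, name, tempo


def parse_smf(data: bytes) -> tuple[NoteTable, SonificationConfig]:
    """Parse SMF bytes back into a note table and the config subset it encodes.

    Each note-on is paired with the next note-off of the same (track,
    channel, pitch); onsets and offsets are reported in real playback
    seconds, honoring the file's tempo meta-event.  The returned config
    carries the file's ppq and (playback) tempo; grid and note duration are
    not stored in SMF and keep their defaults.

    Raises :class:`SMFError` on malformed chunks or unpaired note-on/off.
    """
    r = _ByteReader(data)
    if r.read(4) != b"MThd":
        raise SMFError("not a Standard MIDI File (missing MThd)")
    header_len = struct.unpack(">I", r.read(4))[0]
    if header_len < 6:
        raise SMFError(f"MThd length {header_len} < 6")
    fmt, ntrks, division = struct.unpack(">HHH", r.read(6))
    r.read(header_len - 6)
    if fmt not in (0, 1):
        raise SMFError(f"unsupported SMF format {fmt}")
    if division & 0x8000:
        raise SMFError("SMPTE time division is not supported")
    ppq = division
    if ppq == 0:
        raise SMFError("ppq must be positive")

    tempo: int | None = None
    rows: list[tuple[int, int, int, int, float, float]] = []
    note_track_index = 0
    for chunk_no in range(ntrks):
        if r.read(4) != b"MTrk":
            raise SMFError(f"chunk {chunk_no} is not an MTrk")
        length = struct.unpack(">I", r.read(4))[0]
        events, name, track_tempo = _parse_track(r.read(length))
        if tempo is None and track_tempo is not None:
            tempo = track_tempo
        if not events:
            continue
        track_id = note_track_index
        if name is not None:
            m = re.fullmatch(r"track (\d+)", name)
            if m:
                track_id = int(m.group(1))
        note_track_index += 1
        pending: dict[tuple[int, int], list[tuple[int, int]]] = {}
        for tick, kind, channel, pitch, velocity in sorted(
            events, key=lambda e: (e[0], e[1])
        ):
            key = (channel, pitch)
            if kind == _ON:
                pending.setdefault(key, []).append((tick, velocity))
            else:
                if not pending.get(key):
                    raise SMFError(
                        f"note-off without matching note-on (channel {channel}, pitch {pitch})"
                    )
                on_tick, on_vel = pending[key].pop(0)
                off_tick = max(tick, on_tick + 1)
                rows.append((track_id, channel, pitch, on_vel, on_tick, off_tick))
        unpaired = {k: v for k, v in pending.items() if v}
        if unpaired:
            raise SMFError(f"note-on without matching note-off: {sorted(unpaired)}")

    tempo = tempo if tempo is not None else 500_000
    sec_per_tick = tempo / ppq / 1e6
    if rows:
        frame = pd.DataFrame(
            rows, columns=["track", "channel", "pitch", "velocity", "on", "off"]
        )
        table = NoteTable(
            pd.DataFrame(
                {
                    "track": frame["track"].astype(np.int64),
                    "channel": frame["channel"].astype(np.int64),
                    "pitch": frame["pitch"].astype(np.int64),
                    "velocity": frame["velocity"].astype(np.int64),
                    "onset_s": frame["on"] * sec_per_tick,
                    "offset_s": frame["off"] * sec_per_tick,
                }
            )
        )
    else:
        table = NoteTable()
    config = SonificationConfig(tempo_us_per_quarter=tempo, ppq=ppq)
    return table, config
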