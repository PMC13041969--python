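"""Pitch assignment and the six-column note representation.

A sonified recording is a table of notes with six columns — track, channel,
pitch, velocity, onset and offset — the musical analog of a spike raster.
Two pitch policies cover the demonstrated use cases:

* **one pitch per unit**: each neuron is assigned its own pitch on a musical
  scale (pentatonic by default, to minimize dissonance among concurrently
  sounding units), the auditory analog of anatomical pseudocolor;
* **log-rate**: a continuous rhythm rate (e.g. instantaneous sniff rate,
  the reciprocal inter-inhalation interval) is mapped to pitch on a
  logarithmic axis, so equal rate ratios sound as equal musical intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from neuromidi.errors import PitchMapError, PitchRangeError, RateError
from neuromidi.events import EventStream

__all__ = [
    "ScaleDef",
    "PENTATONIC_MAJOR",
    "PitchMap",
    "LogRatePolicy",
    "NoteTable",
    "scale_pitch",
    "assign_unit_pitches",
    "instantaneous_rate",
    "rate_to_pitch",
    "events_to_notes",
]


@dataclass(frozen=True)
class ScaleDef:
    """A musical scale: a root pitch plus in-octave degree offsets.

    ``degrees`` are strictly increasing semitone offsets within one octave
    (each in 0-11).  Scale index *i* maps to
    ``root + 12 * (i // len(degrees)) + degrees[i % len(degrees)]``.
    """

    root_pitch: int = 48
    degrees: tuple[int, ...] = (0, 2, 4, 7, 9)

    def __post_init__(self) -> None:
        if not 0 <= self.root_pitch <= 127:
            raise PitchRangeError(f"root_pitch must be in [0,127], got {self.root_pitch}")
        degs = tuple(int(d) for d in self.degrees)
        if not degs:
            raise PitchMapError("scale needs at least one degree")
        if any(not 0 <= d <= 11 for d in degs):
            raise PitchMapError(f"scale degrees must lie in [0,11], got {degs}")
        if any(b <= a for a, b in zip(degs, degs[1:])):
            raise PitchMapError(f"scale degrees must be strictly increasing, got {degs}")
        object.__setattr__(self, "degrees", degs)

    def contains(self, pitch: int) -> bool:
        """Whether ``pitch`` lies on this scale (any octave above the root)."""
        return (pitch - self.root_pitch) % 12 in self.degrees

    def pitches_up_to(self, limit: int = 127) -> list[int]:
        """All scale pitches from the root up to ``limit`` inclusive."""
        out, i = [], 0
        while True:
            try:
                p = scale_pitch(self, i)
            except PitchRangeError:
                break
            if p > limit:
                break
            out.append(p)
            i += 1
        return out


#: C major pentatonic rooted at C3 (MIDI 48): the default unit scale.
PENTATONIC_MAJOR = ScaleDef(root_pitch=48, degrees=(0, 2, 4, 7, 9))


def scale_pitch(scale: ScaleDef, index: int) -> int:
    """Pitch of scale degree ``index`` (0-based, octaves unfold upward)."""
    if index < 0:
        raise PitchMapError(f"scale index must be >= 0, got {index}")
    n = len(scale.degrees)
    pitch = scale.root_pitch + 12 * (index // n) + scale.degrees[index % n]
    if pitch > 127:
        raise PitchRangeError(
            f"scale index {index} on root {scale.root_pitch} gives pitch {pitch} > 127"
        )
    return pitch


@dataclass(frozen=True)
class PitchMap:
    """Injective assignment of event identities to MIDI pitches."""

    mapping: Mapping[object, int]

    def __post_init__(self) -> None:
        mapping = dict(self.mapping)
        for ident, p in mapping.items():
            if not 0 <= int(p) <= 127:
                raise PitchRangeError(f"pitch {p} for identity {ident!r} outside [0,127]")
        if len(set(mapping.values())) != len(mapping):
            raise PitchMapError("pitch map must be injective (distinct pitches per identity)")
        object.__setattr__(self, "mapping", mapping)

    def __getitem__(self, ident: object) -> int:
        try:
            return self.mapping[ident]
        except KeyError:
            raise PitchMapError(f"identity {ident!r} has no pitch assignment") from None

    def __len__(self) -> int:
        return len(self.mapping)

    def __contains__(self, ident: object) -> bool:
        return ident in self.mapping


def assign_unit_pitches(
    unit_ids: Sequence,
    scale: ScaleDef = PENTATONIC_MAJOR,
    ordering: Callable[[Sequence], Sequence] | None = None,
    auto_lower_root: bool = True,
) -> PitchMap:
    """Assign one scale pitch per unit: the "one pitch per neuron" map.

    Units are sorted (ascending id by default; pass ``ordering`` to impose
    e.g. probe-depth order) and given consecutive scale degrees starting at
    the scale root.  Injective by construction.

    A pentatonic scale has only five pitches per octave, so large
    populations (e.g. a 52-unit session) exceed what fits above a
    mid-keyboard root.  With ``auto_lower_root`` (default) the root is
    dropped an octave at a time until all units fit; this changes only the
    octave, never the pitch classes, so scale membership is preserved.

    Raises
    ------
    PitchMapError
        Duplicate unit ids.
    PitchRangeError
        More units than the scale can represent below pitch 128 even at
        the lowest root octave.
    """
    ids = list(unit_ids)
    if len(set(ids)) != len(ids):
        raise PitchMapError("unit ids must be unique")
    ordered = list(ordering(ids)) if ordering is not None else sorted(ids)
    if set(ordered) != set(ids):
        raise PitchMapError("ordering policy must permute the unit ids")
    if auto_lower_root:
        while len(scale.pitches_up_to(127)) < len(ordered) and scale.root_pitch >= 12:
            scale = ScaleDef(scale.root_pitch - 12, scale.degrees)
    mapping = {u: scale_pitch(scale, i) for i, u in enumerate(ordered)}
    return PitchMap(mapping)


def instantaneous_rate(times: np.ndarray) -> np.ndarray:
    """Per-event instantaneous rate in Hz from strictly increasing times.

    ``rate[i] = 1 / (t[i] - t[i-1])`` for ``i >= 1``; the first event, which
    has no preceding interval, is assigned the second event's rate so that
    it still produces a note.
    """
    times = np.asarray(times, dtype=float)
    if times.size < 2:
        raise RateError(f"need >= 2 events to compute a rate, got {times.size}")
    intervals = np.diff(times)
    if np.any(intervals <= 0):
        raise RateError("event times must be strictly increasing (zero interval found)")
    rates = np.empty_like(times)
    rates[1:] = 1.0 / intervals
    rates[0] = rates[1]
    return rates


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def rate_to_pitch(
    rate: float,
    r_min: float,
    r_max: float,
    p_lo: int = 36,
    p_hi: int = 84,
    quantize_scale: ScaleDef | None = None,
) -> int:
    """Map a rate (Hz) to a pitch on a log axis.

    ``p = p_lo + (p_hi - p_lo) * (ln rate - ln r_min) / (ln r_max - ln r_min)``,
    clamped to ``[p_lo, p_hi]``, rounded to the nearest integer (ties away
    from zero).  With ``quantize_scale`` the result is snapped to the nearest
    scale pitch, ties toward the lower pitch.
    """
    if not rate > 0:
        raise RateError(f"rate must be > 0 Hz, got {rate}")
    if not 0 < r_min < r_max:
        raise RateError(f"need 0 < r_min < r_max, got {r_min}, {r_max}")
    if not 0 <= p_lo < p_hi <= 127:
        raise PitchRangeError(f"need 0 <= p_lo < p_hi <= 127, got {p_lo}, {p_hi}")
    frac = (math.log(rate) - math.log(r_min)) / (math.log(r_max) - math.log(r_min))
    p = p_lo + (p_hi - p_lo) * frac
    p = min(max(p, float(p_lo)), float(p_hi))
    pitch = _round_half_away(p)
    if quantize_scale is not None:
        candidates = quantize_scale.pitches_up_to(127)
        if not candidates:
            raise PitchRangeError("quantize scale has no representable pitches")
        # nearest scale pitch; on a distance tie prefer the lower pitch
        pitch = min(candidates, key=lambda c: (abs(c - pitch), c))
    return pitch


@dataclass(frozen=True)
class LogRatePolicy:
    """Parameters of the log-rate pitch policy.

    ``r_min``/``r_max`` default to the 1st and 99th percentiles of the
    observed rates when left ``None``; explicit values always win.
    """

    r_min: float | None = None
    r_max: float | None = None
    p_lo: int = 36
    p_hi: int = 84
    quantize_scale: ScaleDef | None = None

    def resolve_range(self, rates: np.ndarray) -> tuple[float, float]:
        r_min = self.r_min if self.r_min is not None else float(np.percentile(rates, 1))
        r_max = self.r_max if self.r_max is not None else float(np.percentile(rates, 99))
        if not 0 < r_min < r_max:
            raise RateError(
                f"resolved rate range invalid: r_min={r_min}, r_max={r_max}"
            )
        return r_min, r_max


NOTE_COLUMNS = ("track", "channel", "pitch", "velocity", "onset_s", "offset_s")


@dataclass(frozen=True)
class NoteTable:
    """The six-column note representation: one row per note.

    Columns: ``track`` (non-negative int), ``channel`` (0-15), ``pitch``
    (0-127), ``velocity`` (1-127), ``onset_s``, ``offset_s`` (seconds,
    ``offset_s > onset_s``).  Rows are sorted by onset.
    """

    frame: pd.DataFrame = field(default_factory=lambda: _empty_frame())

    def __post_init__(self) -> None:
        df = self.frame
        missing = set(NOTE_COLUMNS) - set(df.columns)
        if missing:
            raise PitchMapError(f"note table missing columns: {sorted(missing)}")
        df = df.loc[:, list(NOTE_COLUMNS)].copy()
        for col in ("track", "channel", "pitch", "velocity"):
            df[col] = df[col].astype(np.int64)
        for col in ("onset_s", "offset_s"):
            df[col] = df[col].astype(float)
        if len(df):
            if df["track"].min() < 0:
                raise PitchMapError("track indices must be >= 0")
            if df["channel"].min() < 0 or df["channel"].max() > 15:
                raise PitchMapError("channels must be in [0,15]")
            if df["pitch"].min() < 0 or df["pitch"].max() > 127:
                raise PitchRangeError("pitches must be in [0,127]")
            if df["velocity"].min() < 1 or df["velocity"].max() > 127:
                raise PitchMapError("velocities must be in [1,127]")
            if not (df["offset_s"] > df["onset_s"]).all():
                raise PitchMapError("every note needs offset_s > onset_s")
            df = df.sort_values("onset_s", kind="stable", ignore_index=True)
        else:
            df = df.reset_index(drop=True)
        object.__setattr__(self, "frame", df)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def tracks(self) -> np.ndarray:
        """Sorted distinct track indices present."""
        return np.unique(self.frame["track"].to_numpy()) if len(self) else np.array([], int)

    def concat(self, other: "NoteTable") -> "NoteTable":
        return NoteTable(pd.concat([self.frame, other.frame], ignore_index=True))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NoteTable):
            return NotImplemented
        if len(self) != len(other):
            return False
        a = self.frame.sort_values(list(NOTE_COLUMNS), kind="stable", ignore_index=True)
        b = other.frame.sort_values(list(NOTE_COLUMNS), kind="stable", ignore_index=True)
        return a.equals(b)


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "track": pd.Series(dtype=np.int64),
            "channel": pd.Series(dtype=np.int64),
            "pitch": pd.Series(dtype=np.int64),
            "velocity": pd.Series(dtype=np.int64),
            "onset_s": pd.Series(dtype=float),
            "offset_s": pd.Series(dtype=float),
        }
    )


def _resolve_overlaps(df: pd.DataFrame) -> pd.DataFrame:
    """Truncate earlier notes so equal (track, channel, pitch) notes never overlap.

    Needed for well-formed note-on/note-off pairing: without it a second
    note-on of the same pitch would be silently merged by most players.
    Changes durations only, never the note count.
    """
    if len(df) < 2:
        return df
    df = df.sort_values("onset_s", kind="stable", ignore_index=True)
    for _, idx in df.groupby(["track", "channel", "pitch"], sort=False).groups.items():
        idx = list(idx)
        for a, b in zip(idx, idx[1:]):
            if df.at[a, "offset_s"] > df.at[b, "onset_s"]:
                df.at[a, "offset_s"] = df.at[b, "onset_s"]
    # a truncated-to-zero note would violate offset > onset; nudge by keeping
    # a minimal positive duration equal to one microsecond
    bad = df["offset_s"] <= df["onset_s"]
    df.loc[bad, "offset_s"] = df.loc[bad, "onset_s"] + 1e-6
    return df


def events_to_notes(
    events: EventStream,
    pitch_policy: PitchMap | LogRatePolicy,
    track: int = 0,
    channel: int = 0,
    velocity: int = 100,
    duration_s: float = 0.010,
) -> NoteTable:
    """Turn an event stream into notes: one note per event.

    Onset is the event time; offset is onset plus ``duration_s`` (default a
    constant 10 ms).  Pitch comes from the policy: a :class:`PitchMap` looks
    each identity up ("one pitch per neuron"); a :class:`LogRatePolicy`
    computes the instantaneous event rate and maps it to pitch on a log
    axis.  Overlapping equal-pitch notes are truncated (earlier offset cut
    to the later onset), which changes durations but never the note count.
    """
    if not duration_s > 0:
        raise PitchMapError(f"duration_s must be > 0, got {duration_s}")
    n = len(events)
    if n == 0:
        return NoteTable()
    if isinstance(pitch_policy, PitchMap):
        pitches = [pitch_policy[lab] for lab in events.labels]
    else:
        rates = instantaneous_rate(events.times)
        r_min, r_max = pitch_policy.resolve_range(rates)
        pitches = [
            rate_to_pitch(
                r, r_min, r_max, pitch_policy.p_lo, pitch_policy.p_hi,
                pitch_policy.quantize_scale,
            )
            for r in rates
        ]
    df = pd.DataFrame(
        {
            "track": np.full(n, track, dtype=np.int64),
            "channel": np.full(n, channel, dtype=np.int64),
            "pitch": np.asarray(pitches, dtype=np.int64),
            "velocity": np.full(n, velocity, dtype=np.int64),
            "onset_s": events.times.astype(float),
            "offset_s": events.times.astype(float) + float(duration_s),
        }
    )
    return NoteTable(_resolve_overlaps(df))
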