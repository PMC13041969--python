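"""Sonification configuration: grid, note length, tempo and track instruments."""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

from neuromidi.errors import ConfigError

__all__ = ["SonificationConfig", "resolve_ppq", "PERCUSSION", "PERCUSSION_CHANNEL"]

#: Sentinel instrument value routing a track to the General-MIDI drum channel.
PERCUSSION = "percussion"

#: General-MIDI percussion channel (channel 10, zero-indexed).
PERCUSSION_CHANNEL = 9

#: Largest ticks-per-quarter value representable in an SMF header (15 bits).
MAX_PPQ = 32767


def resolve_ppq(grid_per_s: float, tempo_us_per_quarter: int = 500_000) -> int:
    """Smallest PPQ realizing the time grid with at most one tick of error.

    Ticks per second is ``ppq * 1e6 / tempo``; choosing
    ``ppq = ceil(grid_per_s * tempo / 1e6)`` makes the tick no longer than
    the grid step, so every grid point is within one tick.  Capped at the
    SMF header's 15-bit maximum.
    """
    if not grid_per_s > 0:
        raise ConfigError(f"grid_per_s must be > 0, got {grid_per_s}")
    return min(MAX_PPQ, max(1, math.ceil(grid_per_s * tempo_us_per_quarter / 1e6)))


@dataclass(frozen=True)
class SonificationConfig:
    """Everything that shapes the emitted MIDI besides the notes themselves.

    Attributes
    ----------
    grid_per_s
        Time-grid resolution in points per second; onsets and offsets are
        quantized to this grid.  Default 1e4 (0.1 ms steps).
    duration_s
        Default note length in seconds (10 ms).
    velocity
        Constant note-on velocity (1-127).
    tempo_us_per_quarter
        Base tempo in microseconds per quarter note (500000 = 120 BPM).
        This is the *data* tempo; playback slow-down is applied on top.
    ppq
        Ticks per quarter note.  The defaults (tempo 500000, ppq 5000)
        make one tick exactly 100 us = one grid step.
    slowdown
        Playback slow-down factor (>= 1).  Realized by scaling the tempo
        meta-event only, so tick values are bit-identical across factors;
        demonstrations use 3 (one-third real-time speed).
    track_instruments
        Map from note-table track index to a General-MIDI program number
        (0-127) or the string ``"percussion"`` to route that track to the
        drum channel.
    """

    grid_per_s: float = 1e4
    duration_s: float = 0.010
    velocity: int = 100
    tempo_us_per_quarter: int = 500_000
    ppq: int = 5000
    slowdown: float = 1.0
    track_instruments: Mapping[int, int | str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.grid_per_s > 0:
            raise ConfigError(f"grid_per_s must be > 0, got {self.grid_per_s}")
        if not self.duration_s > 0:
            raise ConfigError(f"duration_s must be > 0, got {self.duration_s}")
        if not 1 <= self.velocity <= 127:
            raise ConfigError(f"velocity must be in [1,127], got {self.velocity}")
        if not self.tempo_us_per_quarter >= 1:
            raise ConfigError("tempo_us_per_quarter must be >= 1")
        if not 1 <= self.ppq <= MAX_PPQ:
            raise ConfigError(f"ppq must be in [1,{MAX_PPQ}], got {self.ppq}")
        if not self.slowdown >= 1:
            raise ConfigError(f"slowdown must be >= 1, got {self.slowdown}")
        insts = {}
        for trk, inst in dict(self.track_instruments).items():
            if inst != PERCUSSION and not (isinstance(inst, int) and 0 <= inst <= 127):
                raise ConfigError(
                    f"instrument for track {trk} must be 0-127 or 'percussion', got {inst!r}"
                )
            insts[int(trk)] = inst
        object.__setattr__(self, "track_instruments", insts)

    @property
    def seconds_per_tick(self) -> float:
        """Data-time seconds per tick (before slow-down)."""
        return self.tempo_us_per_quarter / self.ppq / 1e6

    @property
    def playback_tempo_us_per_quarter(self) -> int:
        """Tempo actually written to the file: base tempo times slow-down."""
        tempo = round(self.tempo_us_per_quarter * self.slowdown)
        if tempo > 0xFFFFFF:
            raise ConfigError(f"slowed tempo {tempo} exceeds the 24-bit SMF limit")
        return tempo

    def with_grid(self, grid_per_s: float) -> "SonificationConfig":
        """New config on a different grid, re-deriving a matching PPQ."""
        return replace(
            self, grid_per_s=grid_per_s,
            ppq=resolve_ppq(grid_per_s, self.tempo_us_per_quarter),
        )
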