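"""Synthetic sessions with the statistical structure of the demonstrated use cases.

Two scenarios are modeled:

* **grooming** — a freely moving mouse whose breathing switches among a few
  rhythmic states (slow, intermediate "grooming", fast), each persisting for
  seconds to minutes, recorded together with multi-unit olfactory-bulb
  background activity.  Breathing is a semi-Markov point process: state
  dwell times are exponential, and within a state inter-inhalation intervals
  are drawn uniformly from the reciprocal of the state's rate band, so every
  instantaneous rate lies inside the band by construction.
* **blink** — visual-cortex units firing in a coarse-to-fine temporal
  sequence after each gaze shift and each blink: unit *k* fires once per
  trigger at ``base_latency + k * latency_step`` plus Gaussian jitter.

Everything is reproducible from an integer seed, and fixture directories are
written in exactly the formats the input module reads (NPY spike arrays,
``params.py``, ``cluster_group.tsv``, event CSVs) plus a ground-truth JSON
sidecar.  All generated data are synthetic stand-ins for the original
recordings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from neuromidi.errors import ConfigError
from neuromidi.events import EventStream, SpikeTable, write_event_file

__all__ = [
    "BreathingStateSpec",
    "SyntheticSession",
    "DEFAULT_BREATHING_STATES",
    "simulate_poisson_units",
    "simulate_breathing",
    "simulate_sequential_responses",
    "make_session_fixture",
    "recover_states_from_pitches",
    "median_response_latencies",
]

DEFAULT_SAMPLE_RATE_HZ = 30_000.0


@dataclass(frozen=True)
class BreathingStateSpec:
    """One breathing state: a name, a rate band (Hz) and a mean dwell time."""

    name: str
    rate_band_hz: tuple[float, float]
    mean_dwell_s: float = 20.0

    def __post_init__(self) -> None:
        low, high = self.rate_band_hz
        if not 0 < low <= high:
            raise ConfigError(f"rate band needs 0 < low <= high, got {self.rate_band_hz}")
        if not self.mean_dwell_s > 0:
            raise ConfigError(f"mean dwell must be > 0 s, got {self.mean_dwell_s}")


#: Slow / intermediate ("grooming") / fast breathing, disjoint rate bands.
DEFAULT_BREATHING_STATES = (
    BreathingStateSpec("slow", (2.0, 4.0)),
    BreathingStateSpec("grooming", (5.0, 8.0)),
    BreathingStateSpec("fast", (9.0, 13.0)),
)


@dataclass(frozen=True)
class SyntheticSession:
    """A complete synthetic recording: breathing, spikes and gaze events."""

    inhalation_times: EventStream
    state_labels: tuple[str, ...]
    spikes: SpikeTable
    gaze_shift_times: EventStream
    seed: int
    extra: dict = field(default_factory=dict)


def simulate_poisson_units(
    n_units: int,
    rates_hz: Sequence[float] | float,
    duration_s: float,
    seed: int,
) -> SpikeTable:
    """Independent homogeneous Poisson spike trains, merged and time-sorted.

    Unit ids are ``0..n_units-1``; ``rates_hz`` may be a scalar applied to
    all units or a per-unit sequence.
    """
    if n_units < 0:
        raise ConfigError(f"n_units must be >= 0, got {n_units}")
    if duration_s < 0:
        raise ConfigError(f"duration_s must be >= 0, got {duration_s}")
    rates = np.broadcast_to(np.asarray(rates_hz, dtype=float), (n_units,))
    if n_units and rates.min() < 0:
        raise ConfigError("rates must be >= 0")
    rng = np.random.default_rng(seed)
    all_times, all_units = [], []
    for unit in range(n_units):
        rate = rates[unit]
        if rate == 0 or duration_s == 0:
            continue
        # draw enough exponential ISIs to cover the window, then trim
        n_expected = int(np.ceil(rate * duration_s + 6 * np.sqrt(rate * duration_s) + 10))
        times = np.cumsum(rng.exponential(1.0 / rate, size=n_expected))
        while times.size and times[-1] < duration_s:
            times = np.concatenate(
                [times, times[-1] + np.cumsum(rng.exponential(1.0 / rate, size=n_expected))]
            )
        times = times[times < duration_s]
        all_times.append(times)
        all_units.append(np.full(times.size, unit, dtype=np.int64))
    if all_times:
        times = np.concatenate(all_times)
        units = np.concatenate(all_units)
        order = np.argsort(times, kind="stable")
        times, units = times[order], units[order]
    else:
        times = np.array([], dtype=float)
        units = np.array([], dtype=np.int64)
    return SpikeTable(unit_ids=units, times_s=times, sampling_rate_hz=DEFAULT_SAMPLE_RATE_HZ)


def simulate_breathing(
    states: Sequence[BreathingStateSpec] = DEFAULT_BREATHING_STATES,
    duration_s: float = 120.0,
    seed: int = 0,
) -> tuple[EventStream, tuple[str, ...]]:
    """State-switching inhalation times with per-inhalation ground-truth labels.

    The state sequence is semi-Markov: dwell times are exponential with each
    state's mean, and the next state is chosen uniformly among the others.
    Within a state, inter-inhalation intervals are uniform over the
    reciprocal of the rate band, so every interval's instantaneous rate lies
    inside the band by construction.  An interval that would cross a state
    switch is redrawn from the new state's band, keeping each inhalation's
    preceding interval consistent with its own label.
    """
    states = list(states)
    if not states:
        raise ConfigError("need at least one breathing state")
    if not duration_s > 0:
        raise ConfigError(f"duration_s must be > 0, got {duration_s}")
    rng = np.random.default_rng(seed)

    def draw_isi(spec: BreathingStateSpec) -> float:
        low, high = spec.rate_band_hz
        return float(rng.uniform(1.0 / high, 1.0 / low))

    state_idx = int(rng.integers(len(states)))
    state_end = float(rng.exponential(states[state_idx].mean_dwell_s))
    t = 0.0
    times: list[float] = []
    labels: list[str] = []
    while True:
        isi = draw_isi(states[state_idx])
        while t + isi > state_end and len(states) > 1:
            others = [i for i in range(len(states)) if i != state_idx]
            state_idx = int(others[rng.integers(len(others))])
            state_end = max(state_end, t) + float(
                rng.exponential(states[state_idx].mean_dwell_s)
            )
            isi = draw_isi(states[state_idx])
        t += isi
        if t >= duration_s:
            break
        times.append(t)
        labels.append(states[state_idx].name)
    return (
        EventStream(labels=tuple(labels), times=np.array(times, dtype=float)),
        tuple(labels),
    )


def simulate_sequential_responses(
    n_units: int,
    trigger_times: EventStream | np.ndarray,
    base_latency_s: float = 0.020,
    latency_step_s: float = 0.010,
    jitter_sd_s: float = 0.0,
    seed: int = 0,
) -> SpikeTable:
    """Trigger-locked sequential firing: unit *k* fires once per trigger.

    Spike time per (trigger, unit) is
    ``trigger + base_latency_s + k * latency_step_s + N(0, jitter_sd_s)``,
    emulating the coarse-to-fine latency ordering of visual-cortex responses
    to gaze shifts and blinks.
    """
    if n_units < 1:
        raise ConfigError(f"n_units must be >= 1, got {n_units}")
    if latency_step_s < 0:
        raise ConfigError(f"latency_step_s must be >= 0, got {latency_step_s}")
    triggers = (
        trigger_times.times if isinstance(trigger_times, EventStream)
        else np.asarray(trigger_times, dtype=float)
    )
    rng = np.random.default_rng(seed)
    if triggers.size == 0:
        return SpikeTable(
            unit_ids=np.array([], dtype=np.int64),
            times_s=np.array([], dtype=float),
            sampling_rate_hz=DEFAULT_SAMPLE_RATE_HZ,
        )
    latencies = base_latency_s + latency_step_s * np.arange(n_units)
    times = (triggers[:, None] + latencies[None, :]).ravel()
    if jitter_sd_s > 0:
        times = times + rng.normal(0.0, jitter_sd_s, size=times.size)
    units = np.tile(np.arange(n_units, dtype=np.int64), triggers.size)
    if times.min() < 0:
        raise ConfigError("negative spike time produced; check base latency and jitter")
    order = np.argsort(times, kind="stable")
    return SpikeTable(
        unit_ids=units[order],
        times_s=times[order],
        sampling_rate_hz=DEFAULT_SAMPLE_RATE_HZ,
    )


def recover_states_from_pitches(
    pitches: Sequence[int],
    states: Sequence[BreathingStateSpec],
    r_min: float,
    r_max: float,
    p_lo: int = 36,
    p_hi: int = 84,
) -> list[str]:
    """Classify drum-track pitches back to breathing-state names.

    Each state's rate band maps (monotonically) to a pitch band under the
    same log-rate mapping used for sonification; a note is assigned to the
    state whose pitch band contains it.  With disjoint rate bands covered
    by ``[r_min, r_max]`` this recovers the generator's ground truth
    exactly, which is the closed-loop check that the sonified drum pitch
    carries the state information.
    """
    from neuromidi.pitch import rate_to_pitch  # local import avoids cycle at module load

    bands = {
        s.name: (
            rate_to_pitch(s.rate_band_hz[0], r_min, r_max, p_lo, p_hi),
            rate_to_pitch(s.rate_band_hz[1], r_min, r_max, p_lo, p_hi),
        )
        for s in states
    }
    out = []
    for p in pitches:
        matches = [name for name, (lo, hi) in bands.items() if lo <= p <= hi]
        out.append(matches[0] if len(matches) == 1 else "ambiguous")
    return out


def median_response_latencies(
    spikes: SpikeTable,
    trigger_times: np.ndarray,
    n_units: int,
    window_s: float = 0.25,
) -> np.ndarray:
    """Per-unit median latency of the first spike after each trigger.

    Used to verify that trigger-locked sequences are audible in the data:
    with jitter much smaller than the latency step, medians must increase
    strictly with unit index.
    """
    medians = np.full(n_units, np.nan)
    for unit in range(n_units):
        times = spikes.times_s[spikes.unit_ids == unit]
        lats = []
        for t in np.asarray(trigger_times, dtype=float):
            after = times[(times > t) & (times <= t + window_s)]
            if after.size:
                lats.append(after[0] - t)
        if lats:
            medians[unit] = float(np.median(lats))
    return medians


def _write_spike_dir(spikes: SpikeTable, directory: Path) -> None:
    directory.mkdir(parents=True, exist_ok=True)
    samples = np.round(spikes.times_s * spikes.sampling_rate_hz).astype(np.int64)
    np.save(directory / "spike_times.npy", samples)
    np.save(directory / "spike_clusters.npy", spikes.unit_ids.astype(np.int64))
    (directory / "params.py").write_text(
        f"sample_rate = {spikes.sampling_rate_hz!r}\n"
    )
    units = spikes.units
    with (directory / "cluster_group.tsv").open("w") as fh:
        fh.write("cluster_id\tgroup\n")
        for u in units:
            label = spikes.curation_labels.get(int(u), "good")
            fh.write(f"{int(u)}\t{label}\n")


def make_session_fixture(
    out_dir: str | Path,
    seed: int = 0,
    scenario: str = "grooming",
    duration_s: float = 120.0,
    n_units: int = 52,
) -> SyntheticSession:
    """Write a complete synthetic session to disk and return it.

    ``"grooming"``: three-state breathing (slow 2-4 Hz, intermediate
    "grooming" 5-8 Hz, fast 9-13 Hz) plus ``n_units`` background Poisson
    units (default 52, matching the demonstrated olfactory-bulb session).
    ``"blink"``: sequential responses locked to both gaze-shift and blink
    events, with small jitter relative to the latency step.

    The directory contains a ``spikes/`` subdirectory in the spike-sorting
    convention, event CSVs, and ``ground_truth.json`` with state labels and
    generator parameters.  Identical seeds yield byte-identical directories.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ConfigError(f"cannot create fixture directory {out_dir}: {exc}") from exc

    rng = np.random.default_rng(seed)
    sub_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=4)]

    if scenario == "grooming":
        inhalations, labels = simulate_breathing(
            DEFAULT_BREATHING_STATES, duration_s=duration_s, seed=sub_seeds[0]
        )
        unit_rates = 10 ** rng.uniform(-0.3, 1.0, size=n_units)  # ~0.5-10 Hz lognormal-ish
        spikes = simulate_poisson_units(
            n_units, unit_rates, duration_s=duration_s, seed=sub_seeds[1]
        )
        gaze = EventStream(labels=(), times=np.array([], dtype=float))
        write_event_file(inhalations, out_dir / "inhalations.csv")
        truth = {
            "scenario": scenario,
            "seed": seed,
            "duration_s": duration_s,
            "state_labels": list(labels),
            "states": [
                {"name": s.name, "rate_band_hz": list(s.rate_band_hz),
                 "mean_dwell_s": s.mean_dwell_s}
                for s in DEFAULT_BREATHING_STATES
            ],
            "n_units": n_units,
        }
    elif scenario == "blink":
        # sparse triggers: gaze shifts ~0.5 Hz, blinks ~0.1 Hz, kept apart
        # so per-trigger responses do not interleave
        n_resp_units = min(n_units, 12)
        gaze_times = np.sort(rng.uniform(1.0, duration_s - 1.0, size=int(duration_s * 0.5)))
        blink_times = np.sort(rng.uniform(1.0, duration_s - 1.0, size=max(3, int(duration_s * 0.1))))
        base, step, jitter = 0.020, 0.010, 0.001
        gaze = EventStream(labels=("gaze_shift",) * gaze_times.size, times=gaze_times)
        blinks = EventStream(labels=("blink",) * blink_times.size, times=blink_times)
        spikes_g = simulate_sequential_responses(
            n_resp_units, gaze, base, step, jitter, seed=sub_seeds[1]
        )
        spikes_b = simulate_sequential_responses(
            n_resp_units, blinks, base, step, jitter, seed=sub_seeds[2]
        )
        merged_times = np.concatenate([spikes_g.times_s, spikes_b.times_s])
        merged_units = np.concatenate([spikes_g.unit_ids, spikes_b.unit_ids])
        spikes = SpikeTable(
            unit_ids=merged_units,
            times_s=merged_times,
            sampling_rate_hz=DEFAULT_SAMPLE_RATE_HZ,
        )
        inhalations = EventStream(labels=(), times=np.array([], dtype=float))
        labels = ()
        write_event_file(gaze, out_dir / "gaze_shifts.csv")
        write_event_file(blinks, out_dir / "blinks.csv")
        truth = {
            "scenario": scenario,
            "seed": seed,
            "duration_s": duration_s,
            "n_units": n_resp_units,
            "base_latency_s": base,
            "latency_step_s": step,
            "jitter_sd_s": jitter,
            "gaze_shift_times": [float(t) for t in gaze_times],
            "blink_times": [float(t) for t in blink_times],
        }
    else:
        raise ConfigError(f"unknown scenario {scenario!r}; use 'grooming' or 'blink'")

    _write_spike_dir(spikes, out_dir / "spikes")
    with (out_dir / "ground_truth.json").open("w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return SyntheticSession(
        inhalation_times=inhalations,
        state_labels=tuple(labels),
        spikes=spikes,
        gaze_shift_times=gaze,
        seed=seed,
        extra=truth,
    )
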