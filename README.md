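# neuromidi

Sonify discrete neural and behavioral events as Standard MIDI Files.

High-dimensional recordings from behaving animals — spike-sorted neural
activity, breathing rhythms, gaze shifts — are hard to browse by eye.
`neuromidi` converts any labeled point process into a multi-track Standard
MIDI File (SMF) so it can be *listened to* alongside video in VLC or a
digital audio workstation. Patterns that a particular quantification would
miss (a breathing rhythm that accompanies grooming, a cortical response to
blinks) become audible.

## The encoding

A sonified recording is a six-column note table — track, channel, pitch,
velocity, onset, offset — built from events by two mapping policies:

- **One pitch per neuron** (`unit_pitch`): each unit *u* is assigned a
  distinct pitch on a musical scale (default C major pentatonic, degrees
  {0, 2, 4, 7, 9}, to minimize dissonance among concurrently sounding
  units). Unit *i* in ascending-id order gets
  `p(i) = root + 12·⌊i/5⌋ + degrees[i mod 5]`.
- **Log-rate** (`log_rate`): for rhythmic events such as inhalations, the
  instantaneous rate `r_i = 1/(t_i − t_{i−1})` is mapped to pitch on a
  logarithmic axis,
  `p = p_lo + (p_hi − p_lo)·(ln r − ln r_min)/(ln r_max − ln r_min)`,
  so equal rate ratios sound as equal musical intervals.

Notes last a constant 10 ms at constant velocity; onsets are quantized to a
grid of 10⁴ points per second. Under the default tempo (120 BPM) and
resolution (5000 ticks per quarter note) one MIDI tick is exactly 100 µs,
so the grid is represented losslessly. Playback slow-down (typically 3×)
is applied by scaling the tempo meta-event only — tick data are
bit-identical at any speed.

## Worked example

Generate a synthetic session (three-state breathing plus 52 Poisson units,
written in the Kilosort/Phy spike-sorting convention), convert it, and
inspect the result:

```
$ neuromidi simulate grooming --seed 7 --out-dir session
wrote grooming session to session: 18497 spikes, 504 inhalations, 0 gaze shifts

$ neuromidi convert session/spikes session/inhalations.csv \
      --out session.mid --slowdown 3
wrote session.mid (19001 notes) and session.mid.manifest.json

$ neuromidi inspect session.mid
file: session.mid
tempo: 1500000 us/quarter, ppq 5000
notes: 19001  playback duration: 360.013 s
  track 0: 18497 notes, pitches 0-122 (52 distinct)
  track 1: 504 notes, pitches 36-84 (41 distinct)
```

Track 0 is the spike train on piano — 52 distinct pitches, one per unit,
all on the pentatonic scale. Track 1 is the inhalation rhythm on the
General-MIDI percussion channel with pitch following log sniff rate. The
120 s session plays in 360 s because of the 3× slow-down (tempo 1 500 000
µs/quarter instead of 500 000). The JSON manifest records the resolved
configuration, per-track summaries and the SHA-256 of the output, so a run
can be reproduced byte-for-byte.

Spike directories are read directly from Kilosort/Phy output
(`spike_times.npy`, `spike_clusters.npy`, `params.py`,
`cluster_group.tsv`; curated `good` units kept by default). Any other
event type is a two-column CSV/TSV of (identity, time in seconds). Full
per-track control — instruments, scales, rate ranges, track indices — goes
in a TOML config file (see `neuromidi convert --help`).

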