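# Methods

## The conversion model

`neuromidi` treats every input — spike-sorted neural activity, inhalation
times, gaze shifts, generic labeled events — as a marked point process:
pairs (identity, time in seconds). Conversion to sound is a pure function
of that process and a configuration:

1. events are mapped to a **six-column note table** (track, channel,
   pitch, velocity, onset, offset);
2. note times are **quantized** to a uniform grid;
3. the table is serialized to a **format-1 Standard MIDI File** with one
   chunk per track plus a conductor track carrying the tempo.

No audio is rendered; the SMF is the product, consumed by any
MIDI-capable player or DAW next to the session video.

## Pitch policies

**One pitch per unit.** Units are ordered (ascending id by default; an
ordering hook accepts e.g. probe-depth order, which is deliberately left to
the caller since no single ordering is canonical) and assigned consecutive
degrees of a scale. The default scale is C major pentatonic — five pitch
classes per octave, chosen so that many simultaneously sounding units stay
consonant. A pentatonic octave holds only five pitches, so a population of
52 units cannot fit above a mid-keyboard root: `assign_unit_pitches`
lowers the root an octave at a time until the population fits (root 0
yields 54 pentatonic pitches ≤ 127). Octave shifts change no pitch
classes, so scale membership is preserved exactly. Assignment is injective
by construction and refuses duplicate ids or populations that cannot fit
at any root octave.

**Log-rate.** For rhythms, the instantaneous rate is the reciprocal
inter-event interval; the first event, which has no preceding interval, is
assigned the second event's rate rather than dropped, so the rhythm's
first beat still sounds. (Consequence: any analysis of rate-coded pitch —
including the state-recovery check below — is defined from the second
event on.) The rate-to-pitch map is linear in log rate between
(`r_min`, `p_lo`) and (`r_max`, `p_hi`), clamped at the ends, rounded to
the nearest integer with ties away from zero. `r_min`/`r_max` default to
the 1st/99th percentiles of the observed rates; explicit values always
win and should be used whenever runs must be comparable. Optional snapping
to a scale takes the nearest scale pitch, ties toward the lower pitch —
both tie rules chosen for determinism, not musicality.

**Overlap rule.** Two notes of the same (track, channel, pitch) may not
overlap, otherwise note-on/note-off pairing is ambiguous in most players;
the earlier note's offset is truncated to the later onset. Truncation
changes durations only — the note count always equals the event count. A
note truncated to zero length keeps a floor duration of 1 µs (one tick
after tick rounding), so no note ever vanishes.

## Timing, ticks and slow-down

Onsets and offsets are quantized to a grid of `grid_per_s` points per
second (default 10⁴, i.e. 100 µs steps — far finer than the 10 ms note
and any behavioral timescale), rounding to the nearest point, ties away
from zero. The grid is realized in MIDI ticks: at the default 120 BPM
tempo (500 000 µs/quarter) and 5000 ticks/quarter, one tick is exactly
100 µs, so quantized times are stored losslessly. For non-default grids,
`resolve_ppq` picks the smallest ticks-per-quarter ≤ 32767 (the SMF
header's 15-bit limit) whose tick is no longer than the grid step.
A note's off-tick is floored to at least one tick after its on-tick.

Slow-down is implemented purely in the tempo meta-event: a factor *k*
multiplies the written tempo, leaving every tick untouched, so files at
different playback speeds differ in exactly three bytes and parse back to
real durations scaled by *k*. Default velocity is 100 (a value the
encoding leaves free; constant by design — velocity- and duration-coding
are out of scope), channel is constant 0, except tracks flagged
`percussion`, which are routed to the General-MIDI drum channel (10,
zero-indexed 9) so kick-drum sounds render in generic players.

Serialization is deterministic: no running status, events at equal ticks
ordered note-off < program-change < note-on then by (channel, pitch), and
each track chunk carries a `track N` name meta-event so parsing recovers
the original track indices. The parser accepts foreign format-0/1 files
(running status included) and pairs each note-on with the next matching
note-off, first-in-first-out per (track, channel, pitch); unpaired events
are an error.

## Synthetic sessions

The generator produces data with the statistical structure of the two
demonstrated use cases, not biophysical realism:

- **Breathing** is a semi-Markov point process over named states
  (defaults: slow 2–4 Hz, intermediate "grooming" 5–8 Hz, fast 9–13 Hz;
  mean dwell 20 s each, exponential, next state uniform among the
  others — matching rhythms that persist for seconds to minutes).
  Within a state, inter-inhalation intervals are uniform over the band's
  reciprocal, so every instantaneous rate lies inside the band *by
  construction*; an interval that would cross a state switch is redrawn
  from the new state's band. This makes the state-recovery check exact
  rather than statistical: disjoint rate bands under a covering log-rate
  map yield disjoint pitch bands, and classifying drum pitches recovers
  every ground-truth label (from the second inhalation on).
- **Background spiking** is independent homogeneous Poisson per unit
  (default 52 units, rates log-uniform ~0.5–10 Hz), the minimal model for
  testing one-pitch-per-neuron bookkeeping at a realistic population size.
- **Trigger-locked sequences** fire unit *k* once per trigger at
  `base + k·step` plus Gaussian jitter (defaults 20 ms base, 10 ms step,
  1 ms jitter — jitter ≪ step so the coarse-to-fine order is recoverable
  from per-unit median latencies). Gaze shifts (~0.5 Hz) and blinks
  (~0.1 Hz) share the same response model.

Sessions default to 120 s — long enough for several state dwells and
tens of triggers while keeping the whole suite inside seconds of CPU.
Everything derives from one integer seed (sub-seeds drawn below 2³¹);
fixture directories are byte-identical across runs and are written in
exactly the formats the readers consume (NPY spike arrays, `params.py`,
`cluster_group.tsv`, event CSVs) plus a `ground_truth.json` sidecar. What
passing tests on these fixtures do **not** show: robustness to real-world
artifacts such as mis-sorted units, bursting, missing curation labels
beyond the Phy vocabulary, or drift in breathing bands; the generators
contain none of these.

## Degenerate inputs and numerical choices

- Event streams may be empty (empty note table, valid conductor-only SMF)
  or contain a single event at t = 0; instantaneous rate requires ≥ 2
  strictly increasing times and refuses duplicates.
- Ties in event time are kept in input order (stable sorts throughout).
- All roundings are explicit: grid and tick quantization ties away from
  zero; scale snapping ties toward the lower pitch.
- Validation errors are typed (`errors.py`) and raised at construction,
  so no invalid table reaches the serializer.

## Limitations

- Constant velocity and constant note length only; no chord/harmony
  logic; no audio synthesis or video handling.
- One tempo per file; tempo changes in foreign files are read only as the
  first tempo event.
- The parser ignores non-note channel messages (pitch bend, CC) rather
  than preserving them.
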