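"""Event and spike-table input: the pipeline's front door.

Two input routes feed the converter:

* generic two-column event files (identity, time in seconds), and
* spike-sorting output directories in the Kilosort/Phy convention
  (``spike_times.npy`` in sample indices, ``spike_clusters.npy``,
  a ``params.py`` declaring ``sample_rate``, and an optional
  ``cluster_group.tsv`` of curation labels).

Both converge on :class:`EventStream`, the universal intermediate
representation: labeled events sorted by time.
"""

from __future__ import annotations

import ast
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from neuromidi.errors import (
    EmptyFileError,
    EventFileError,
    LengthMismatchError,
    MissingFileError,
    NegativeTimeError,
    NonNumericTimeError,
    SamplingRateError,
    SpikeSortingFormatError,
)

__all__ = [
    "EventStream",
    "SpikeTable",
    "read_event_file",
    "write_event_file",
    "read_spike_sorting_output",
    "spikes_to_event_stream",
]


@dataclass(frozen=True)
class EventStream:
    """Labeled, time-sorted discrete events.

    Parameters
    ----------
    labels
        One identity per event.  Identities are opaque: strings or integers
        are both fine; they are only ever compared for equality.
    times
        Event times in seconds, non-negative and finite, sorted
        non-decreasing.  Ties keep input order (stable sort).
    """

    labels: tuple
    times: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        labels = tuple(self.labels)
        if len(labels) != times.size:
            raise EventFileError(
                f"labels ({len(labels)}) and times ({times.size}) differ in length"
            )
        if times.size and not np.all(np.isfinite(times)):
            raise NonNumericTimeError("event times must be finite")
        if times.size and times.min() < 0:
            raise NegativeTimeError("event times must be >= 0 seconds")
        if times.size and np.any(np.diff(times) < 0):
            order = np.argsort(times, kind="stable")
            times = times[order]
            labels = tuple(labels[i] for i in order)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return self.times.size

    @property
    def unique_labels(self) -> tuple:
        """Distinct identities in first-appearance order."""
        seen: dict = {}
        for lab in self.labels:
            seen.setdefault(lab, None)
        return tuple(seen)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EventStream):
            return NotImplemented
        return self.labels == other.labels and np.array_equal(self.times, other.times)


@dataclass(frozen=True)
class SpikeTable:
    """Per-spike unit assignments and times from spike sorting.

    ``times_s`` are seconds (sample index divided by ``sampling_rate_hz``),
    sorted non-decreasing; ``unit_ids`` is the matching cluster id per spike.
    ``curation_labels`` maps unit id to its Phy group string ("good", "mua",
    "noise") when a curation table was present.
    """

    unit_ids: np.ndarray
    times_s: np.ndarray
    sampling_rate_hz: float
    curation_labels: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unit_ids = np.asarray(self.unit_ids, dtype=np.int64)
        times = np.asarray(self.times_s, dtype=float)
        if unit_ids.size != times.size:
            raise LengthMismatchError(
                f"unit_ids ({unit_ids.size}) and times_s ({times.size}) differ in length"
            )
        if not self.sampling_rate_hz > 0:
            raise SamplingRateError(
                f"sampling_rate_hz must be > 0, got {self.sampling_rate_hz}"
            )
        if times.size and np.any(np.diff(times) < 0):
            order = np.argsort(times, kind="stable")
            times = times[order]
            unit_ids = unit_ids[order]
        object.__setattr__(self, "unit_ids", unit_ids)
        object.__setattr__(self, "times_s", times)
        object.__setattr__(self, "curation_labels", dict(self.curation_labels))

    def __len__(self) -> int:
        return self.times_s.size

    @property
    def units(self) -> np.ndarray:
        """Sorted array of distinct unit ids present."""
        return np.unique(self.unit_ids)


def _sniff_delimiter(first_line: str) -> str:
    return "\t" if "\t" in first_line else ","


def read_event_file(path: str | Path) -> EventStream:
    """Read a two-column event file into an :class:`EventStream`.

    The file is delimiter-separated text (comma or tab, auto-detected).
    Column one holds event identities (kept verbatim as strings, except
    pure integers which become ints), column two holds event times in
    seconds.  An optional header row ``event_id,time_s`` is skipped.

    Raises
    ------
    MissingFileError, EmptyFileError, NonNumericTimeError, NegativeTimeError
    """
    path = Path(path)
    if not path.is_file():
        raise MissingFileError(f"event file not found: {path}")
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise EmptyFileError(f"event file is empty: {path}")
    delim = _sniff_delimiter(lines[0])
    start = 0
    first_fields = [f.strip() for f in lines[0].split(delim)]
    if len(first_fields) >= 2 and first_fields[0].lower() in ("event_id", "label", "id"):
        start = 1
    if start == len(lines):
        raise EmptyFileError(f"event file has a header but no data rows: {path}")
    labels: list = []
    times: list[float] = []
    for lineno, line in enumerate(lines[start:], start + 1):
        fields = [f.strip() for f in line.split(delim)]
        if len(fields) < 2:
            raise EventFileError(f"{path}:{lineno}: expected two columns, got {len(fields)}")
        ident: object = fields[0]
        if re.fullmatch(r"[+-]?\d+", fields[0]):
            ident = int(fields[0])
        try:
            t = float(fields[1])
        except ValueError as exc:
            raise NonNumericTimeError(
                f"{path}:{lineno}: non-numeric time {fields[1]!r}"
            ) from exc
        if not np.isfinite(t):
            raise NonNumericTimeError(f"{path}:{lineno}: non-finite time {t!r}")
        if t < 0:
            raise NegativeTimeError(f"{path}:{lineno}: negative time {t}")
        labels.append(ident)
        times.append(t)
    return EventStream(labels=tuple(labels), times=np.array(times, dtype=float))


def write_event_file(stream: EventStream, path: str | Path) -> None:
    """Write an :class:`EventStream` as a CSV with header ``event_id,time_s``.

    Times are written with ``repr`` precision so that read-back round-trips
    exactly.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("event_id,time_s\n")
        for lab, t in zip(stream.labels, stream.times):
            fh.write(f"{lab},{float(t)!r}\n")


def _read_params_sample_rate(params_path: Path) -> float:
    """Extract ``sample_rate`` from a Phy-style ``params.py``.

    The file is plain Python assignments; we evaluate only literal
    right-hand sides rather than executing it.
    """
    for line in params_path.read_text().splitlines():
        m = re.match(r"\s*sample_rate\s*[=:]\s*(.+?)\s*(#.*)?$", line)
        if m:
            try:
                value = ast.literal_eval(m.group(1))
            except (ValueError, SyntaxError) as exc:
                raise SamplingRateError(
                    f"cannot parse sample_rate in {params_path}: {m.group(1)!r}"
                ) from exc
            return float(value)
    raise SamplingRateError(f"no sample_rate declaration in {params_path}")


def read_spike_sorting_output(
    directory: str | Path,
    keep_labels: Iterable[str] | None = None,
    sampling_rate_hz: float | None = None,
) -> SpikeTable:
    """Load a Kilosort/Phy-convention spike-sorting directory.

    Expects ``spike_times.npy`` (sample indices), ``spike_clusters.npy``
    (cluster id per spike, same length), ``params.py`` declaring
    ``sample_rate``, and optionally ``cluster_group.tsv`` with columns
    ``cluster_id`` and ``group`` (Phy curation labels).

    Parameters
    ----------
    keep_labels
        Curation labels to retain.  If a curation table exists and this is
        ``None``, only units labeled ``"good"`` are kept (the standard Phy
        workflow); if no curation table exists all units are kept.  Pass an
        explicit set to override.
    sampling_rate_hz
        Overrides the rate declared in ``params.py`` when given.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise MissingFileError(f"spike-sorting directory not found: {directory}")
    times_path = directory / "spike_times.npy"
    clusters_path = directory / "spike_clusters.npy"
    for p in (times_path, clusters_path):
        if not p.is_file():
            raise MissingFileError(f"required spike-sorting file missing: {p}")

    if sampling_rate_hz is None:
        params_path = directory / "params.py"
        if not params_path.is_file():
            raise SamplingRateError(
                f"no params.py in {directory} and no sampling rate override given"
            )
        sampling_rate_hz = _read_params_sample_rate(params_path)
    if not sampling_rate_hz > 0:
        raise SamplingRateError(f"sampling rate must be > 0, got {sampling_rate_hz}")

    samples = np.load(times_path).ravel()
    clusters = np.load(clusters_path).ravel().astype(np.int64)
    if samples.size != clusters.size:
        raise LengthMismatchError(
            f"spike_times has {samples.size} entries but spike_clusters has {clusters.size}"
        )
    if samples.size and samples.min() < 0:
        raise SpikeSortingFormatError("negative spike sample index")

    curation: dict[int, str] = {}
    group_path = directory / "cluster_group.tsv"
    if group_path.is_file():
        table = pd.read_csv(group_path, sep="\t")
        if not {"cluster_id", "group"}.issubset(table.columns):
            raise SpikeSortingFormatError(
                f"{group_path} must have columns cluster_id and group"
            )
        curation = dict(zip(table["cluster_id"].astype(int), table["group"].astype(str)))
        if keep_labels is None:
            keep_labels = {"good"}

    times_s = samples.astype(float) / float(sampling_rate_hz)
    if keep_labels is not None and curation:
        keep = frozenset(keep_labels)
        kept_units = {u for u, lab in curation.items() if lab in keep}
        mask = np.isin(clusters, sorted(kept_units))
        samples, clusters, times_s = samples[mask], clusters[mask], times_s[mask]
        curation = {u: lab for u, lab in curation.items() if u in kept_units}

    return SpikeTable(
        unit_ids=clusters,
        times_s=times_s,
        sampling_rate_hz=float(sampling_rate_hz),
        curation_labels=curation,
    )


def spikes_to_event_stream(spikes: SpikeTable) -> EventStream:
    """View a :class:`SpikeTable` as an :class:`EventStream`.

    Event identity is the unit id; order is preserved (both are
    time-sorted).
    """
    return EventStream(
        labels=tuple(int(u) for u in spikes.unit_ids),
        times=spikes.times_s.copy(),
    )
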