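"""Network-level activity summaries, raster diagrams, and synchrony calls.

The three headline parameters are the percentage of working cells (cells
with at least one detected oscillation), the oscillation frequency
(average oscillations per minute), and the mean oscillation duration.

The synchronous-event caller (``find_sync_events``) is an in-house
operationalization — a fixed time binning with a participation threshold —
and is labelled as such in its output; it is not part of the reference
detection procedure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .event_detection import CalciumEvent

__all__ = [
    "ActivitySummary",
    "Raster",
    "SyncEvent",
    "summarize",
    "build_raster",
    "find_sync_events",
    "events_by_cell_from_table",
    "plot_raster",
]

EventLike = CalciumEvent | tuple[float, float]


def _interval(event: EventLike) -> tuple[float, float]:
    if isinstance(event, CalciumEvent):
        return event.onset_time, event.offset_time
    onset, offset = event
    return float(onset), float(offset)


@dataclass(frozen=True)
class ActivitySummary:
    """Per-culture activity parameters.

    ``freq_osc_per_min`` and ``mean_duration`` are NaN (flagged by
    ``activity_defined`` = False) when no cell shows any oscillation.
    """

    n_cells: int
    n_working: int
    pct_working: float
    freq_osc_per_min: float
    mean_duration: float

    def __post_init__(self) -> None:
        if not 0 <= self.pct_working <= 100:
            raise ValueError("pct_working must lie in [0, 100]")

    @property
    def activity_defined(self) -> bool:
        return self.n_working > 0


@dataclass(frozen=True)
class Raster:
    """Per-cell oscillation onset times over a recording window."""

    onsets: Mapping[int, np.ndarray]
    recording_length: float

    def __post_init__(self) -> None:
        for cell, times in self.onsets.items():
            times = np.asarray(times, dtype=float)
            if times.size and (times.min() < 0 or times.max() > self.recording_length):
                raise ValueError(f"onsets of cell {cell} fall outside the recording")

    @property
    def working_cells(self) -> tuple[int, ...]:
        return tuple(c for c in sorted(self.onsets) if len(self.onsets[c]) > 0)


@dataclass(frozen=True)
class SyncEvent:
    """A window where a supra-threshold fraction of working cells fired."""

    start: float
    end: float
    cells: tuple[int, ...]
    participation: float


def summarize(
    events_by_cell: Mapping[int, Sequence[EventLike]],
    n_cells: int,
    recording_length: float,
    frequency_over: str = "working",
) -> ActivitySummary:
    """Aggregate per-cell event lists into the three activity parameters.

    ``pct_working`` counts cells with >= 1 event out of ``n_cells``;
    frequency is the mean of per-cell counts per minute over working cells
    (``frequency_over="all"`` averages over every cell instead);
    ``mean_duration`` averages over all events.  When no cell is active
    the frequency and duration are NaN, flagged via ``activity_defined``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if not recording_length > 0:
        raise ValueError("recording_length must be > 0")
    if frequency_over not in ("working", "all"):
        raise ValueError("frequency_over must be 'working' or 'all'")
    minutes = recording_length / 60.0
    counts = {c: len(evs) for c, evs in events_by_cell.items() if len(evs) > 0}
    n_working = len(counts)
    if n_working > n_cells:
        raise ValueError("more working cells than n_cells")
    pct = 100.0 * n_working / n_cells
    if n_working == 0:
        return ActivitySummary(n_cells, 0, pct, float("nan"), float("nan"))
    if frequency_over == "working":
        freq = float(np.mean([k / minutes for k in counts.values()]))
    else:
        freq = float(sum(counts.values()) / n_cells / minutes)
    durations = [
        b - a
        for evs in events_by_cell.values()
        for a, b in map(_interval, evs)
    ]
    return ActivitySummary(n_cells, n_working, pct, freq, float(np.mean(durations)))


def build_raster(
    events_by_cell: Mapping[int, Sequence[EventLike]],
    recording_length: float,
) -> Raster:
    """Strokes at oscillation onset times, one row per cell (sorted by id)."""
    onsets = {
        cell: np.asarray(sorted(_interval(e)[0] for e in evs), dtype=float)
        for cell, evs in sorted(events_by_cell.items())
    }
    return Raster(onsets, recording_length)


def find_sync_events(
    raster: Raster,
    bin_width: float = 1.0,
    participation_threshold: float = 0.3,
) -> list[SyncEvent]:
    """Call network-synchronous windows on a raster (non-reference rule).

    The time axis is cut into consecutive bins of ``bin_width``; a bin
    qualifies when the fraction of *working* cells with >= 1 onset inside
    it reaches ``participation_threshold``; adjacent qualifying bins merge
    into one event.  Participation of a merged event is the fraction of
    working cells firing anywhere inside its window.
    """
    if not bin_width > 0:
        raise ValueError("bin_width must be > 0")
    if not 0 < participation_threshold <= 1:
        raise ValueError("participation_threshold must lie in (0, 1]")
    working = raster.working_cells
    if not working:
        return []
    n_bins = max(1, math.ceil(raster.recording_length / bin_width))
    hits = np.zeros((len(working), n_bins), dtype=bool)
    for row, cell in enumerate(working):
        bins = np.minimum(
            (np.asarray(raster.onsets[cell]) / bin_width).astype(int), n_bins - 1
        )
        hits[row, bins] = True
    fraction = hits.mean(axis=0)
    qualifying = fraction >= participation_threshold

    events = []
    b = 0
    while b < n_bins:
        if not qualifying[b]:
            b += 1
            continue
        start_bin = b
        while b < n_bins and qualifying[b]:
            b += 1
        start = start_bin * bin_width
        end = min(b * bin_width, raster.recording_length)
        in_window = hits[:, start_bin:b].any(axis=1)
        cells = tuple(c for c, flag in zip(working, in_window) if flag)
        events.append(SyncEvent(start, end, cells, len(cells) / len(working)))
    return events


def events_by_cell_from_table(events_df) -> dict[int, list[tuple[float, float]]]:
    """Regroup an events table (cell_id, onset_s, offset_s) per cell."""
    out: dict[int, list[tuple[float, float]]] = {}
    for row in events_df.itertuples(index=False):
        out.setdefault(int(row.cell_id), []).append(
            (float(row.onset_s), float(row.offset_s))
        )
    return out


def plot_raster(raster: Raster, path=None, ax=None):
    """Render the raster as strokes (optional; needs matplotlib)."""
    import matplotlib

    if path is not None and ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    for row, cell in enumerate(sorted(raster.onsets)):
        times = raster.onsets[cell]
        ax.vlines(times, row + 0.6, row + 1.4, colors="k", linewidths=0.8)
    ax.set_xlim(0, raster.recording_length)
    ax.set_ylim(0.5, len(raster.onsets) + 0.5)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("cell")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
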