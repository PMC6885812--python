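"""Synthetic fluorescence recordings, respirometry tables, and Ct tables.

Ground-truth generators for every downstream stage: per-cell calcium
traces (optionally rendered into image stacks over an ROI layout) with
known event times, Gaussian respirometry replicate tables, and qPCR Ct
tables encoding known fold changes.

Reproducibility contract: one global ``seed`` drives a hierarchy of
per-cell substreams (``SeedSequence(seed, spawn_key=(1, cell))``), so
identical configs give bitwise-identical output and adding a cell never
perturbs the other cells' traces.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .imaging_io import FluorescenceTrace, RoiMap

__all__ = [
    "SimConfig",
    "GroundTruth",
    "transient_kernel",
    "transient_visible_duration",
    "simulate_traces",
    "simulate_stack",
    "simulate_respirometry",
    "simulate_ct_table",
]

# a transient is considered "over" once it decays to this fraction of peak
_VISIBLE_LEVEL = 0.1


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic calcium recording.

    Intensities are in relative units on the 0-255 acquisition scale;
    rates are per minute; times in seconds.  ``sync_fraction`` is the
    expected fraction of cells recruited by each network-wide event and
    ``sync_jitter`` the SD of per-cell onset jitter around it.
    """

    n_cells: int = 50
    duration: float = 300.0
    frame_rate: float = 4.0
    baseline: float = 50.0
    amplitude: float = 100.0
    rise_tau: float = 0.5
    decay_tau: float = 3.0
    event_rate: float = 2.0
    sync_fraction: float = 0.0
    sync_jitter: float = 0.1
    network_event_rate: float = 0.0
    noise_sd: float = 0.0
    quantize: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        numeric = {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if f.name not in ("quantize", "seed", "n_cells")
        }
        for name, value in numeric.items():
            if not math.isfinite(float(value)):
                raise ValueError(f"{name} must be finite")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not self.duration > 0:
            raise ValueError("duration must be > 0")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be > 0")
        if not 0 <= self.sync_fraction <= 1:
            raise ValueError("sync_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not 0 < self.rise_tau < self.decay_tau:
            raise ValueError("need 0 < rise_tau < decay_tau")
        if self.event_rate < 0 or self.network_event_rate < 0:
            raise ValueError("event rates must be >= 0")
        if self.sync_jitter < 0:
            raise ValueError("sync_jitter must be >= 0")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass(frozen=True)
class GroundTruth:
    """True event intervals per cell plus network-event participant lists.

    ``events[c]`` is the merged, sorted list of ``(onset_s, offset_s)``
    intervals for cell ``c``; ``onsets[c]`` keeps every raw transient onset
    (before overlap merging); ``network_events`` holds
    ``(time_s, participants)`` pairs.
    """

    events: tuple[tuple[tuple[float, float], ...], ...]
    network_events: tuple[tuple[float, tuple[int, ...]], ...] = field(default=())
    duration: float = 0.0
    onsets: tuple[tuple[float, ...], ...] = field(default=())

    def __post_init__(self) -> None:
        for cell_events in self.events:
            for onset, offset in cell_events:
                if not offset > onset:
                    raise ValueError("event offsets must exceed onsets")
                if onset < 0 or offset > self.duration + 1e-9:
                    raise ValueError("event times must lie within the recording")

    def event_count(self, cell: int) -> int:
        return len(self.events[cell])

    @property
    def total_events(self) -> int:
        return sum(len(e) for e in self.events)

    def to_json(self, path) -> None:
        payload = {
            "duration": self.duration,
            "events": [
                [{"onset_s": a, "offset_s": b} for a, b in cell]
                for cell in self.events
            ],
            "onsets": [list(cell) for cell in self.onsets],
            "network_events": [
                {"time_s": t, "participants": list(p)}
                for t, p in self.network_events
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            events=tuple(
                tuple((e["onset_s"], e["offset_s"]) for e in cell)
                for cell in payload["events"]
            ),
            network_events=tuple(
                (ne["time_s"], tuple(ne["participants"]))
                for ne in payload["network_events"]
            ),
            duration=payload["duration"],
            onsets=tuple(tuple(cell) for cell in payload.get("onsets", [])),
        )


def transient_kernel(
    t: np.ndarray, rise_tau: float, decay_tau: float
) -> np.ndarray:
    """Difference-of-exponentials transient, normalized to unit peak.

    ``K(t) = (exp(-t/decay_tau) - exp(-t/rise_tau)) / peak`` for t >= 0,
    0 before onset.
    """
    t = np.asarray(t, dtype=float)
    t_peak = (
        rise_tau * decay_tau / (decay_tau - rise_tau) * math.log(decay_tau / rise_tau)
    )
    peak = math.exp(-t_peak / decay_tau) - math.exp(-t_peak / rise_tau)
    raw = np.exp(-np.maximum(t, 0.0) / decay_tau) - np.exp(
        -np.maximum(t, 0.0) / rise_tau
    )
    return np.where(t >= 0, raw / peak, 0.0)


def transient_visible_duration(
    rise_tau: float, decay_tau: float, level: float = _VISIBLE_LEVEL
) -> float:
    """Time from onset until the unit-peak kernel decays to ``level``.

    Used as the ground-truth event duration (defaults give ~8.7 s,
    matching ~10 s apparent transients at the default kinetics).
    """
    t_peak = (
        rise_tau * decay_tau / (decay_tau - rise_tau) * math.log(decay_tau / rise_tau)
    )

    def f(t: float) -> float:
        return float(transient_kernel(np.array([t]), rise_tau, decay_tau)[0]) - level

    upper = t_peak + decay_tau * math.log(1.0 / level) + 10 * decay_tau
    return brentq(f, t_peak, upper)


def _cell_rng(seed: int, cell: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1, cell)))


def _stream_rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream, 0)))


def _merge_intervals(
    intervals: Sequence[tuple[float, float]],
) -> tuple[tuple[float, float], ...]:
    if not intervals:
        return ()
    merged = []
    for onset, offset in sorted(intervals):
        if merged and onset <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], offset))
        else:
            merged.append((onset, offset))
    return tuple(merged)


def simulate_traces(
    config: SimConfig,
) -> tuple[list[FluorescenceTrace], GroundTruth]:
    """Simulate per-cell traces plus the ground truth behind them.

    Each cell fires independent transients as a Poisson process at
    ``event_rate``; network events occur at ``network_event_rate`` and
    recruit each cell independently with probability ``sync_fraction``,
    jittered by ``N(0, sync_jitter)``.  Overlapping transients sum
    linearly; Gaussian noise of ``noise_sd`` is added; with ``quantize``
    values are rounded and clipped to the integer 0-255 range.
    """
    n_frames = config.n_frames
    if n_frames < 2:
        raise ValueError("duration x frame_rate must give at least 2 frames")
    times = np.arange(n_frames) / config.frame_rate
    visible = transient_visible_duration(config.rise_tau, config.decay_tau)

    net_rng = _stream_rng(config.seed, 2)
    n_net = net_rng.poisson(config.network_event_rate * config.duration / 60.0)
    net_times = np.sort(net_rng.uniform(0.0, config.duration, size=n_net))

    traces = []
    per_cell_events = []
    per_cell_onsets = []
    participants: list[list[int]] = [[] for _ in range(n_net)]
    for cell in range(config.n_cells):
        rng = _cell_rng(config.seed, cell)
        n_own = rng.poisson(config.event_rate * config.duration / 60.0)
        onsets = list(rng.uniform(0.0, config.duration, size=n_own))
        # network recruitment: per-cell draws keep cells independent
        joins = rng.random(n_net) < config.sync_fraction
        jitters = rng.normal(0.0, config.sync_jitter, size=n_net)
        for k in range(n_net):
            if joins[k]:
                onset = float(net_times[k] + jitters[k])
                if 0.0 <= onset < config.duration:
                    onsets.append(onset)
                    participants[k].append(cell)
        signal = np.full(n_frames, config.baseline, dtype=float)
        for onset in onsets:
            signal += config.amplitude * transient_kernel(
                times - onset, config.rise_tau, config.decay_tau
            )
        if config.noise_sd > 0:
            signal += rng.normal(0.0, config.noise_sd, size=n_frames)
        if config.quantize:
            signal = np.clip(np.rint(signal), 0, 255)
        traces.append(FluorescenceTrace(cell, signal, config.frame_rate))
        per_cell_events.append(
            _merge_intervals(
                [(o, min(o + visible, config.duration)) for o in sorted(onsets)]
            )
        )
        per_cell_onsets.append(tuple(sorted(onsets)))
    truth = GroundTruth(
        events=tuple(per_cell_events),
        network_events=tuple(
            (float(t), tuple(p)) for t, p in zip(net_times, participants)
        ),
        duration=config.duration,
        onsets=tuple(per_cell_onsets),
    )
    return traces, truth


def simulate_stack(
    config: SimConfig, roi_layout: RoiMap
) -> tuple[np.ndarray, list[FluorescenceTrace], GroundTruth]:
    """Render simulated traces into an image stack over an ROI layout.

    Pixels of ROI ``r`` carry the r-th cell's noise-free trace value plus
    independent pixel noise of ``config.noise_sd``; background pixels carry
    ``baseline`` plus the same noise.  Returns the stack together with the
    underlying noise-free traces and ground truth.  ROI labels map to cells
    in sorted-label order.
    """
    labels = roi_layout.labels
    clean = dataclasses.replace(
        config,
        n_cells=max(len(labels), 1),
        noise_sd=0.0,
        quantize=False,
    )
    traces, truth = simulate_traces(clean)
    if not labels:  # degenerate layout: pure background
        traces = []
        truth = GroundTruth(events=(), duration=config.duration)
    n_frames = config.n_frames
    stack = np.full(
        (n_frames, *roi_layout.shape), config.baseline, dtype=float
    )
    for cell, label in enumerate(sorted(labels)):
        mask = roi_layout.mask(label)
        stack[:, mask] = traces[cell].values[:, None]
    if config.noise_sd > 0:
        rng = _stream_rng(config.seed, 3)
        stack += rng.normal(0.0, config.noise_sd, size=stack.shape)
    if config.quantize:
        stack = np.clip(np.rint(stack), 0, 255).astype(np.uint8)
    return stack, traces, truth


def simulate_respirometry(
    group_means: Mapping[str, Mapping[str, float] | Sequence[float]],
    sd: float | Mapping[str, float] = 0.0,
    n: int = 3,
    seed: int = 0,
):
    """Gaussian respirometry replicates (columns group, replicate, V4_gm,
    V3, V4_succ), truncated at 0 by redrawing.

    ``group_means`` maps group label to the three state means, either as a
    mapping with keys V4_gm/V3/V4_succ or as a 3-sequence in that order.
    ``sd`` is one value or a per-state mapping.
    """
    import pandas as pd

    states = ("V4_gm", "V3", "V4_succ")
    if n < 1:
        raise ValueError("n must be >= 1")
    if not isinstance(sd, Mapping):
        sd = {s: float(sd) for s in states}
    if any(sd[s] < 0 for s in states):
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(4, 0)))
    rows = []
    for group, means in group_means.items():
        if not isinstance(means, Mapping):
            means = dict(zip(states, means))
        for s in states:
            if not means[s] > 0:
                raise ValueError(f"mean {s} for group {group!r} must be > 0")
        for rep in range(1, n + 1):
            row = {"group": group, "replicate": rep}
            for s in states:
                value = rng.normal(means[s], sd[s])
                while value <= 0:  # truncate at 0 by redrawing
                    value = rng.normal(means[s], sd[s])
                row[s] = value
            rows.append(row)
    return pd.DataFrame(rows)


def simulate_ct_table(
    true_fold_changes: Mapping[str, Mapping[str, float]],
    base_ct: float = 25.0,
    noise_sd: float = 0.0,
    n: int = 3,
    seed: int = 0,
    reference_gene: str = "Oaz1",
):
    """qPCR Ct table (columns sample, group, gene, Ct) encoding known folds.

    Target Ct is ``base_ct - log2(fold) + noise``, reference Ct is
    ``base_ct + noise`` (noise iid Gaussian of ``noise_sd``), so the
    ddCt pipeline recovers ``true_fold_changes`` up to noise when the
    calibrator group is simulated at fold 1.
    """
    import pandas as pd

    if n < 1:
        raise ValueError("n must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    for group, folds in true_fold_changes.items():
        for gene, fold in folds.items():
            if not fold > 0:
                raise ValueError(
                    f"fold for group {group!r}, gene {gene!r} must be > 0"
                )
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(5, 0)))
    rows = []
    for group, folds in true_fold_changes.items():
        for rep in range(1, n + 1):
            sample = f"{group}_{rep}"
            rows.append(
                {
                    "sample": sample,
                    "group": group,
                    "gene": reference_gene,
                    "Ct": base_ct + rng.normal(0.0, noise_sd),
                }
            )
            for gene, fold in folds.items():
                rows.append(
                    {
                        "sample": sample,
                        "group": group,
                        "gene": gene,
                        "Ct": base_ct - math.log2(fold) + rng.normal(0.0, noise_sd),
                    }
                )
    return pd.DataFrame(rows)
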