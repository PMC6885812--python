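"""Derivative-threshold detection of calcium oscillations on single traces.

The detector works in three stages on a raw trace ``F`` of length ``N``:

1. smoothing by averaging neighbouring points: ``S[i] = (F[i] + F[i+1]) / 2``
   (length ``N - 1``);
2. a simple derivative ``D[i] = S[i+1] - S[i]`` (length ``N - 2``);
3. a threshold ``theta = k * SD(D)`` with the accuracy coefficient
   ``k = 0.45`` by default; suprathreshold excursions of the derivative mark
   the beginnings (``D > +theta``, fluorescence rising) and endings
   (``D < -theta``, fluorescence falling) of oscillations.

An event opens at the first sample of a maximal positive run and closes at
the last sample of the first subsequent maximal negative run; positive runs
encountered while an event is open extend it.  An event still open at the
end of the trace closes at the final frame.  A flat trace (``theta == 0``)
yields no events.  Derivative index ``i`` maps to raw frame ``i + 1`` (the
centre of the two-point smoothing / differencing stencil); times are
``frame / frame_rate`` with frame 0 at t = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .imaging_io import FluorescenceTrace

__all__ = [
    "DetectionParams",
    "CalciumEvent",
    "smooth",
    "derivative",
    "threshold",
    "detect_events",
    "detect_events_table",
]


@dataclass(frozen=True)
class DetectionParams:
    """Tuning knobs of the derivative-threshold detector.

    Attributes
    ----------
    smoothing_window : int
        Number of neighbouring points averaged; 2 reproduces the reference
        pairwise filter.
    accuracy_coefficient : float
        ``k`` multiplying the derivative SD to form the threshold
        (default 0.45).
    min_event_samples : int
        Events spanning fewer raw frames are discarded (default 1, i.e.
        keep everything).
    sd_mode : str
        ``"population"`` (divide by N, default) or ``"sample"`` (N - 1).
    """

    smoothing_window: int = 2
    accuracy_coefficient: float = 0.45
    min_event_samples: int = 1
    sd_mode: str = "population"

    def __post_init__(self) -> None:
        if self.smoothing_window < 1:
            raise ValueError("smoothing_window must be >= 1")
        if not self.accuracy_coefficient > 0:
            raise ValueError("accuracy_coefficient must be > 0")
        if self.min_event_samples < 1:
            raise ValueError("min_event_samples must be >= 1")
        if self.sd_mode not in ("population", "sample"):
            raise ValueError("sd_mode must be 'population' or 'sample'")

    @property
    def sd_ddof(self) -> int:
        return 0 if self.sd_mode == "population" else 1


@dataclass(frozen=True)
class CalciumEvent:
    """One detected oscillation: onset/offset frames, times, and duration."""

    cell_id: int
    onset_index: int
    offset_index: int
    onset_time: float
    offset_time: float
    duration: float

    def __post_init__(self) -> None:
        if not self.offset_time > self.onset_time:
            raise ValueError("offset_time must exceed onset_time")
        if not np.isclose(self.duration, self.offset_time - self.onset_time):
            raise ValueError("duration must equal offset_time - onset_time")


def smooth(values: np.ndarray | Sequence[float], window: int = 2) -> np.ndarray:
    """Moving average of ``window`` neighbouring points, length N - window + 1.

    With the default window of 2 this is ``S[i] = (F[i] + F[i+1]) / 2``.
    """
    values = np.asarray(values, dtype=float)
    if values.size < max(window, 2):
        raise ValueError("need at least 2 samples (and >= window) to smooth")
    if window == 1:
        return values.copy()
    kernel = np.full(window, 1.0 / window)
    return np.convolve(values, kernel, mode="valid")


def derivative(smoothed: np.ndarray | Sequence[float]) -> np.ndarray:
    """Difference of subsequent points, ``D[i] = S[i+1] - S[i]``."""
    smoothed = np.asarray(smoothed, dtype=float)
    if smoothed.size < 2:
        raise ValueError("need at least 2 samples to differentiate")
    return np.diff(smoothed)


def threshold(deriv: np.ndarray, params: DetectionParams | None = None) -> float:
    """Detection threshold ``theta = k * SD(D)`` over the whole derivative.

    The SD includes event epochs (no exclusion); a constant derivative
    gives ``theta == 0``, which the caller treats as "no events".
    """
    params = params or DetectionParams()
    deriv = np.asarray(deriv, dtype=float)
    if deriv.size == 0:
        raise ValueError("derivative series is empty")
    return params.accuracy_coefficient * float(deriv.std(ddof=params.sd_ddof))


def detect_events(
    trace: FluorescenceTrace, params: DetectionParams | None = None
) -> list[CalciumEvent]:
    """Detect oscillations on one trace; see the module docstring for rules.

    Returns events sorted by onset, non-overlapping, each with
    ``offset_time > onset_time``.

    Raises
    ------
    ValueError
        If the trace is too short for a non-empty derivative.
    """
    params = params or DetectionParams()
    values = trace.values
    n = values.size
    if n < params.smoothing_window + 2:
        raise ValueError(
            f"trace of {n} samples is too short for window "
            f"{params.smoothing_window}"
        )
    deriv = derivative(smooth(values, params.smoothing_window))
    theta = threshold(deriv, params)
    if theta == 0.0:
        return []

    # D[i] sits at the centre of its stencil over the raw trace
    shift = params.smoothing_window // 2
    events: list[tuple[int, int]] = []
    open_start: int | None = None
    in_negative_run = False
    for i, d in enumerate(deriv):
        if open_start is None:
            if d > theta:
                open_start = i
        elif not in_negative_run:
            if d < -theta:
                in_negative_run = True
        elif d >= -theta:  # negative run ended on the previous sample
            events.append((open_start + shift, (i - 1) + shift))
            in_negative_run = False
            # the closing sample may itself start the next oscillation
            open_start = i if d > theta else None
    if open_start is not None:
        if in_negative_run:  # negative run ran to the end of D
            events.append((open_start + shift, (len(deriv) - 1) + shift))
        else:  # open event with no ending excursion: close at trace end
            events.append((open_start + shift, n - 1))

    out = []
    for onset, offset in events:
        if offset - onset + 1 < params.min_event_samples:
            continue
        t_on = onset / trace.frame_rate
        t_off = offset / trace.frame_rate
        out.append(
            CalciumEvent(trace.cell_id, onset, offset, t_on, t_off, t_off - t_on)
        )
    return out


def detect_events_table(
    traces: Sequence[FluorescenceTrace], params: DetectionParams | None = None
):
    """Run the detector over many traces and tabulate all events.

    Returns a DataFrame with columns cell_id, onset_frame, offset_frame,
    onset_s, offset_s, duration_s (empty but typed when nothing is found).
    """
    import pandas as pd

    rows = []
    for tr in traces:
        for ev in detect_events(tr, params):
            rows.append(
                {
                    "cell_id": ev.cell_id,
                    "onset_frame": ev.onset_index,
                    "offset_frame": ev.offset_index,
                    "onset_s": ev.onset_time,
                    "offset_s": ev.offset_time,
                    "duration_s": ev.duration,
                }
            )
    columns = [
        "cell_id",
        "onset_frame",
        "offset_frame",
        "onset_s",
        "offset_s",
        "duration_s",
    ]
    return pd.DataFrame(rows, columns=columns)
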