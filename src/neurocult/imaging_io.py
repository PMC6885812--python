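"""Image-stack I/O, ROI trace extraction, and two-channel viability counting.

Fluorescence stacks are ``(n_frames, height, width)`` arrays; ROIs are
integer label images (0 = background).  The per-cell trace is the arithmetic
mean of the ROI's pixels in each frame, on the acquisition intensity scale
(relative units, nominally 0-255 for 8-bit data).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import tifffile
from skimage import measure
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)

__all__ = [
    "FluorescenceTrace",
    "RoiMap",
    "ViabilityCounts",
    "extract_traces",
    "count_viability",
    "segment_rois",
    "read_stack",
    "write_stack",
    "traces_to_frame",
    "write_traces_csv",
    "read_traces_csv",
]


@dataclass(frozen=True)
class FluorescenceTrace:
    """One cell's fluorescence time series in relative units.

    Parameters
    ----------
    cell_id : int
        ROI label / cell identifier.
    values : numpy.ndarray
        Intensity per frame (relative units).  Must hold at least two
        finite samples.
    frame_rate : float
        Acquisition rate in Hz.
    """

    cell_id: int
    values: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("trace needs at least 2 samples in a 1-D array")
        if not np.all(np.isfinite(values)):
            raise ValueError("trace values must be finite")
        if not (self.frame_rate > 0 and math.isfinite(self.frame_rate)):
            raise ValueError("frame_rate must be positive and finite")
        object.__setattr__(self, "values", values)

    @property
    def n_frames(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Recording length in seconds (n_frames / frame_rate)."""
        return self.n_frames / self.frame_rate

    @property
    def times(self) -> np.ndarray:
        """Frame timestamps in seconds, frame 0 at t = 0."""
        return np.arange(self.n_frames) / self.frame_rate


@dataclass(frozen=True)
class RoiMap:
    """Integer label image assigning pixels to cells (0 = background).

    ``labels`` may list the cell identifiers explicitly; any listed label
    without pixels is rejected at extraction time.  By default the labels
    are the sorted nonzero values present in the image.
    """

    label_image: np.ndarray
    labels: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        img = np.asarray(self.label_image)
        if img.ndim != 2:
            raise ValueError("label image must be 2-D")
        if not np.issubdtype(img.dtype, np.integer):
            raise ValueError("label image must have an integer dtype")
        if img.min() < 0:
            raise ValueError("labels must be non-negative")
        object.__setattr__(self, "label_image", img)
        if not self.labels:
            present = tuple(int(v) for v in np.unique(img) if v != 0)
            object.__setattr__(self, "labels", present)

    @classmethod
    def from_masks(cls, masks: Mapping[int, np.ndarray]) -> "RoiMap":
        """Build a label image from per-cell boolean masks.

        Raises
        ------
        ValueError
            If any two masks overlap (labels must be disjoint).
        """
        if not masks:
            raise ValueError("at least one mask is required")
        shapes = {np.asarray(m).shape for m in masks.values()}
        if len(shapes) != 1:
            raise ValueError("all masks must share one shape")
        shape = shapes.pop()
        img = np.zeros(shape, dtype=np.int32)
        coverage = np.zeros(shape, dtype=bool)
        for label, mask in masks.items():
            if label <= 0:
                raise ValueError(f"mask label {label} must be positive")
            mask = np.asarray(mask, dtype=bool)
            if np.any(coverage & mask):
                raise ValueError(f"ROI label {label} overlaps a previous ROI")
            coverage |= mask
            img[mask] = label
        return cls(img, tuple(masks))

    @property
    def shape(self) -> tuple[int, int]:
        return self.label_image.shape

    def mask(self, label: int) -> np.ndarray:
        return self.label_image == label

    def iter_masks(self) -> Iterator[tuple[int, np.ndarray]]:
        for label in self.labels:
            yield label, self.mask(label)


@dataclass(frozen=True)
class ViabilityCounts:
    """Dead / total nucleus counts and the dead-cell percentage.

    ``dead_fraction`` is NaN (and ``defined`` False) when no object is
    found in the total-stain channel; a zero denominator is flagged, never
    silently reported as 0 %.
    """

    n_dead: int
    n_total: int
    dead_fraction: float

    def __post_init__(self) -> None:
        if self.n_dead < 0 or self.n_total < 0:
            raise ValueError("counts must be non-negative")
        if self.n_dead > self.n_total:
            raise ValueError("n_dead cannot exceed n_total")

    @property
    def defined(self) -> bool:
        return self.n_total > 0


def extract_traces(
    stack: np.ndarray,
    rois: RoiMap,
    frame_rate: float,
) -> list[FluorescenceTrace]:
    """Extract per-cell mean-fluorescence traces from an image stack.

    The trace value at frame ``t`` is the arithmetic mean of the ROI's
    pixels in frame ``t``.

    Raises
    ------
    ValueError
        If frame dimensions differ from the label image, or a listed
        label has no pixels (the label is named in the message).
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be (n_frames, height, width)")
    if stack.shape[1:] != rois.shape:
        raise ValueError(
            f"stack frames {stack.shape[1:]} do not match ROI image {rois.shape}"
        )
    traces = []
    flat = stack.reshape(stack.shape[0], -1).astype(float)
    flat_labels = rois.label_image.ravel()
    for label in rois.labels:
        idx = np.flatnonzero(flat_labels == label)
        if idx.size == 0:
            raise ValueError(f"ROI label {label} has no pixels")
        traces.append(
            FluorescenceTrace(label, flat[:, idx].mean(axis=1), frame_rate)
        )
    return traces


def count_viability(
    dead_channel: np.ndarray,
    total_channel: np.ndarray,
    intensity_threshold: float | tuple[float, float] | None = None,
    min_object_area: int = 10,
) -> ViabilityCounts:
    """Count stained nuclei per channel and form the dead-cell percentage.

    Objects are 8-connected components of above-threshold pixels with area
    >= ``min_object_area``.  ``intensity_threshold`` may be one value for
    both channels, a ``(dead, total)`` pair, or ``None`` for per-channel
    Otsu thresholds.  If the raw dead count exceeds the total count it is
    capped at the total count and a warning is logged.
    """
    dead_channel = np.asarray(dead_channel)
    total_channel = np.asarray(total_channel)
    if dead_channel.shape != total_channel.shape:
        raise ValueError("channel images must share one shape")
    if isinstance(intensity_threshold, tuple):
        thr_dead, thr_total = intensity_threshold
    else:
        thr_dead = thr_total = intensity_threshold
    n_dead = _count_objects(dead_channel, thr_dead, min_object_area)
    n_total = _count_objects(total_channel, thr_total, min_object_area)
    if n_dead > n_total:
        logger.warning(
            "dead-channel count %d exceeds total-channel count %d; capping",
            n_dead,
            n_total,
        )
        n_dead = n_total
    fraction = 100.0 * n_dead / n_total if n_total > 0 else float("nan")
    return ViabilityCounts(n_dead, n_total, fraction)


def _count_objects(
    image: np.ndarray, threshold: float | None, min_object_area: int
) -> int:
    if threshold is None:
        if np.ptp(image) == 0:  # flat image: Otsu undefined, nothing to count
            return 0
        threshold = threshold_otsu(image)
    binary = image > threshold
    if not binary.any():
        return 0
    labelled = measure.label(binary, connectivity=2)
    areas = np.bincount(labelled.ravel())[1:]
    return int(np.sum(areas >= min_object_area))


def segment_rois(
    stack: np.ndarray, min_area: int = 10, threshold: float | None = None
) -> RoiMap:
    """Convenience ROI segmentation: Otsu on the temporal-mean image,
    8-connected components, area filter.

    Provided for exploratory use; analyses replicating the reference
    workflow should supply manually drawn label images instead.
    """
    mean_img = np.asarray(stack, dtype=float).mean(axis=0)
    if threshold is None:
        threshold = threshold_otsu(mean_img)
    labelled = measure.label(mean_img > threshold, connectivity=2)
    areas = np.bincount(labelled.ravel())
    out = np.zeros_like(labelled, dtype=np.int32)
    next_label = 1
    for label in range(1, areas.size):
        if areas[label] >= min_area:
            out[labelled == label] = next_label
            next_label += 1
    return RoiMap(out)


# ---------------------------------------------------------------------------
# file formats


def read_stack(path) -> np.ndarray:
    """Read a multi-page TIFF stack as (n_frames, height, width)."""
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    return stack


def write_stack(path, stack: np.ndarray) -> None:
    tifffile.imwrite(path, stack)


def traces_to_frame(traces: Sequence[FluorescenceTrace]):
    """Tabulate traces: ``time_s`` column plus one ``cell_<id>`` column each."""
    import pandas as pd

    if not traces:
        raise ValueError("no traces to tabulate")
    rates = {t.frame_rate for t in traces}
    lengths = {t.n_frames for t in traces}
    if len(rates) != 1 or len(lengths) != 1:
        raise ValueError("traces must share frame_rate and length")
    data = {"time_s": traces[0].times}
    for tr in traces:
        data[f"cell_{tr.cell_id}"] = tr.values
    return pd.DataFrame(data)


def write_traces_csv(path, traces: Sequence[FluorescenceTrace]) -> None:
    traces_to_frame(traces).to_csv(path, index=False)


def read_traces_csv(path) -> list[FluorescenceTrace]:
    """Read the trace CSV dialect (time_s + cell_* columns) back to traces."""
    import pandas as pd

    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError("traces CSV must have a time_s column")
    times = df["time_s"].to_numpy(float)
    if times.size < 2:
        raise ValueError("traces CSV must hold at least 2 frames")
    dt = np.diff(times)
    if not np.allclose(dt, dt[0]) or dt[0] <= 0:
        raise ValueError("time_s must increase in uniform steps")
    frame_rate = 1.0 / dt[0]
    traces = []
    for col in df.columns:
        if col.startswith("cell_"):
            cell_id = int(col.removeprefix("cell_"))
            traces.append(
                FluorescenceTrace(cell_id, df[col].to_numpy(float), frame_rate)
            )
    if not traces:
        raise ValueError("no cell_* columns found")
    return traces
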