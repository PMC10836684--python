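"""Micrograph quantification: hydrogel geometry, fluorescence, swelling.

Mirrors the analysis applied to real micrographs: binarize with Otsu's
threshold, take the largest 8-connected foreground component, and report
its axis-aligned bounding box as the hydrogel's length (box height) and
width (box width) in micrometers; mean fluorescence is averaged inside
the same rectangle. Time-lapse lengths become relative swelling curves
dL/L0 = (L(t) - L0) / L0 with L0 the first (pre-signal) measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .errors import (
    DegenerateImageError,
    InvalidParameterError,
    NoObjectError,
    UnknownChannelError,
)
from .micrograph import MicrographStack

__all__ = [
    "Measurement",
    "RoundStats",
    "SwellingCurve",
    "measure_length",
    "measure_objects",
    "measure_stack",
    "normalize_fluorescence",
    "otsu_threshold",
    "roi_mean_fluorescence",
    "round_stats",
    "swelling_curve",
]


@dataclass
class Measurement:
    """Geometry and fluorescence of one hydrogel object."""

    object_id: int
    length_um: float
    width_um: float
    mean_fluorescence: dict[str, float] = field(default_factory=dict)
    centroid_px: tuple[float, float] = (0.0, 0.0)
    bbox_px: tuple[int, int, int, int] = (0, 0, 0, 0)
    round_id: Optional[int] = None
    time_h: Optional[float] = None


@dataclass
class SwellingCurve:
    """Relative length change over time for one hydrogel edge."""

    times_h: np.ndarray
    dL_over_L0: np.ndarray
    L0_um: float
    edge_label: str = "free"

    def endpoint(self) -> float:
        return float(self.dL_over_L0[-1])


def otsu_threshold(img: np.ndarray) -> float:
    """Otsu's threshold over a 256-bin histogram of the image range.

    The returned value maximizes the between-class variance of the
    foreground/background split; a constant image has no two classes and
    raises :class:`DegenerateImageError`.
    """
    arr = np.asarray(img, dtype=np.float64)
    if arr.size == 0 or np.unique(arr).size < 2:
        raise DegenerateImageError("image has fewer than 2 distinct values")
    return float(threshold_otsu(arr, nbins=256))


def measure_length(
    img: np.ndarray,
    pixel_size_um: float,
    method: str = "otsu",
    rect: tuple[int, int, int, int] | None = None,
    object_id: int = 0,
) -> Measurement:
    """Measure one hydrogel in a single-channel image.

    ``otsu`` mode binarizes at the Otsu threshold and measures the
    largest 8-connected foreground component's bounding box; ``manual_rect``
    mode takes a caller-supplied ``(r0, c0, r1, c1)`` pixel rectangle
    (half-open), mirroring a hand-drawn rectangle selection. Length is
    box height x pixel size; width is box width x pixel size; mean
    intensity is averaged over the rectangle.
    """
    arr = np.asarray(img, dtype=np.float64)
    if pixel_size_um <= 0:
        raise InvalidParameterError("pixel size must be positive")
    if method == "manual_rect":
        if rect is None:
            raise InvalidParameterError("manual_rect mode requires rect")
        r0, c0, r1, c1 = rect
        if not (0 <= r0 < r1 <= arr.shape[0] and 0 <= c0 < c1 <= arr.shape[1]):
            raise InvalidParameterError(f"rect {rect} is empty or out of bounds")
        bbox = (r0, c0, r1, c1)
        centroid = ((r0 + r1) / 2.0, (c0 + c1) / 2.0)
    elif method == "otsu":
        thresh = otsu_threshold(arr)
        binary = arr > thresh
        if not binary.any():
            raise NoObjectError("no foreground pixels above the Otsu threshold")
        labels = label(binary, connectivity=2)
        regions = regionprops(labels)
        biggest = max(regions, key=lambda r: r.area)
        bbox = tuple(int(v) for v in biggest.bbox)  # (minr, minc, maxr, maxc)
        centroid = tuple(float(v) for v in biggest.centroid)
        r0, c0, r1, c1 = bbox
    else:
        raise InvalidParameterError(f"unknown method {method!r}")
    return Measurement(
        object_id=object_id,
        length_um=(r1 - r0) * pixel_size_um,
        width_um=(c1 - c0) * pixel_size_um,
        mean_fluorescence={"img": float(arr[r0:r1, c0:c1].mean())},
        centroid_px=centroid,
        bbox_px=bbox,
    )


def measure_stack(
    stack: MicrographStack, channel: str, object_id: int = 0
) -> Measurement:
    """Otsu-measure one channel of a stack; attaches all-channel ROI means."""
    m = measure_length(
        stack.channel(channel), stack.pixel_size_um, method="otsu", object_id=object_id
    )
    r0, c0, r1, c1 = m.bbox_px
    m.mean_fluorescence = {
        ch: float(stack.channels[ch][r0:r1, c0:c1].mean()) for ch in stack.channels
    }
    m.time_h = stack.time_h
    return m


def measure_objects(
    img: np.ndarray, pixel_size_um: float, min_area_px: int = 9
) -> list[Measurement]:
    """Otsu-measure every foreground object in a single-channel image.

    Objects smaller than ``min_area_px`` (noise speckle) are dropped;
    the rest are returned ordered by centroid (column-major: left to
    right, then top to bottom), each with its bounding-box geometry and
    in-box mean intensity.
    """
    arr = np.asarray(img, dtype=np.float64)
    thresh = otsu_threshold(arr)
    labels = label(arr > thresh, connectivity=2)
    regions = [r for r in regionprops(labels) if r.area >= min_area_px]
    if not regions:
        raise NoObjectError("no foreground objects above the minimum area")
    regions.sort(key=lambda r: (round(r.centroid[1]), round(r.centroid[0])))
    out = []
    for i, r in enumerate(regions):
        r0, c0, r1, c1 = r.bbox
        out.append(Measurement(
            object_id=i,
            length_um=(r1 - r0) * pixel_size_um,
            width_um=(c1 - c0) * pixel_size_um,
            mean_fluorescence={"img": float(arr[r0:r1, c0:c1].mean())},
            centroid_px=tuple(float(v) for v in r.centroid),
            bbox_px=(r0, c0, r1, c1),
        ))
    return out


def roi_mean_fluorescence(
    stack: MicrographStack, rect: tuple[int, int, int, int], channel: str
) -> float:
    """Mean intensity of ``channel`` inside pixel rect ``(r0, c0, r1, c1)``."""
    if channel not in stack.channels:
        raise UnknownChannelError(channel)
    arr = stack.channels[channel]
    r0, c0, r1, c1 = rect
    if not (0 <= r0 < r1 <= arr.shape[0] and 0 <= c0 < c1 <= arr.shape[1]):
        raise InvalidParameterError(f"rect {rect} is empty or out of bounds")
    return float(arr[r0:r1, c0:c1].mean())


def swelling_curve(
    times_h: Sequence[float],
    lengths_um: Sequence[float],
    edge_label: str = "free",
) -> SwellingCurve:
    """Build dL/L0 from time-ordered lengths of one object.

    The first timepoint is the pre-signal baseline L0, so the curve
    starts at exactly 0. At least two timepoints and a positive L0 are
    required.
    """
    t = np.asarray(times_h, dtype=np.float64)
    L = np.asarray(lengths_um, dtype=np.float64)
    if t.shape != L.shape or t.size < 2:
        raise InvalidParameterError("need >= 2 matching timepoints and lengths")
    if np.any(np.diff(t) < 0):
        raise InvalidParameterError("times must be nondecreasing")
    L0 = float(L[0])
    if L0 <= 0:
        raise InvalidParameterError(f"nonpositive baseline length {L0}")
    return SwellingCurve(
        times_h=t, dL_over_L0=(L - L0) / L0, L0_um=L0, edge_label=edge_label
    )


@dataclass
class RoundStats:
    """Per-round summary plus an across-round homogeneity test."""

    table: pd.DataFrame  # index round_id; columns mean/std per metric
    anova_F: Optional[float]
    anova_p: Optional[float]
    metric: str = "length_um"


def round_stats(
    measurements: Sequence[Measurement],
    metric: str = "length_um",
    channel: str | None = None,
) -> RoundStats:
    """Summarize a metric per patterning round and test homogeneity.

    ``metric`` is ``"length_um"``, ``"width_um"`` or ``"fluorescence"``
    (with ``channel``). Rounds are compared with one-way ANOVA at the
    caller's chosen alpha; with a single round the summary is returned
    without a test, and identically valued groups report F=0, p=1.
    """

    def value(m: Measurement) -> float:
        if metric == "fluorescence":
            if channel is None:
                raise InvalidParameterError("fluorescence metric requires a channel")
            return m.mean_fluorescence[channel]
        return getattr(m, metric)

    groups: dict[int, list[float]] = {}
    for m in measurements:
        if m.round_id is None:
            raise InvalidParameterError("measurements must carry round_id")
        groups.setdefault(m.round_id, []).append(value(m))
    rows = {
        rid: {"mean": float(np.mean(v)), "std": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
              "n": len(v)}
        for rid, v in sorted(groups.items())
    }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "round_id"
    if len(groups) < 2:
        return RoundStats(table=table, anova_F=None, anova_p=None, metric=metric)
    samples = [np.asarray(v) for v in groups.values()]
    flat = np.concatenate(samples)
    if np.allclose(flat, flat[0]):
        return RoundStats(table=table, anova_F=0.0, anova_p=1.0, metric=metric)
    F, p = stats.f_oneway(*samples)
    return RoundStats(table=table, anova_F=float(F), anova_p=float(p), metric=metric)


def normalize_fluorescence(
    series: Sequence[float], baseline_index: int = 0
) -> np.ndarray:
    """Divide a fluorescence series by its baseline entry (baseline -> 1)."""
    arr = np.asarray(series, dtype=np.float64)
    if not 0 <= baseline_index < arr.size:
        raise InvalidParameterError("baseline index out of range")
    baseline = arr[baseline_index]
    if baseline <= 0:
        raise InvalidParameterError(f"nonpositive baseline value {baseline}")
    return arr / baseline
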