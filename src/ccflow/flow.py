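"""Quantification of choriocapillaris filling from subtracted stacks.

Implements the measurements behind the qualitative observations: the
radial dye wave (arrival-time map and its correlation with distance from
the optic disc), functional-lobule segmentation, inter-lobule slow-zone
width statistics, fast/slow consecutive-frame overlays, and pulsatile
filling-cycle counting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.ndimage as ndi
from scipy.signal import find_peaks
from scipy.stats import spearmanr
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import medial_axis

from .errors import EmptySelectionError, NoUnitsError
from .subtraction import SubtractionStack

#: sentinel for pixels that never exceed the arrival threshold
UNDETECTED = np.inf


@dataclass
class ArrivalMap:
    """Per-pixel first-exceedance times (s); ``inf`` where never detected."""

    arrival_s: np.ndarray
    threshold: float

    @property
    def detected(self) -> np.ndarray:
        return np.isfinite(self.arrival_s)


@dataclass
class LobuleSegmentation:
    """Label map of functional filling units.

    ``labels`` uses 0 for inter-unit zone/background; units are 1..n_units.
    ``zone_mask`` covers all below-threshold pixels, disjoint from units.
    """

    labels: np.ndarray
    n_units: int
    unit_areas_um2: np.ndarray
    zone_mask: np.ndarray
    threshold: float
    pixel_pitch_um: float


@dataclass
class ZoneWidthStats:
    """Widths of inter-unit slow zones, sampled along their medial axes."""

    widths_um: np.ndarray
    percentile_5: float
    median: float
    percentile_95: float


@dataclass
class PulsatilityTrace:
    """ROI mean-intensity trace and its detected refilling peaks."""

    times_s: np.ndarray
    roi_mean_intensity: np.ndarray
    detected_peaks: np.ndarray  # peak times, s
    n_cycles: int


def arrival_time_map(sub: SubtractionStack, threshold_frac: float) -> ArrivalMap:
    """Time each pixel first exceeds ``threshold_frac`` of the stack max."""
    if not 0.0 < threshold_frac < 1.0:
        raise ValueError("threshold_frac must lie in (0, 1)")
    frames = np.asarray(sub.frames)
    if frames.size == 0:
        raise EmptySelectionError("empty stack")
    threshold = threshold_frac * float(frames.max())
    above = frames > threshold
    any_above = above.any(axis=0)
    first = above.argmax(axis=0)
    times = np.asarray(sub.timestamps_s)[first].astype(float)
    times[~any_above] = UNDETECTED
    return ArrivalMap(arrival_s=times, threshold=threshold)


def segment_functional_units(
    frame: np.ndarray,
    min_area_um2: float,
    pixel_pitch_um: float,
    split_merged: bool = False,
    split_min_distance_px: int = 14,
) -> LobuleSegmentation:
    """Segment bright filling units: Otsu threshold, 8-connected components.

    Components smaller than ``min_area_um2`` are discarded as noise specks.
    The zone mask is everything below threshold (slow or not-yet-filled).

    With ``split_merged`` a marker-controlled watershed on the distance
    transform of the bright mask additionally cuts components joined by
    narrow necks — lobules whose slow boundary zone is locally too thin or
    too faint to break 8-connectivity. Markers are distance-transform peaks
    at least ``split_min_distance_px`` apart.
    """
    frame = np.asarray(frame)
    if frame.min() == frame.max():
        raise NoUnitsError("constant frame: nothing to segment")
    thr = threshold_otsu(frame)
    bright = frame > thr
    if not bright.any():
        raise NoUnitsError("no pixels above threshold")
    if split_merged:
        labels = _watershed_split(bright, split_min_distance_px)
    else:
        labels = cc_label(bright, connectivity=2)
    px_area = pixel_pitch_um**2
    counts = np.bincount(labels.ravel())
    keep = np.flatnonzero(counts * px_area >= min_area_um2)
    keep = keep[keep != 0]
    if keep.size == 0:
        raise NoUnitsError("all components below the minimum unit area")
    remap = np.zeros(counts.size, dtype=np.int32)
    remap[keep] = np.arange(1, keep.size + 1)
    labels = remap[labels]
    return LobuleSegmentation(
        labels=labels,
        n_units=int(keep.size),
        unit_areas_um2=counts[keep] * px_area,
        zone_mask=~bright,
        threshold=float(thr),
        pixel_pitch_um=float(pixel_pitch_um),
    )


def measure_zone_widths(
    seg: LobuleSegmentation, pixel_pitch_um: float
) -> ZoneWidthStats:
    """Measure slow-zone widths along the zone medial axis.

    Width at a medial-axis point is twice the Euclidean distance to the
    nearest unit pixel, in micrometres. Only medial-axis points lying
    between two *distinct* units count (points flanked by a single unit,
    e.g. against the field border, are excluded). Distinctness is judged
    on connectivity of the bright mask: a gap only counts when it
    separates units that are genuinely disconnected, so hairline watershed
    cuts through a contiguous bright plate do not register as zones.
    """
    zone = np.asarray(seg.zone_mask, dtype=bool)
    if not zone.any():
        raise EmptySelectionError("zone mask is empty")
    units = seg.labels > 0
    if not units.any():
        raise EmptySelectionError("no units to measure between")

    # distance from every pixel to the nearest unit pixel, and that pixel's
    # component grown across the zones (a Voronoi partition of the gap space)
    components = cc_label(units, connectivity=2)
    dist, (iy, ix) = ndi.distance_transform_edt(~units, return_indices=True)
    grown = components[iy, ix]

    # fixed rng: medial_axis permutes its pixel-processing order otherwise,
    # making the skeleton (and the width sample) run-dependent
    skel = medial_axis(zone, rng=0)
    # a medial point separates two units iff >= 2 distinct grown labels
    # meet within its 3x3 neighbourhood
    lo = ndi.minimum_filter(grown, size=3)
    hi = ndi.maximum_filter(grown, size=3)
    between = skel & (lo != hi)
    if not between.any():
        raise EmptySelectionError("no medial-axis points between two units")
    widths = 2.0 * dist[between] * pixel_pitch_um
    widths = widths[widths > 0]
    if widths.size == 0:
        raise EmptySelectionError("no positive widths (units touch)")
    p5, med, p95 = np.percentile(widths, [5, 50, 95])
    return ZoneWidthStats(
        widths_um=np.sort(widths),
        percentile_5=float(p5),
        median=float(med),
        percentile_95=float(p95),
    )


def _watershed_split(bright: np.ndarray, min_distance_px: int) -> np.ndarray:
    """Cut bright components at narrow necks via distance-transform watershed."""
    from skimage.feature import peak_local_max
    from skimage.segmentation import watershed

    dist = ndi.distance_transform_edt(bright)
    peaks = peak_local_max(
        dist, min_distance=min_distance_px, labels=bright, exclude_border=False
    )
    if len(peaks) == 0:
        return cc_label(bright, connectivity=2)
    markers = np.zeros(bright.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    return watershed(-dist, markers, mask=bright)


def overlay_consecutive(frame_a: np.ndarray, frame_b: np.ndarray) -> np.ndarray:
    """Red/blue overlay of two consecutive subtracted frames.

    Red = earlier frame (fast-filling cores), blue = later frame (slow
    perimeter zones), green = 0. Channels are kept intact, no blending.
    """
    frame_a = np.asarray(frame_a)
    frame_b = np.asarray(frame_b)
    if frame_a.shape != frame_b.shape:
        raise ValueError("frames must share a shape")
    out = np.zeros(frame_a.shape + (3,), dtype=frame_a.dtype)
    out[..., 0] = frame_a
    out[..., 2] = frame_b
    return out


def count_filling_cycles(
    sub: SubtractionStack,
    roi: tuple[int, int, int, int],
    prominence_frac: float,
) -> PulsatilityTrace:
    """Count pulsatile refilling cycles in an ROI of the subtracted stack.

    ``roi`` is (row0, col0, height, width). The ROI mean-intensity trace is
    scanned for local maxima with prominence at least ``prominence_frac``
    times the trace maximum; trace endpoints are never peaks.
    """
    r0, c0, h, w = roi
    frames = np.asarray(sub.frames)
    if len(frames) < 4:
        raise EmptySelectionError("need at least 4 frames")
    if h <= 0 or w <= 0 or r0 < 0 or c0 < 0:
        raise ValueError("degenerate ROI")
    if r0 + h > frames.shape[1] or c0 + w > frames.shape[2]:
        raise ValueError("ROI exceeds frame bounds")
    trace = frames[:, r0 : r0 + h, c0 : c0 + w].mean(axis=(1, 2))
    prom = prominence_frac * float(trace.max()) if trace.max() > 0 else np.inf
    peaks, _ = find_peaks(trace, prominence=prom)
    times = np.asarray(sub.timestamps_s)[peaks]
    return PulsatilityTrace(
        times_s=np.asarray(sub.timestamps_s).copy(),
        roi_mean_intensity=trace,
        detected_peaks=times,
        n_cycles=int(len(peaks)),
    )


def radial_wave_stat(
    amap: ArrivalMap,
    disc_center_px: tuple[float, float],
    min_detected: int = 100,
) -> float:
    """Spearman correlation of arrival time with distance from the disc.

    ``disc_center_px`` is (x, y) in pixel coordinates (may be outside the
    image). A strongly positive value means the filling wave sweeps
    radially outward from the peripapillary side.
    """
    det = amap.detected
    n = int(det.sum())
    if n < min_detected:
        raise EmptySelectionError(f"only {n} detected pixels (< {min_detected})")
    yy, xx = np.nonzero(det)
    dx = xx - disc_center_px[0]
    dy = yy - disc_center_px[1]
    dist = np.hypot(dx, dy)
    rho, _ = spearmanr(amap.arrival_s[det], dist)
    return float(rho)


def max_otsu_variance_frame(sub: SubtractionStack) -> int:
    """Index of the frame with maximal Otsu inter-class variance.

    The frame on which bright filling units separate most strongly from the
    dark slow zones — the natural frame for lobule segmentation.
    """
    best_i, best_v = 0, -np.inf
    for i, f in enumerate(np.asarray(sub.frames)):
        if f.min() == f.max():
            continue
        v = _otsu_interclass_variance(f)
        if v > best_v:
            best_i, best_v = i, v
    if not np.isfinite(best_v):
        raise NoUnitsError("all frames constant")
    return best_i


def _otsu_interclass_variance(frame: np.ndarray) -> float:
    thr = threshold_otsu(frame)
    fg = frame > thr
    w1 = fg.mean()
    if w1 in (0.0, 1.0):
        return 0.0
    mu1 = frame[fg].mean()
    mu0 = frame[~fg].mean()
    return float(w1 * (1 - w1) * (mu1 - mu0) ** 2)
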