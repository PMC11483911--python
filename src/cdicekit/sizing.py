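"""Automated droplet detection and sizing for high-speed bright-field video.

Replaces manual Fiji measurement with a deterministic pipeline:

1. pixel calibration from repeated measurements of the capillary opening,
2. a temporal-median background model (plus a per-pixel variability map),
3. coarse segmentation of the background-subtracted frame, refined per
   candidate by re-thresholding at half the 90th-percentile contrast so
   the boundary lands on the half-amplitude point of the droplet rim,
4. two diameter estimates per droplet — area-equivalent and maximum-Feret
   (caliper) — with errors propagated from the pixel-size uncertainty and
   a fixed measurement floor,
5. population statistics (boxplot quartiles, 1.5 IQR outliers) and a
   deterministic bimodal split by 1-D within-class-variance minimisation,
   used to separate satellite droplets from primary droplets at low
   rotation speed.

Motion blur elongates droplets only along the flow axis, so regions with
eccentricity above a configurable threshold are sized from their minor
axis instead.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

logger = logging.getLogger(__name__)

__all__ = [
    "CalibrationModel",
    "DetectionFilters",
    "RegionCandidate",
    "DropletMeasurement",
    "PopulationStats",
    "Subpopulation",
    "calibrate_pixel_size",
    "background_model",
    "detect_droplets",
    "measure_diameter",
    "measure_stack",
    "population_stats",
    "split_bimodal",
    "match_to_truth",
]

#: Default pixel calibration of the imaging setup (um/px) and the single
#: droplet measurement error floor (um) from triplicate remeasurement.
DEFAULT_PIXEL_SIZE = 2.431
DEFAULT_PIXEL_SIZE_SD = 0.105
DEFAULT_MEASUREMENT_ERROR = 2.0


@dataclass(frozen=True)
class CalibrationModel:
    """Pixel scale with uncertainty and per-droplet measurement floor."""

    pixel_size_mean: float = DEFAULT_PIXEL_SIZE  # um/px
    pixel_size_sd: float = DEFAULT_PIXEL_SIZE_SD  # um/px
    measurement_error: float = DEFAULT_MEASUREMENT_ERROR  # um

    def __post_init__(self) -> None:
        if self.pixel_size_mean <= 0:
            raise ValueError("pixel_size_mean must be > 0")
        if self.pixel_size_sd < 0 or self.measurement_error < 0:
            raise ValueError("uncertainties must be >= 0")


def calibrate_pixel_size(
    capillary_widths_px,
    known_width_um: float,
    known_width_sd_um: float = 0.0,
    measurement_error_um: float = DEFAULT_MEASUREMENT_ERROR,
) -> CalibrationModel:
    """Derive the pixel scale from repeat measurements of the capillary.

    Parameters
    ----------
    capillary_widths_px : sequence of float
        At least three independent width measurements in pixels.
    known_width_um : float
        True capillary opening width.
    known_width_sd_um : float
        Uncertainty of the capillary width itself; propagated in
        quadrature with the spread (sample sd) of the measurements.
    """
    widths = np.asarray(capillary_widths_px, dtype=float)
    if widths.size < 3:
        raise ValueError("need at least 3 capillary width measurements")
    if np.any(widths <= 0) or known_width_um <= 0:
        raise ValueError("widths must be > 0")
    mean_w = widths.mean()
    pixel_size = known_width_um / mean_w
    rel_spread = widths.std(ddof=1) / mean_w
    rel_known = known_width_sd_um / known_width_um
    sd = pixel_size * math.hypot(rel_spread, rel_known)
    return CalibrationModel(pixel_size, sd, measurement_error_um)


def background_model(stack: np.ndarray, stride: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Temporal median background and per-pixel variability of a stack.

    ``stride`` subsamples the stack (every ``stride``-th frame) before
    computing the per-pixel median (background) and standard deviation
    (variability); e.g. stride 50 over 5000 frames uses exactly 100 frames.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("stack must be (n_frames >= 2, H, W)")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    sub = stack[::stride].astype(float)
    return np.median(sub, axis=0), sub.std(axis=0)


@dataclass(frozen=True)
class DetectionFilters:
    """Segmentation thresholds and rejection rules.

    ``min_diameter_px`` is the resolution floor (regions with smaller
    equivalent diameter cannot be measured with sufficient certainty);
    ``min_abs_contrast`` is the minimum background-subtracted intensity
    (absolute grey levels) to count as signal; ``min_circularity`` uses
    ``4 pi A / P^2``.
    """

    min_diameter_px: float = 2.0
    min_circularity: float = 0.6
    min_abs_contrast: float = 6.0
    exclude_border: bool = True
    min_region_px: int = 4
    smoothing_sigma: float = 1.0
    eccentricity_threshold: float = 0.2


@dataclass
class RegionCandidate:
    """One refined droplet candidate region in a frame."""

    mask: np.ndarray  # local boolean mask (refined)
    offset: tuple[int, int]  # (y, x) of mask[0, 0] in the frame
    centroid: tuple[float, float]  # (y, x) frame coordinates
    area_px: float
    equivalent_diameter_px: float
    feret_diameter_px: float
    minor_axis_px: float
    major_axis_px: float
    eccentricity: float
    circularity: float
    touches_border: bool
    frame_index: int = 0


def _region_candidate(
    local_mask: np.ndarray,
    offset: tuple[int, int],
    frame_shape: tuple[int, int],
    frame_index: int,
) -> RegionCandidate:
    props = measure.regionprops(local_mask.astype(np.uint8))[0]
    cy, cx = props.centroid
    cy += offset[0]
    cx += offset[1]
    perimeter = props.perimeter
    circ = 4.0 * math.pi * props.area / perimeter**2 if perimeter > 0 else 0.0
    miny, minx, maxy, maxx = props.bbox
    touches = (
        miny + offset[0] <= 0
        or minx + offset[1] <= 0
        or maxy + offset[0] >= frame_shape[0]
        or maxx + offset[1] >= frame_shape[1]
    )
    return RegionCandidate(
        mask=local_mask,
        offset=offset,
        centroid=(cy, cx),
        area_px=float(props.area),
        equivalent_diameter_px=float(props.equivalent_diameter_area),
        feret_diameter_px=float(props.feret_diameter_max),
        minor_axis_px=float(props.axis_minor_length),
        major_axis_px=float(props.axis_major_length),
        eccentricity=float(props.eccentricity),
        circularity=min(circ, 1.0),
        touches_border=touches,
        frame_index=frame_index,
    )


def detect_droplets(
    frame: np.ndarray,
    background: np.ndarray,
    filters: DetectionFilters | None = None,
    frame_index: int = 0,
) -> tuple[list[RegionCandidate], list[tuple[tuple[float, float], str]]]:
    """Detect droplet candidates in one background-subtracted frame.

    Droplets are darker than the background, so the signed difference
    ``background - frame`` (clipped at 0) is segmented.  A coarse mask at
    ``min_abs_contrast`` is split into connected components; each is
    refined by re-thresholding the raw difference at half its local
    90th-percentile amplitude (the rim half-amplitude point, i.e. the true
    droplet edge for rim-profiled droplets), hole-filled, and screened by
    the resolution floor, circularity and border rules.

    Returns
    -------
    (candidates, rejections)
        ``rejections`` holds (centroid, reason) for every screened-out
        component; reasons are ``below_resolution_floor``,
        ``low_circularity`` and ``touches_border``.
    """
    if filters is None:
        filters = DetectionFilters()
    frame = np.asarray(frame, dtype=float)
    if frame.shape != np.asarray(background).shape:
        raise ValueError("frame and background must have the same shape")
    diff = np.clip(np.asarray(background, dtype=float) - frame, 0.0, None)
    smooth = ndimage.gaussian_filter(diff, filters.smoothing_sigma)
    coarse = smooth > filters.min_abs_contrast
    coarse = ndimage.binary_fill_holes(coarse)
    labels, n_labels = ndimage.label(coarse)
    candidates: list[RegionCandidate] = []
    rejections: list[tuple[tuple[float, float], str]] = []
    pad = 3
    for lbl in range(1, n_labels + 1):
        component = labels == lbl
        if component.sum() < filters.min_region_px:
            continue
        ys, xs = np.nonzero(component)
        y0, y1 = max(0, ys.min() - pad), min(frame.shape[0], ys.max() + 1 + pad)
        x0, x1 = max(0, xs.min() - pad), min(frame.shape[1], xs.max() + 1 + pad)
        local_diff = diff[y0:y1, x0:x1]
        amplitude = np.percentile(local_diff[component[y0:y1, x0:x1]], 90)
        refined = local_diff > max(amplitude / 2.0, filters.min_abs_contrast / 2.0)
        refined = ndimage.binary_fill_holes(refined)
        # keep only the component overlapping the coarse detection
        ref_labels, _ = ndimage.label(refined)
        overlap = ref_labels[component[y0:y1, x0:x1]]
        overlap = overlap[overlap > 0]
        if overlap.size == 0:
            continue
        refined = ref_labels == np.bincount(overlap).argmax()
        cand = _region_candidate(refined, (y0, x0), frame.shape, frame_index)
        if cand.equivalent_diameter_px < filters.min_diameter_px:
            rejections.append((cand.centroid, "below_resolution_floor"))
            logger.debug("rejected region at %s: below resolution floor", cand.centroid)
        elif filters.exclude_border and cand.touches_border:
            rejections.append((cand.centroid, "touches_border"))
            logger.debug("rejected region at %s: touches border", cand.centroid)
        elif cand.circularity < filters.min_circularity:
            rejections.append((cand.centroid, "low_circularity"))
            logger.debug("rejected region at %s: low circularity", cand.centroid)
        else:
            candidates.append(cand)
    return candidates, rejections


@dataclass(frozen=True)
class DropletMeasurement:
    """Two independent diameter estimates for one droplet, in um."""

    area_equiv_diameter: float
    area_equiv_error: float
    caliper_diameter: float
    caliper_error: float
    centroid: tuple[float, float]
    circularity: float
    eccentricity: float
    frame_index: int


def measure_diameter(
    region: RegionCandidate,
    calibration: CalibrationModel,
    eccentricity_threshold: float = 0.2,
) -> DropletMeasurement:
    """Convert a candidate region to calibrated diameters with errors.

    The area-equivalent diameter is ``2 sqrt(A/pi) * pixel_size`` and the
    caliper diameter the maximum Feret extent (less one pixel: the Feret
    measure spans the pixel footprint, which overhangs a disk of diameter
    d by half a pixel on each side).  Each error is the
    quadrature sum of the relative pixel-size uncertainty scaled by the
    diameter and the fixed measurement floor.  Elongated regions
    (eccentricity above threshold, i.e. motion-blurred) are sized from the
    minor axis, which the blur leaves untouched.
    """
    if region.area_px < 2:
        raise ValueError("degenerate (single-pixel) region cannot be measured")
    px = calibration.pixel_size_mean
    if region.eccentricity > eccentricity_threshold:
        d_area_px = region.minor_axis_px
        d_caliper_px = region.minor_axis_px
    else:
        d_area_px = region.equivalent_diameter_px
        d_caliper_px = max(region.feret_diameter_px - 1.0, 1.0)
    d_area = d_area_px * px
    d_caliper = d_caliper_px * px
    rel = calibration.pixel_size_sd / calibration.pixel_size_mean
    err_area = math.hypot(d_area * rel, calibration.measurement_error)
    err_caliper = math.hypot(d_caliper * rel, calibration.measurement_error)
    return DropletMeasurement(
        area_equiv_diameter=d_area,
        area_equiv_error=err_area,
        caliper_diameter=d_caliper,
        caliper_error=err_caliper,
        centroid=region.centroid,
        circularity=region.circularity,
        eccentricity=region.eccentricity,
        frame_index=region.frame_index,
    )


MEASUREMENT_COLUMNS = [
    "frame_index",
    "centroid_y",
    "centroid_x",
    "area_equiv_diameter_um",
    "area_equiv_error_um",
    "caliper_diameter_um",
    "caliper_error_um",
    "circularity",
    "eccentricity",
]


def measure_stack(
    stack: np.ndarray,
    calibration: CalibrationModel,
    filters: DetectionFilters | None = None,
    background: np.ndarray | None = None,
    stride: int = 1,
) -> pd.DataFrame:
    """Run the full pipeline on a stack and return a measurement table."""
    if filters is None:
        filters = DetectionFilters()
    if background is None:
        background, _ = background_model(stack, stride=stride)
    rows = []
    for f in range(stack.shape[0]):
        candidates, _ = detect_droplets(stack[f], background, filters, frame_index=f)
        for cand in candidates:
            m = measure_diameter(cand, calibration, filters.eccentricity_threshold)
            rows.append(
                (
                    f,
                    m.centroid[0],
                    m.centroid[1],
                    m.area_equiv_diameter,
                    m.area_equiv_error,
                    m.caliper_diameter,
                    m.caliper_error,
                    m.circularity,
                    m.eccentricity,
                )
            )
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def match_to_truth(
    measurements: pd.DataFrame, truth: pd.DataFrame, max_distance_px: float = 10.0
) -> pd.DataFrame:
    """Join measurements to ground truth by nearest centroid per frame."""
    merged = []
    for f, group in measurements.groupby("frame_index"):
        t = truth[truth["frame_index"] == f]
        if t.empty:
            continue
        tx = t["center_x"].to_numpy()
        ty = t["center_y"].to_numpy()
        for _, row in group.iterrows():
            dist = np.hypot(tx - row["centroid_x"], ty - row["centroid_y"])
            j = int(dist.argmin())
            if dist[j] <= max_distance_px + t["true_diameter_um"].iloc[j]:
                rec = row.to_dict()
                rec["true_diameter_um"] = t["true_diameter_um"].iloc[j]
                rec["subpopulation"] = t["subpopulation"].iloc[j]
                rec["match_distance_px"] = float(dist[j])
                merged.append(rec)
    return pd.DataFrame(merged)


# ---------------------------------------------------------------------------
# Population statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Subpopulation:
    mean: float
    sd: float
    n: int
    label: str


@dataclass(frozen=True)
class PopulationStats:
    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    outliers: tuple[float, ...]
    subpopulations: tuple[Subpopulation, ...] | None = None


def population_stats(diameters, split: bool = False) -> PopulationStats:
    """Boxplot-style summary of a diameter sample.

    Quartiles use linear interpolation; outliers are points beyond
    1.5 IQR from the quartiles (conventional boxplot whiskers).  With
    ``split=True`` (and n >= 4) a bimodal split is attempted.
    """
    d = np.asarray(diameters, dtype=float)
    if d.size == 0:
        raise ValueError("need at least one measurement")
    q1, med, q3 = np.percentile(d, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = tuple(float(v) for v in d[(d < lo) | (d > hi)])
    subpops = None
    if split and d.size >= 4:
        subpops = tuple(split_bimodal(d))
    return PopulationStats(
        n=int(d.size),
        mean=float(d.mean()),
        sd=float(d.std(ddof=1)) if d.size > 1 else 0.0,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        outliers=outliers,
        subpopulations=subpops,
    )


def split_bimodal(diameters, separation_factor: float = 3.0) -> list[Subpopulation]:
    """Split a 1-D diameter sample into at most two subpopulations.

    The threshold minimises the weighted within-class variance over all
    splits of the sorted sample (the exact 1-D analogue of Otsu's
    criterion, no histogram binning).  The split is accepted only when the
    class means differ by more than ``separation_factor`` pooled standard
    deviations; otherwise a single population is returned.  Labels are
    ``small`` / ``large`` (or ``all`` for a single population).
    """
    d = np.sort(np.asarray(diameters, dtype=float))
    n = d.size
    if n < 4:
        raise ValueError("bimodal split requires at least 4 measurements")

    def _pop(values: np.ndarray, label: str) -> Subpopulation:
        sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
        return Subpopulation(float(values.mean()), sd, int(values.size), label)

    best_k, best_wcv = None, np.inf
    # prefix sums give O(n) within-class variance over all split points
    csum = np.cumsum(d)
    csum2 = np.cumsum(d**2)
    for k in range(2, n - 1):  # both classes get >= 2 points
        n1, n2 = k, n - k
        s1, s2 = csum[k - 1], csum[-1] - csum[k - 1]
        ss1, ss2 = csum2[k - 1], csum2[-1] - csum2[k - 1]
        var1 = ss1 / n1 - (s1 / n1) ** 2
        var2 = ss2 / n2 - (s2 / n2) ** 2
        wcv = n1 * var1 + n2 * var2
        if wcv < best_wcv:
            best_wcv, best_k = wcv, k
    low, high = d[:best_k], d[best_k:]
    pooled_var = (
        (low.size - 1) * low.var(ddof=1) + (high.size - 1) * high.var(ddof=1)
    ) / max(n - 2, 1)
    pooled_sd = math.sqrt(max(pooled_var, 0.0))
    if high.mean() - low.mean() > separation_factor * pooled_sd:
        return [_pop(low, "small"), _pop(high, "large")]
    return [_pop(d, "all")]
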