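"""Per-nucleus marker-positivity quantification from two-channel images.

The workflow mirrors a standard ImageJ-style analysis: threshold the
nuclear (DAPI) channel, take connected components as nucleus ROIs with a
size filter, subtract a smooth background from the marker channel with a
rolling-ball-style morphological estimate, measure marker intensity per
nucleus, classify nuclei as marker-positive, and report the percentage
of positive nuclei per anatomical region.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import disk, opening

DEFAULT_MIN_AREA = 20
DEFAULT_ROLLING_BALL_RADIUS = 50


@dataclass
class TwoChannelImage:
    """Paired nuclear (DAPI) and marker intensity images."""

    dapi: np.ndarray
    marker: np.ndarray
    pixel_size: Optional[float] = None  # micrometers per pixel
    region_masks: Optional[dict[str, np.ndarray]] = None

    def __post_init__(self) -> None:
        self.dapi = np.asarray(self.dapi, dtype=float)
        self.marker = np.asarray(self.marker, dtype=float)
        if self.dapi.ndim != 2 or self.dapi.shape != self.marker.shape:
            raise ValueError("dapi and marker must be equal-shape 2-D arrays")
        if (self.dapi < 0).any() or (self.marker < 0).any():
            raise ValueError("intensities must be >= 0")
        if self.region_masks is not None:
            for name, mask in self.region_masks.items():
                if mask.shape != self.dapi.shape:
                    raise ValueError(f"region mask {name!r} shape mismatch")


@dataclass
class NucleusROI:
    """One segmented nucleus: its pixel coordinates and geometry."""

    label: int
    rows: np.ndarray
    cols: np.ndarray
    area: int
    centroid: tuple[float, float]


@dataclass
class PositivityResult:
    region: str
    n_nuclei: int
    n_positive: int
    percent_positive: Optional[float]


def segment_nuclei(
    dapi: np.ndarray,
    method: str = "otsu",
    min_area: int = DEFAULT_MIN_AREA,
    max_area: Optional[int] = None,
) -> list[NucleusROI]:
    """Threshold the DAPI channel and extract nucleus ROIs.

    ``method`` is ``"otsu"`` or ``"fixed:<value>"``.  Components use
    8-connectivity; ROIs outside ``[min_area, max_area]`` are dropped
    and labels are reassigned in raster order of each component's first
    pixel.  Touching nuclei merge into one ROI (no watershed split).
    """
    img = np.asarray(dapi, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D array")
    if not img.any():
        return []
    if method == "otsu":
        threshold = float(threshold_otsu(img))
    elif method.startswith("fixed:"):
        threshold = float(method.split(":", 1)[1])
    else:
        raise ValueError(f"unknown method {method!r}")
    mask = img > threshold
    labeled = cc_label(mask, connectivity=2)
    rois = []
    next_label = 1
    for prop in regionprops(labeled):  # regionprops is raster-ordered by label
        if prop.area < min_area:
            continue
        if max_area is not None and prop.area > max_area:
            continue
        coords = prop.coords
        rois.append(
            NucleusROI(
                label=next_label,
                rows=coords[:, 0].copy(),
                cols=coords[:, 1].copy(),
                area=int(prop.area),
                centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
            )
        )
        next_label += 1
    return rois


def rolling_ball_subtract(
    marker: np.ndarray, radius: int = DEFAULT_ROLLING_BALL_RADIUS
) -> np.ndarray:
    """Subtract a smooth background estimated by grayscale opening.

    The background is the morphological opening of the image with a disk
    of the given radius (a documented approximation of the classic
    rolling-ball estimate); features smaller than the disk survive the
    subtraction, smooth background does not.  Output is clipped at 0.
    """
    img = np.asarray(marker, dtype=float)
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if radius > img.shape[0] and radius > img.shape[1]:
        raise ValueError("radius exceeds both image dimensions")
    try:  # decomposed footprint is much faster for large radii
        footprint = disk(radius, decomposition="sequence")
    except TypeError:  # pragma: no cover - older scikit-image
        footprint = disk(radius)
    background = opening(img, footprint)
    return np.clip(img - background, 0.0, None)


def nucleus_intensities(
    rois: Sequence[NucleusROI], corrected_marker: np.ndarray
) -> pd.DataFrame:
    """Mean and median corrected marker intensity per nucleus."""
    img = np.asarray(corrected_marker, dtype=float)
    rows = []
    for roi in rois:
        if roi.rows.size == 0:
            raise ValueError(f"ROI {roi.label} is empty")
        if roi.rows.max() >= img.shape[0] or roi.cols.max() >= img.shape[1]:
            raise ValueError(f"ROI {roi.label} outside image bounds")
        pixels = img[roi.rows, roi.cols]
        rows.append({
            "label": roi.label,
            "area": roi.area,
            "mean_intensity": float(pixels.mean()),
            "median_intensity": float(np.median(pixels)),
        })
    return pd.DataFrame(rows)


def _otsu_exact(values: np.ndarray) -> float:
    """Exact Otsu threshold for a 1-D sample.

    Evaluates every split of the sorted values (no histogram binning,
    which matters for small samples with wide empty gaps) and returns
    the midpoint between the two values at the between-class-variance
    maximizing split.
    """
    x = np.sort(values)
    n = x.size
    csum = np.cumsum(x)
    k = np.arange(1, n)
    mean0 = csum[:-1] / k
    mean1 = (csum[-1] - csum[:-1]) / (n - k)
    between = k * (n - k) * (mean0 - mean1) ** 2
    best = int(np.argmax(between))
    return 0.5 * (x[best] + x[best + 1])


def classify_positive(
    intensities: Sequence[float] | pd.Series,
    strategy: str = "otsu_on_nucleus_means",
) -> np.ndarray:
    """Boolean marker-positivity per nucleus.

    ``strategy`` is ``"otsu_on_nucleus_means"`` (default: exact Otsu
    split of the per-nucleus means, high cluster positive) or
    ``"fixed:<value>"`` (positive iff mean > value).
    """
    values = np.asarray(intensities, dtype=float)
    if values.size == 0:
        raise ValueError("no ROIs to classify")
    if strategy == "otsu_on_nucleus_means":
        if np.unique(values).size < 2:
            return np.zeros(values.shape, dtype=bool)
        threshold = _otsu_exact(values)
        return values > threshold
    if strategy.startswith("fixed:"):
        parts = strategy.split(":", 1)
        if len(parts) != 2 or parts[1] == "":
            raise ValueError("fixed strategy requires a value, e.g. 'fixed:10'")
        return values > float(parts[1])
    if strategy == "fixed":
        raise ValueError("fixed strategy requires a value, e.g. 'fixed:10'")
    raise ValueError(f"unknown strategy {strategy!r}")


def quantify_regions(
    image: TwoChannelImage,
    rois: Sequence[NucleusROI],
    positives: Sequence[bool],
) -> list[PositivityResult]:
    """Percent marker-positive nuclei per region.

    Each ROI is assigned to the region whose mask contains the pixel at
    its (rounded) centroid; without masks a single ``whole_image``
    region is used.  Regions with no nuclei report a null percentage.
    """
    positives = np.asarray(positives, dtype=bool)
    if len(positives) != len(rois):
        raise ValueError("positives length disagrees with ROI count")
    masks = image.region_masks
    if not masks:
        masks = {"whole_image": np.ones_like(image.dapi, dtype=bool)}
    overlap = np.zeros_like(image.dapi, dtype=int)
    for mask in masks.values():
        overlap += mask.astype(int)
    if (overlap > 1).any():
        raise ValueError("region masks overlap")

    counts = {name: [0, 0] for name in masks}
    for roi, pos in zip(rois, positives):
        r = int(round(roi.centroid[0]))
        c = int(round(roi.centroid[1]))
        r = min(max(r, 0), image.dapi.shape[0] - 1)
        c = min(max(c, 0), image.dapi.shape[1] - 1)
        for name, mask in masks.items():
            if mask[r, c]:
                counts[name][0] += 1
                counts[name][1] += int(pos)
                break
    results = []
    for name in masks:
        n, npos = counts[name]
        results.append(
            PositivityResult(
                region=name,
                n_nuclei=n,
                n_positive=npos,
                percent_positive=(100.0 * npos / n) if n else None,
            )
        )
    return results


def quantify_image(
    image: TwoChannelImage,
    segmentation_method: str = "otsu",
    min_area: int = DEFAULT_MIN_AREA,
    max_area: Optional[int] = None,
    rolling_ball_radius: int = DEFAULT_ROLLING_BALL_RADIUS,
    positivity_strategy: str = "otsu_on_nucleus_means",
    intensity_stat: str = "mean_intensity",
) -> tuple[list[PositivityResult], dict]:
    """End-to-end quantification; returns results plus provenance.

    The provenance dict records every threshold and parameter actually
    used, sufficient to reproduce the run.
    """
    rois = segment_nuclei(image.dapi, segmentation_method, min_area, max_area)
    provenance = {
        "segmentation_method": segmentation_method,
        "min_area": min_area,
        "max_area": max_area,
        "rolling_ball_radius": rolling_ball_radius,
        "positivity_strategy": positivity_strategy,
        "intensity_stat": intensity_stat,
        "n_rois": len(rois),
    }
    if not rois:
        masks = image.region_masks or {"whole_image": None}
        return (
            [PositivityResult(name, 0, 0, None) for name in masks],
            provenance,
        )
    corrected = rolling_ball_subtract(image.marker, rolling_ball_radius)
    table = nucleus_intensities(rois, corrected)
    positives = classify_positive(table[intensity_stat], positivity_strategy)
    results = quantify_regions(image, rois, positives)
    return results, provenance


def results_to_frame(results: Sequence[PositivityResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "region": r.region,
                "n_nuclei": r.n_nuclei,
                "n_positive": r.n_positive,
                "percent_positive": r.percent_positive,
            }
            for r in results
        ]
    )
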