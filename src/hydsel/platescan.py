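"""Synthetic plate rendering and colony detection.

The colony-growth dose-response assay photographs agar plates seeded with
~50 cells after days of growth under a custom atmosphere, then identifies
and sizes colonies computationally.  This module provides both ends of that
loop: a renderer that draws disk-like colonies (soft Gaussian-style edges,
uneven background, sensor noise) with the ground truth retained, and a
detector (background-corrected global Otsu threshold, connected components,
area filter, optional watershed split) whose calls feed dose-response
tables.

Colonies are assumed brighter than background, as on an inverted camera
stage; set ``polarity='dark'`` for the opposite convention.  The plate rim
is excluded by a circular mask (default 95% of the plate radius).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.segmentation import watershed

from .fitkit import DoseResponse
from .seqcore import ValidationError


class PackingError(ValueError):
    """Too many colonies for the available plate area."""


@dataclass
class PlateImage:
    """Single-channel plate photograph with values in [0, 1]."""

    pixels: np.ndarray
    pixel_size_mm: Optional[float] = None
    mask_fraction: float = 0.95

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValidationError("plate image must be single-channel 2-D")
        if min(self.pixels.shape) < 64:
            raise ValidationError("plate image must be at least 64x64")

    @property
    def plate_mask(self) -> np.ndarray:
        h, w = self.pixels.shape
        r = self.mask_fraction * min(h, w) / 2.0
        yy, xx = np.ogrid[:h, :w]
        return (yy - (h - 1) / 2) ** 2 + (xx - (w - 1) / 2) ** 2 <= r**2

    def save(self, path: str | Path) -> None:
        """Write as 16-bit grayscale PNG or TIFF (by extension)."""
        arr = np.clip(self.pixels, 0, 1)
        iio.imwrite(str(path), (arr * 65535).round().astype(np.uint16))

    @classmethod
    def load(
        cls, path: str | Path, pixel_size_mm: Optional[float] = None,
        mask_fraction: float = 0.95,
    ) -> "PlateImage":
        raw = iio.imread(str(path))
        if raw.ndim == 3:
            raise ValidationError(f"{path}: expected a single-channel image")
        info = np.iinfo(raw.dtype) if np.issubdtype(raw.dtype, np.integer) else None
        arr = raw.astype(float) / (info.max if info else 1.0)
        return cls(arr, pixel_size_mm=pixel_size_mm, mask_fraction=mask_fraction)


@dataclass
class PlateGroundTruth:
    """Rendered colony centers and radii, one entry per colony."""

    centroids: list[tuple[float, float]]
    radii: list[float]

    def areas(self) -> np.ndarray:
        return np.pi * np.asarray(self.radii) ** 2


@dataclass
class ColonyCall:
    centroid: tuple[float, float]
    area_px2: float
    equivalent_diameter: float
    mean_intensity: float
    area_mm2: Optional[float] = None


def render_plate(
    n_colonies: int = 50,
    shape: tuple[int, int] = (384, 384),
    radius_mean: float = 6.0,
    radius_sd: float = 1.0,
    intensity: float = 0.6,
    background: float = 0.15,
    gradient: float = 0.05,
    noise_sigma: float = 0.05,
    edge_softness: float = 1.0,
    min_separation: float = 6.0,
    mask_fraction: float = 0.95,
    seed: int = 0,
    max_attempts_per_colony: int = 2000,
) -> tuple[PlateImage, PlateGroundTruth]:
    """Render a synthetic plate photograph with known colony positions.

    Colonies are disks with a logistic (Gaussian-like) edge roll-off of scale
    ``edge_softness`` px, placed with at least ``min_separation`` px between
    rims inside the plate mask, on a tilted background with additive Gaussian
    noise.  Raises PackingError when placement is infeasible.
    """
    if n_colonies < 0 or radius_mean <= 0 or intensity <= 0:
        raise ValidationError("render parameters must be positive")
    rng = np.random.default_rng(seed)
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    plate_r = mask_fraction * min(h, w) / 2.0

    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    for _ in range(n_colonies):
        r = float(np.clip(rng.normal(radius_mean, radius_sd), 0.3 * radius_mean, None))
        placed = False
        for _attempt in range(max_attempts_per_colony):
            # uniform over the disk where the whole colony fits
            rho = (plate_r - r - 2) * np.sqrt(rng.random())
            theta = rng.random() * 2 * np.pi
            y, x = cy + rho * np.sin(theta), cx + rho * np.cos(theta)
            if all(
                np.hypot(y - yi, x - xi) >= r + ri + min_separation
                for (yi, xi), ri in zip(centers, radii)
            ):
                centers.append((y, x))
                radii.append(r)
                placed = True
                break
        if not placed:
            raise PackingError(
                f"could not place colony {len(centers) + 1} of {n_colonies} "
                f"(plate radius {plate_r:.0f}px, min separation {min_separation}px)"
            )

    yy, xx = np.mgrid[:h, :w]
    img = background + gradient * ((yy - cy) / h + (xx - cx) / w)
    for (y, x), r in zip(centers, radii):
        pad = int(np.ceil(r + 6 * edge_softness))
        y0, y1 = max(0, int(y) - pad), min(h, int(y) + pad + 1)
        x0, x1 = max(0, int(x) - pad), min(w, int(x) + pad + 1)
        d = np.hypot(yy[y0:y1, x0:x1] - y, xx[y0:y1, x0:x1] - x)
        img[y0:y1, x0:x1] += intensity / (1.0 + np.exp((d - r) / edge_softness))
    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    return (
        PlateImage(img, mask_fraction=mask_fraction),
        PlateGroundTruth(centroids=centers, radii=radii),
    )


@dataclass
class DetectionConfig:
    """Tunables of the colony detector; all recorded in reports."""

    min_area: int = 8
    max_area: Optional[int] = None
    background_size: int = 31  # median-filter kernel (px) for background removal
    polarity: str = "bright"  # colonies brighter ('bright') or darker ('dark')
    mask_fraction: float = 0.95
    split_touching: bool = False  # watershed split of merged blobs
    threshold: Optional[float] = None  # fixed threshold; None = Otsu
    refine_sizing: bool = True  # per-colony half-maximum (FWHM) area refinement
    noise_floor_sigmas: float = 3.5  # threshold never below this many MAD-sigmas


def detect_colonies(
    img: PlateImage, config: Optional[DetectionConfig] = None
) -> list[ColonyCall]:
    """Detect and size colonies; calls are sorted by area, largest first.

    Pipeline: median-filter background subtraction, Otsu (or fixed) global
    threshold inside the plate mask, connected components, area filtering,
    optional watershed split of touching blobs.  A constant or saturated
    image yields an empty list with a warning.
    """
    cfg = config or DetectionConfig()
    px = img.pixels if cfg.polarity == "bright" else 1.0 - img.pixels
    img = PlateImage(img.pixels, img.pixel_size_mm, cfg.mask_fraction)
    mask = img.plate_mask
    corrected = px - ndimage.median_filter(px, size=cfg.background_size)
    inside = corrected[mask]
    if np.ptp(inside) < 1e-9:
        warnings.warn("plate image is constant/saturated inside the mask; no colonies",
                      stacklevel=2)
        return []
    if cfg.threshold is None:
        # Otsu finds a split even in pure noise, so the threshold is floored
        # at a robust (MAD-based) multiple of the background sigma; plates
        # with no real signal then yield no components of colony size.
        sigma = 1.4826 * np.median(np.abs(inside - np.median(inside)))
        thr = max(threshold_otsu(inside), cfg.noise_floor_sigmas * sigma)
    else:
        thr = cfg.threshold
    binary = (corrected > thr) & mask
    if not binary.any():
        return []
    if cfg.split_touching:
        distance = ndimage.distance_transform_edt(binary)
        from skimage.feature import peak_local_max

        peaks = peak_local_max(
            distance, labels=label(binary), min_distance=3, exclude_border=False
        )
        markers = np.zeros_like(binary, dtype=int)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        labels = watershed(-distance, markers, mask=binary)
    else:
        labels = label(binary)
    calls = []
    for region in regionprops(labels, intensity_image=px):
        if region.area < cfg.min_area:
            continue
        if cfg.max_area is not None and region.area > cfg.max_area:
            continue
        area = float(region.area)
        y, x = region.centroid
        if cfg.refine_sizing:
            refined = _refine_fwhm(corrected, labels, region)
            if refined is not None:
                area, (y, x) = refined
        hh, ww = px.shape
        r = cfg.mask_fraction * min(hh, ww) / 2.0
        if (y - (hh - 1) / 2) ** 2 + (x - (ww - 1) / 2) ** 2 > r**2:
            continue
        area_mm2 = (
            area * img.pixel_size_mm**2 if img.pixel_size_mm else None
        )
        calls.append(
            ColonyCall(
                centroid=(float(y), float(x)),
                area_px2=area,
                equivalent_diameter=float(np.sqrt(4 * area / np.pi)),
                mean_intensity=float(region.intensity_mean),
                area_mm2=area_mm2,
            )
        )
    calls.sort(key=lambda c: c.area_px2, reverse=True)
    return calls


def _refine_fwhm(
    corrected: np.ndarray, labels: np.ndarray, region
) -> Optional[tuple[float, tuple[float, float]]]:
    """Resize one detected blob at half its peak (background-corrected) height.

    The global threshold that best *detects* colonies generally sits below
    the half-maximum of the radial intensity profile, so raw component areas
    overestimate disk areas; re-thresholding each colony's neighborhood at
    half of its robust peak recovers the full-width-half-maximum footprint,
    which for a symmetric edge profile matches the true disk.
    """
    pad = 6
    zoom = 4  # subpixel sizing: quantization error shrinks by zoom^2
    (y0, x0, y1, x1) = region.bbox
    y0, x0 = max(0, y0 - pad), max(0, x0 - pad)
    y1, x1 = min(corrected.shape[0], y1 + pad), min(corrected.shape[1], x1 + pad)
    patch = corrected[y0:y1, x0:x1]
    in_region = labels[y0:y1, x0:x1] == region.label
    peak = np.quantile(patch[in_region], 0.9)
    if peak <= 0:
        return None
    up = ndimage.zoom(patch, zoom, order=1)
    half = ndimage.binary_fill_holes(up >= peak / 2.0)
    lab = label(half)
    cy, cx = region.centroid
    sy = min(int(round((cy - y0) * zoom)), lab.shape[0] - 1)
    sx = min(int(round((cx - x0) * zoom)), lab.shape[1] - 1)
    if lab[sy, sx] == 0:
        return None
    comp = lab == lab[sy, sx]
    # a merged neighbor would have been a separate Otsu-level component;
    # restrict to this blob's own and unclaimed territory
    claim = ndimage.zoom(
        (labels[y0:y1, x0:x1] == region.label) | (labels[y0:y1, x0:x1] == 0),
        zoom, order=0,
    )
    comp &= claim
    if not comp.any():
        return None
    area = float(comp.sum()) / zoom**2
    ys, xs = np.nonzero(comp)
    return area, (float(ys.mean()) / zoom + y0, float(xs.mean()) / zoom + x0)


def evaluate_detection(
    calls: Sequence[ColonyCall],
    truth: PlateGroundTruth,
    max_centroid_dist: float = 3.0,
) -> dict:
    """Greedy centroid matching of calls to ground truth.

    Returns recall, precision and per-matched-colony relative area errors
    against the analytic disk area pi r^2.
    """
    unmatched = list(range(len(truth.centroids)))
    matches: list[tuple[int, int]] = []
    for ci, call in enumerate(calls):
        best, best_d = None, max_centroid_dist
        for ti in unmatched:
            ty, tx = truth.centroids[ti]
            d = float(np.hypot(call.centroid[0] - ty, call.centroid[1] - tx))
            if d <= best_d:
                best, best_d = ti, d
        if best is not None:
            matches.append((ci, best))
            unmatched.remove(best)
    n_truth, n_calls = len(truth.centroids), len(calls)
    recall = len(matches) / n_truth if n_truth else 1.0
    precision = len(matches) / n_calls if n_calls else 1.0
    rel_area_err = [
        (calls[ci].area_px2 - np.pi * truth.radii[ti] ** 2)
        / (np.pi * truth.radii[ti] ** 2)
        for ci, ti in matches
    ]
    return {
        "recall": recall,
        "precision": precision,
        "n_matched": len(matches),
        "rel_area_errors": np.asarray(rel_area_err),
    }


@dataclass
class PlateSummary:
    o2_percent: float
    h2: bool
    mean_area: float
    sd_area: float
    n_colonies: int
    flagged_empty: bool = False


def summarize_plate(
    calls: Sequence[ColonyCall], o2_percent: float, h2: bool = True
) -> PlateSummary:
    """Mean/SD colony area for one plate; empty plates are flagged."""
    if not calls:
        return PlateSummary(o2_percent, h2, 0.0, float("nan"), 0, flagged_empty=True)
    areas = np.array([c.area_px2 for c in calls])
    return PlateSummary(
        o2_percent=o2_percent,
        h2=h2,
        mean_area=float(areas.mean()),
        sd_area=float(areas.std(ddof=1)) if areas.size > 1 else float("nan"),
        n_colonies=int(areas.size),
    )


def dose_response_from_summaries(
    summaries: Sequence[PlateSummary],
) -> DoseResponse:
    """Assemble plate summaries (one atmosphere) into a DoseResponse table."""
    ordered = sorted(summaries, key=lambda s: s.o2_percent)
    return DoseResponse(
        o2_levels=np.array([s.o2_percent for s in ordered]),
        responses=np.array([s.mean_area for s in ordered]),
        sd=np.array([s.sd_area for s in ordered]),
        n=np.array([s.n_colonies for s in ordered]),
    )


def summaries_to_frame(summaries: Sequence[PlateSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "o2_percent": [s.o2_percent for s in summaries],
            "h2": [s.h2 for s in summaries],
            "mean_area": [s.mean_area for s in summaries],
            "sd_area": [s.sd_area for s in summaries],
            "n_colonies": [s.n_colonies for s in summaries],
            "flagged_empty": [s.flagged_empty for s in summaries],
        }
    )


def calls_to_frame(calls: Sequence[ColonyCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "centroid_row": [c.centroid[0] for c in calls],
            "centroid_col": [c.centroid[1] for c in calls],
            "area_px2": [c.area_px2 for c in calls],
            "eq_diameter_px": [c.equivalent_diameter for c in calls],
            "mean_intensity": [c.mean_intensity for c in calls],
        }
    )
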