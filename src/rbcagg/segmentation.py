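"""From a raw field of view to labeled regions with measured properties.

The stages mirror how RBC aggregates are extracted from phase-contrast
frames in practice: intensity conditioning (contrast stretch, optional
illumination flattening and light denoising), threshold binarization with
foreground-polarity detection (cells are darker than the background, but
halos can flip naive assumptions), mask clean-up, and connected-component
labeling with per-region morphometry including skeleton endpoint and
branch-point counts used for rouleau / branched / network classification
downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import filters, measure, morphology

from .synthetic import ImageFrame

__all__ = [
    "LabeledSegmentation",
    "BinarizationResult",
    "SingleCellAreaError",
    "normalize_contrast",
    "correct_illumination",
    "denoise",
    "binarize",
    "otsu_threshold_exhaustive",
    "clean_mask",
    "label_components",
    "estimate_single_cell_area",
]

REGION_COLUMNS = [
    "label",
    "area_px",
    "centroid_y",
    "centroid_x",
    "bbox_min_y",
    "bbox_min_x",
    "bbox_max_y",
    "bbox_max_x",
    "eccentricity",
    "skeleton_endpoints",
    "skeleton_branch_points",
    "border_touching",
]


class SingleCellAreaError(RuntimeError):
    """No singlet population could be identified and no prior was supplied."""


@dataclass
class BinarizationResult:
    """Binary mask plus the threshold used and degenerate-input flags."""

    mask: np.ndarray
    threshold: float | None
    polarity: str  # "dark" or "bright" foreground
    empty_foreground: bool = False
    empty_background: bool = False


@dataclass
class LabeledSegmentation:
    """Foreground mask, label map, and the measured region table."""

    foreground_mask: np.ndarray
    label_map: np.ndarray
    regions: pd.DataFrame

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def field_area_px(self) -> int:
        return int(self.foreground_mask.size)


# --------------------------------------------------------------------------
# Intensity conditioning
# --------------------------------------------------------------------------

def normalize_contrast(frame: ImageFrame, low_pct: float = 1.0, high_pct: float = 99.0) -> ImageFrame:
    """Linear contrast stretch clipping at the given intensity percentiles.

    The output spans the full 8-bit range.  A constant image is returned
    unchanged with a warning (there is nothing to stretch).
    """
    if not 0.0 <= low_pct < high_pct <= 100.0:
        raise ValueError("need 0 <= low_pct < high_pct <= 100")
    img = frame.pixels.astype(np.float64)
    lo, hi = np.percentile(img, [low_pct, high_pct])
    if hi <= lo:
        warnings.warn("constant (or near-constant) image: contrast left unchanged")
        return frame
    stretched = np.clip((img - lo) * (255.0 / (hi - lo)), 0.0, 255.0)
    return replace(frame, pixels=np.rint(stretched).astype(np.uint8))


def correct_illumination(frame: ImageFrame, sigma: float = 25.0) -> ImageFrame:
    """Flatten smooth shading by dividing out a heavily blurred background.

    The illumination field is estimated with a Gaussian whose scale is large
    against a cell but small against the field, so multiplicative gradients
    (uneven lamp/condenser alignment) are removed while cells survive.
    """
    img = frame.pixels.astype(np.float64)
    est = ndi.gaussian_filter(img, sigma=sigma, mode="nearest")
    flat = img / np.maximum(est, 1e-6) * 128.0
    return replace(frame, pixels=np.clip(np.rint(flat), 0, 255).astype(np.uint8))


def denoise(frame: ImageFrame, size: int = 3) -> ImageFrame:
    """Median-filter denoising (edge-preserving).

    A median window suppresses additive sensor noise without dragging the
    bright phase-contrast halo into boundary pixels the way linear smoothing
    does, so object areas stay nearly unbiased.  ``size`` ≤ 1 disables.
    """
    if size <= 1:
        return frame
    img = ndi.median_filter(frame.pixels, size=size)
    return replace(frame, pixels=img)


# --------------------------------------------------------------------------
# Binarization
# --------------------------------------------------------------------------

def otsu_threshold_exhaustive(image: np.ndarray) -> int:
    """Otsu's threshold by exhaustive search over all 8-bit cut points.

    Maximizes the between-class variance w₀w₁(μ₀−μ₁)² over thresholds t,
    with classes {v ≤ t} and {v > t}.  Serves as the independent oracle for
    the library Otsu in tests; O(256) per histogram.
    """
    hist = np.bincount(np.asarray(image, dtype=np.uint8).ravel(), minlength=256).astype(np.float64)
    total = hist.sum()
    omega = np.cumsum(hist) / total
    mu = np.cumsum(hist * np.arange(256)) / total
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b = np.nan_to_num(sigma_b, nan=-1.0, posinf=-1.0)
    return int(np.argmax(sigma_b[:-1]))


def binarize(
    frame: ImageFrame,
    method: str = "otsu",
    fixed_threshold: float | None = None,
    polarity: str = "auto",
) -> BinarizationResult:
    """Threshold the image into foreground (RBC material) and background.

    Foreground is the cell side of the threshold.  With ``polarity="auto"``
    the side occupying less than half the pixels is taken as foreground —
    cells are sparse — which is robust to the phase-contrast halo; override
    with ``"dark"`` or ``"bright"``.  A constant image yields an empty mask
    flagged ``empty_foreground``.
    """
    img = frame.pixels
    if method == "fixed":
        if fixed_threshold is None:
            raise ValueError("method='fixed' requires fixed_threshold")
        if not img.min() <= fixed_threshold <= img.max():
            raise ValueError("fixed_threshold outside the image intensity range")
        t = float(fixed_threshold)
    elif method == "otsu":
        if img.min() == img.max():
            mask = np.zeros(img.shape, dtype=bool)
            return BinarizationResult(mask, None, "dark", empty_foreground=True)
        t = float(filters.threshold_otsu(img))
    else:
        raise ValueError(f"unknown threshold method {method!r}")

    dark = img <= t
    if polarity == "dark":
        mask = dark
    elif polarity == "bright":
        mask = ~dark
    elif polarity == "auto":
        mask = dark if dark.mean() < 0.5 else ~dark
    else:
        raise ValueError(f"unknown polarity {polarity!r}")
    pol = "dark" if (mask == dark).all() else "bright"
    return BinarizationResult(
        mask=mask,
        threshold=t,
        polarity=pol,
        empty_foreground=not mask.any(),
        empty_background=bool(mask.all()),
    )


# --------------------------------------------------------------------------
# Mask clean-up
# --------------------------------------------------------------------------

def clean_mask(mask: np.ndarray, min_speck_area_px: int = 50, fill_holes: bool = True) -> np.ndarray:
    """Remove sub-threshold specks and optionally fill interior holes.

    Never adds foreground outside filled holes; idempotent.
    """
    if min_speck_area_px < 0:
        raise ValueError("min_speck_area_px must be >= 0")
    out = np.asarray(mask, dtype=bool)
    if min_speck_area_px > 1:
        # removes components with area < min_speck_area_px (max_size is inclusive)
        out = morphology.remove_small_objects(out, max_size=min_speck_area_px - 1, connectivity=2)
    if fill_holes:
        out = ndi.binary_fill_holes(out)
    return out


# --------------------------------------------------------------------------
# Labeling and morphometry
# --------------------------------------------------------------------------

_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.uint8)


def _skeleton_features(mask: np.ndarray, label_map: np.ndarray, n_labels: int):
    """Per-label skeleton endpoint and branch-point counts.

    The skeleton of the whole mask is computed once; an endpoint is a
    skeleton pixel with exactly one 8-neighbor on the skeleton, a branch
    point a maximal 8-connected cluster of skeleton pixels with three or
    more neighbors (clustering avoids counting one junction several times).
    """
    endpoints = np.zeros(n_labels + 1, dtype=np.int64)
    branches = np.zeros(n_labels + 1, dtype=np.int64)
    if n_labels == 0:
        return endpoints, branches
    skel = morphology.skeletonize(mask)
    if skel.any():
        nb = ndi.convolve(skel.astype(np.uint8), _NEIGHBOR_KERNEL, mode="constant")
        end_px = skel & (nb == 1)
        np.add.at(endpoints, label_map[end_px], 1)
        branch_px = skel & (nb >= 3)
        if branch_px.any():
            clusters, n_clusters = ndi.label(branch_px, structure=np.ones((3, 3)))
            for sl_idx, sl in enumerate(ndi.find_objects(clusters), start=1):
                ys, xs = np.nonzero(clusters[sl] == sl_idx)
                lab = label_map[sl][ys[0], xs[0]]
                branches[lab] += 1
    return endpoints, branches


def label_components(
    mask: np.ndarray, connectivity: int = 8, compute_skeleton: bool = True
) -> LabeledSegmentation:
    """Label maximal connected foreground components and measure them.

    ``connectivity`` is 4 or 8 (pixel adjacency).  The region table carries
    area, centroid, bounding box, eccentricity, border contact, and — when
    ``compute_skeleton`` — skeleton endpoint/branch-point counts for the
    morphology classifier.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    mask = np.asarray(mask, dtype=bool)
    label_map, n_labels = ndi.label(
        mask, structure=ndi.generate_binary_structure(2, 2 if connectivity == 8 else 1)
    )

    if n_labels == 0:
        regions = pd.DataFrame(columns=REGION_COLUMNS)
        return LabeledSegmentation(mask, label_map, regions)

    props = measure.regionprops_table(
        label_map,
        properties=("label", "area", "centroid", "bbox", "eccentricity"),
    )
    h, w = mask.shape
    endpoints, branches = (
        _skeleton_features(mask, label_map, n_labels)
        if compute_skeleton
        else (np.zeros(n_labels + 1, dtype=np.int64),) * 2
    )
    labels = props["label"].astype(int)
    regions = pd.DataFrame(
        {
            "label": labels,
            "area_px": props["area"].astype(int),
            "centroid_y": props["centroid-0"],
            "centroid_x": props["centroid-1"],
            "bbox_min_y": props["bbox-0"].astype(int),
            "bbox_min_x": props["bbox-1"].astype(int),
            "bbox_max_y": props["bbox-2"].astype(int),
            "bbox_max_x": props["bbox-3"].astype(int),
            "eccentricity": props["eccentricity"],
            "skeleton_endpoints": endpoints[labels],
            "skeleton_branch_points": branches[labels],
            "border_touching": (
                (props["bbox-0"] == 0)
                | (props["bbox-1"] == 0)
                | (props["bbox-2"] == h)
                | (props["bbox-3"] == w)
            ),
        }
    )
    return LabeledSegmentation(mask, label_map, regions.sort_values("label").reset_index(drop=True))


# --------------------------------------------------------------------------
# Single-cell area
# --------------------------------------------------------------------------

def estimate_single_cell_area(
    regions: pd.DataFrame, expected_cell_area_px: float | None = None
) -> float:
    """Pixel area of one unaggregated cell, from the singlet population.

    When a prior is supplied it is returned as-is.  Otherwise the singlet
    population is taken to be the smallest tight cluster of region areas:
    unaggregated cells are near-identical in projected area and are the
    smallest objects in the field, whereas even a two-cell clump is ≥ ~1.7×
    larger.  Scanning areas in ascending order, the first area with at least
    three regions within [1, 1.35] × itself anchors the cluster (a lone
    small artifact cannot anchor it), and the estimate is the cluster
    median.  Raises :class:`SingleCellAreaError` when no such population
    exists (too few regions, or only large aggregates) — supply
    ``expected_cell_area_px`` in that case.
    """
    if expected_cell_area_px is not None:
        if expected_cell_area_px <= 0:
            raise ValueError("expected_cell_area_px must be positive")
        return float(expected_cell_area_px)
    if regions is None or len(regions) == 0:
        raise SingleCellAreaError(
            "no regions to estimate from: supply expected_cell_area_px"
        )
    areas = np.sort(regions["area_px"].to_numpy(dtype=float))
    for anchor in areas:
        band = areas[(areas >= anchor) & (areas <= 1.35 * anchor)]
        if len(band) >= 3:
            return float(np.median(band))
    raise SingleCellAreaError(
        "no singlet population found (too few regions, or only large "
        "aggregates): supply expected_cell_area_px"
    )
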