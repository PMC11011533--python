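"""Seeded, ground-truthed synthetic phase-contrast scenes of RBC suspensions.

This module emulates what a microfluidic flow chamber looks like under a
phase-contrast microscope when a dilute (≈2% hematocrit) red-blood-cell
suspension is allowed to aggregate at low shear (8.9 s⁻¹) or is dispersed at
high shear (446 s⁻¹).  Cells are drawn as overlapping-disc unions:

* ``singlet``  — one disc (an unaggregated cell);
* ``rouleau``  — a linear chain of discs with centre spacing 1.2 × radius,
  the projected look of coin-stacked cells;
* ``branched`` — a chain with short side-chains sprouting from it;
* ``network``  — several branched units merged into one connected complex.

Rendering follows phase-contrast polarity: dark cell interiors with a bright
halo rim on a mid-gray background, optionally degraded by a multiplicative
illumination gradient and additive Gaussian noise.  Every scene carries an
exact :class:`SceneGroundTruth` (per-object cell counts, pixel areas,
morphology class, and the true aggregate count NA and area fraction AI), so
the downstream segmentation and metrics stages can be validated pixel-exactly.

All randomness flows through a single :class:`numpy.random.Generator` seeded
from ``SceneSpec.seed``; identical specs produce bit-identical images and
truth on the same platform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi


# --------------------------------------------------------------------------
# Conventions
# --------------------------------------------------------------------------

class ShearCondition(str, Enum):
    """Flow regime of a field of view."""

    LOW = "LOW"    # 8.9 s^-1, aggregation-permissive
    HIGH = "HIGH"  # 446 s^-1, disaggregating


#: Shear rates (s^-1) the two conditions map to.
SHEAR_RATES_PER_S = {ShearCondition.LOW: 8.9, ShearCondition.HIGH: 446.0}

# Phase-contrast gray levels (8-bit) before degradation.
BACKGROUND_LEVEL = 128.0
CELL_LEVEL = 60.0
HALO_LEVEL = 190.0

MORPHOLOGIES = ("singlet", "rouleau", "branched", "network")

#: Disc-centre spacing along a chain, in units of the cell radius.  1.2 gives
#: the stacked-coin projected overlap of rouleaux and keeps the area of each
#: extra cell below one full disc area (~0.77 disc areas per extra cell).
ROULEAU_SPACING = 1.2

#: Incremental union area contributed by each extra disc in a chain at
#: spacing 1.2 r, as a fraction of a full disc area (two-disc lens overlap
#: subtracted; exact for adjacent discs).
_CHAIN_AREA_INCREMENT = 1.0 - (
    2.0 * math.acos(ROULEAU_SPACING / 2.0)
    - (ROULEAU_SPACING / 2.0) * math.sqrt(4.0 - ROULEAU_SPACING**2)
) / math.pi

#: Minimum background gap (pixels) enforced between distinct objects so that
#: connected-component labeling can recover them individually.
OBJECT_GAP_PX = 2


class PlacementError(RuntimeError):
    """Raised when the requested areal density cannot be achieved."""

    def __init__(self, requested: float, achieved: float):
        self.requested = requested
        self.achieved = achieved
        super().__init__(
            f"could not reach areal density {requested:.4f}; "
            f"achieved {achieved:.4f} after bounded placement attempts"
        )


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass
class ImageFrame:
    """One grayscale field of view with provenance metadata."""

    pixels: np.ndarray
    shear_condition: ShearCondition = ShearCondition.LOW
    sample_id: str = ""
    group_label: str = ""

    @property
    def height_px(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width_px(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def field_area_px(self) -> int:
        return self.height_px * self.width_px


@dataclass
class SceneObject:
    """Ground truth for one placed object (a cell or an aggregate)."""

    object_id: int
    cell_count: int
    pixel_area: int
    morphology_class: str
    border_touching: bool
    #: disc centres (row, col) in field coordinates; kept so high-shear
    #: re-rendering can preserve survivor geometry exactly.
    discs: list = field(default_factory=list, repr=False)


@dataclass
class SceneGroundTruth:
    """Exact per-scene truth against which measurements are validated."""

    objects: list
    field_area_px: int
    min_cells: int = 3

    @property
    def aggregates(self) -> list:
        return [o for o in self.objects if o.cell_count >= self.min_cells]

    @property
    def true_NA(self) -> int:
        """Number of objects meeting the ≥ min_cells aggregate criterion."""
        return len(self.aggregates)

    @property
    def true_AI(self) -> float:
        """Fraction of the field covered by aggregate pixels."""
        return sum(o.pixel_area for o in self.aggregates) / self.field_area_px

    @property
    def total_cells(self) -> int:
        return sum(o.cell_count for o in self.objects)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "object_id": o.object_id,
                    "cell_count": o.cell_count,
                    "pixel_area": o.pixel_area,
                    "class": o.morphology_class,
                    "border_touching": o.border_touching,
                }
                for o in self.objects
            ],
            columns=["object_id", "cell_count", "pixel_area", "class", "border_touching"],
        )


@dataclass
class SceneSpec:
    """Parameters of one synthetic field of view.

    ``areal_density`` is the fraction of the field covered by cell pixels and
    acts as the proxy for the 2% imaging hematocrit; the generator places
    objects until the truth-mask coverage is within ±10% (relative) of it.
    ``aggregate_stability`` is the probability that an aggregate survives the
    switch to high shear (see :func:`apply_high_shear`).
    """

    field_width_px: int = 1600
    field_height_px: int = 300
    cell_radius_px: float = 8.0
    areal_density: float = 0.10
    morphology_weights: dict = field(
        default_factory=lambda: {
            "singlet": 0.35, "rouleau": 0.50, "branched": 0.12, "network": 0.03,
        }
    )
    rouleau_length_range: tuple = (3, 7)
    branch_probability: float = 0.25
    network_merge_probability: float = 0.5
    aggregate_stability: float = 0.06
    noise_sd: float = 0.0
    illumination_gradient: float = 0.0
    shear_condition: ShearCondition = ShearCondition.LOW
    seed: int = 0
    #: when set, place exactly this many objects and ignore areal_density.
    n_objects: int | None = None
    #: aggregate criterion used for the truth NA / AI.
    min_cells: int = 3
    #: allow objects to be clipped at the field edge (flagged border-touching).
    #: Off by default so truth cell counts always refer to fully visible
    #: objects and the area criterion can be validated pixel-exactly.
    allow_border: bool = False
    #: physical calibration convention (50 µm scale bar vs. ~8 px cell radius).
    um_per_px: float = 0.44

    def validate(self) -> None:
        if self.field_width_px <= 0 or self.field_height_px <= 0:
            raise ValueError("field dimensions must be positive")
        if self.cell_radius_px <= 0:
            raise ValueError("cell_radius_px must be positive")
        if not 0.0 <= self.areal_density <= 0.35:
            raise ValueError("areal_density must lie in [0, 0.35]")
        w = self.morphology_weights
        if set(w) != set(MORPHOLOGIES):
            raise ValueError(f"morphology_weights must cover {MORPHOLOGIES}")
        if any(v < 0 for v in w.values()):
            raise ValueError("morphology_weights must be nonnegative")
        if abs(sum(w.values()) - 1.0) > 1e-9:
            raise ValueError("morphology_weights must sum to 1 within 1e-9")
        lo, hi = self.rouleau_length_range
        if not (1 <= lo <= hi):
            raise ValueError("rouleau_length_range must be an increasing pair >= 1")
        for name in ("branch_probability", "network_merge_probability", "aggregate_stability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0.0 <= self.illumination_gradient <= 0.5:
            raise ValueError("illumination_gradient must lie in [0, 0.5]")
        if self.min_cells < 1:
            raise ValueError("min_cells must be >= 1")


# --------------------------------------------------------------------------
# Object geometry
# --------------------------------------------------------------------------

def _chain_centers(rng: np.random.Generator, n: int, radius: float) -> list:
    """Centres of a nearly straight chain of n discs (jittered heading)."""
    theta = rng.uniform(0.0, 2.0 * math.pi)
    step = ROULEAU_SPACING * radius
    pts = [(0.0, 0.0)]
    for _ in range(n - 1):
        theta += rng.uniform(-0.25, 0.25)
        y, x = pts[-1]
        pts.append((y + step * math.sin(theta), x + step * math.cos(theta)))
    return pts


def _branched_centers(rng: np.random.Generator, spec: SceneSpec) -> list:
    """A main chain with side-chains sprouting at branch_probability per cell."""
    lo, hi = spec.rouleau_length_range
    k_main = int(rng.integers(max(lo, 4), hi + 1))
    r = spec.cell_radius_px
    step = ROULEAU_SPACING * r
    main = _chain_centers(rng, k_main, r)
    pts = list(main)
    for i in range(1, k_main - 1):
        if rng.random() < spec.branch_probability:
            # sprout roughly perpendicular to the local chain direction
            dy = main[i + 1][0] - main[i - 1][0]
            dx = main[i + 1][1] - main[i - 1][1]
            base = math.atan2(dy, dx)
            side = base + rng.choice([-1.0, 1.0]) * rng.uniform(math.pi / 3, 2 * math.pi / 3)
            y, x = main[i]
            for _ in range(int(rng.integers(1, 4))):
                y, x = y + step * math.sin(side), x + step * math.cos(side)
                pts.append((y, x))
                side += rng.uniform(-0.25, 0.25)
    return pts


def _network_centers(rng: np.random.Generator, spec: SceneSpec) -> list:
    """Several branched units merged into one connected complex."""
    pts = _branched_centers(rng, spec)
    n_units = 1
    step = ROULEAU_SPACING * spec.cell_radius_px
    while n_units < 4 and (n_units < 2 or rng.random() < spec.network_merge_probability):
        anchor = pts[int(rng.integers(len(pts)))]
        unit = _branched_centers(rng, spec)
        theta = rng.uniform(0.0, 2.0 * math.pi)
        oy = anchor[0] + step * math.sin(theta)
        ox = anchor[1] + step * math.cos(theta)
        pts.extend((oy + y, ox + x) for y, x in unit)
        n_units += 1
    return pts


def _make_object_centers(rng: np.random.Generator, morphology: str, spec: SceneSpec) -> list:
    if morphology == "singlet":
        return [(0.0, 0.0)]
    if morphology == "rouleau":
        lo, hi = spec.rouleau_length_range
        return _chain_centers(rng, int(rng.integers(lo, hi + 1)), spec.cell_radius_px)
    if morphology == "branched":
        return _branched_centers(rng, spec)
    if morphology == "network":
        return _network_centers(rng, spec)
    raise ValueError(f"unknown morphology {morphology!r}")


def rasterize_discs(discs: Sequence, radius: float, height: int, width: int):
    """Rasterize a union of discs clipped to the field.

    Returns ``(local_mask, y0, x0, border_touching)`` where ``local_mask`` is
    the boolean union over its bounding box, ``(y0, x0)`` its offset in field
    coordinates, and ``border_touching`` is True when the union's geometric
    extent crosses the field boundary (the raster is clipped); ``None`` if
    the union lies wholly outside the field.  A pixel belongs to a disc when
    its centre lies within ``radius``.
    """
    ys = [c[0] for c in discs]
    xs = [c[1] for c in discs]
    y0 = max(0, int(math.floor(min(ys) - radius)))
    y1 = min(height, int(math.ceil(max(ys) + radius)) + 1)
    x0 = max(0, int(math.floor(min(xs) - radius)))
    x1 = min(width, int(math.ceil(max(xs) + radius)) + 1)
    if y0 >= y1 or x0 >= x1:
        return None
    yy, xx = np.mgrid[y0:y1, x0:x1]
    yy = yy + 0.5  # pixel-centre sampling
    xx = xx + 0.5
    mask = np.zeros((y1 - y0, x1 - x0), dtype=bool)
    r2 = radius * radius
    for cy, cx in discs:
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r2
    if not mask.any():
        return None
    clipped = (
        min(ys) - radius < 0
        or max(ys) + radius > height
        or min(xs) - radius < 0
        or max(xs) + radius > width
    )
    return mask, y0, x0, bool(clipped)


def expected_object_area(morphology: str, spec: SceneSpec) -> float:
    """Approximate expected union area (px²) of one object of this class."""
    a1 = math.pi * spec.cell_radius_px**2
    lo, hi = spec.rouleau_length_range
    mean_k = (lo + hi) / 2.0
    if morphology == "singlet":
        return a1
    if morphology == "rouleau":
        return a1 * (1.0 + _CHAIN_AREA_INCREMENT * (mean_k - 1.0))
    # branched: main chain plus expected sprout cells
    k_main = (max(lo, 4) + hi) / 2.0
    sprouts = max(k_main - 2.0, 0.0) * spec.branch_probability * 2.0
    branched = a1 * (1.0 + _CHAIN_AREA_INCREMENT * (k_main + sprouts - 1.0))
    if morphology == "branched":
        return branched
    # network: geometric number of merged units, capped at 4
    p = spec.network_merge_probability
    mean_units = min(2.0 + p / max(1.0 - p, 0.25), 4.0)
    return branched * mean_units


# --------------------------------------------------------------------------
# Scene generation
# --------------------------------------------------------------------------

_DILATE_STRUCT = ndi.generate_binary_structure(2, 2)


def _try_place(
    rng: np.random.Generator,
    centers: Sequence,
    spec: SceneSpec,
    truth_mask: np.ndarray,
    forbidden: np.ndarray,
    max_attempts: int = 200,
):
    """Attempt to drop an object at a random location with a clear gap.

    Returns ``(pixel_area, border_touching, shifted_centers)`` on success or
    ``None`` when no collision-free position was found.
    """
    h, w = truth_mask.shape
    cy0 = float(np.mean([c[0] for c in centers]))
    cx0 = float(np.mean([c[1] for c in centers]))
    for _ in range(max_attempts):
        ty = rng.uniform(0, h)
        tx = rng.uniform(0, w)
        shifted = [(y - cy0 + ty, x - cx0 + tx) for y, x in centers]
        ras = rasterize_discs(shifted, spec.cell_radius_px, h, w)
        if ras is None:
            continue
        mask, y0, x0, border = ras
        if border and not spec.allow_border:
            continue
        sl = (slice(y0, y0 + mask.shape[0]), slice(x0, x0 + mask.shape[1]))
        if np.any(forbidden[sl] & mask):
            continue
        truth_mask[sl] |= mask
        # grow the forbidden zone by the inter-object gap around this object
        pad = OBJECT_GAP_PX
        py0, px0 = max(0, y0 - pad), max(0, x0 - pad)
        py1 = min(h, y0 + mask.shape[0] + pad)
        px1 = min(w, x0 + mask.shape[1] + pad)
        padded = np.zeros((py1 - py0, px1 - px0), dtype=bool)
        padded[y0 - py0 : y0 - py0 + mask.shape[0], x0 - px0 : x0 - px0 + mask.shape[1]] = mask
        grown = ndi.binary_dilation(padded, _DILATE_STRUCT, iterations=pad)
        forbidden[py0:py1, px0:px1] |= grown
        return int(mask.sum()), border, shifted
    return None


def _render(truth_mask: np.ndarray, spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Render the truth mask with phase-contrast polarity and degradations."""
    img = np.full(truth_mask.shape, BACKGROUND_LEVEL, dtype=np.float64)
    img[truth_mask] = CELL_LEVEL
    halo = ndi.binary_dilation(truth_mask, _DILATE_STRUCT) & ~truth_mask
    img[halo] = HALO_LEVEL
    if spec.illumination_gradient > 0:
        w = truth_mask.shape[1]
        x = np.arange(w, dtype=np.float64)
        gain = 1.0 + spec.illumination_gradient * (2.0 * x / max(w - 1, 1) - 1.0)
        img = img * gain[np.newaxis, :]
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_scene(spec: SceneSpec) -> tuple[ImageFrame, SceneGroundTruth]:
    """Generate one field of view and its exact ground truth.

    Objects are sampled from ``morphology_weights`` and placed uniformly at
    random with a minimum background gap between them, until the truth-mask
    coverage reaches ``areal_density`` (±10% relative) — or exactly
    ``n_objects`` objects when that override is set.

    Raises :class:`PlacementError` when the density cannot be achieved after
    bounded attempts.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.field_height_px, spec.field_width_px
    truth_mask = np.zeros((h, w), dtype=bool)
    forbidden = np.zeros((h, w), dtype=bool)
    objects: list[SceneObject] = []

    names = list(spec.morphology_weights)
    weights = np.array([spec.morphology_weights[n] for n in names], dtype=float)
    weights = weights / weights.sum()

    def place_one(morph: str) -> bool:
        centers = _make_object_centers(rng, morph, spec)
        placed = _try_place(rng, centers, spec, truth_mask, forbidden)
        if placed is None:
            return False
        area, border, shifted = placed
        objects.append(
            SceneObject(
                object_id=len(objects) + 1,
                cell_count=len(shifted),
                pixel_area=area,
                morphology_class=morph,
                border_touching=border,
                discs=shifted,
            )
        )
        return True

    def undo_last() -> None:
        # remove the object's pixels; the forbidden zone is left marked,
        # which only (conservatively) wastes a little placement room
        obj = objects.pop()
        ras = rasterize_discs(obj.discs, spec.cell_radius_px, h, w)
        if ras is not None:
            m, y0, x0, _ = ras
            truth_mask[y0 : y0 + m.shape[0], x0 : x0 + m.shape[1]] &= ~m

    if spec.n_objects is not None:
        for _ in range(spec.n_objects):
            morph = str(rng.choice(names, p=weights))
            if not place_one(morph):
                raise PlacementError(spec.areal_density, truth_mask.mean())
    else:
        target = spec.areal_density * h * w
        placed_area = 0.0
        max_objects = 20000
        # when a large object cannot be fitted (crowded or small field), retry
        # with the next smaller morphology before giving up on the density
        fallback = {"network": "branched", "branched": "rouleau", "rouleau": "singlet", "singlet": None}
        retries = 0
        while placed_area < target and len(objects) < max_objects:
            morph = str(rng.choice(names, p=weights))
            # near the target, downgrade to a smaller class rather than
            # overshoot; stop at the nearest achievable coverage
            while morph is not None:
                est = expected_object_area(morph, spec)
                if placed_area + est <= target or (placed_area + est - target) <= (target - placed_area):
                    break
                morph = fallback[morph]
            if morph is None:
                break  # even a singlet would overshoot: target is matched
            before = len(objects)
            while morph is not None and not place_one(morph):
                morph = fallback[morph]
            if morph is None:
                if placed_area >= 0.9 * target:
                    break
                raise PlacementError(spec.areal_density, placed_area / (h * w))
            new_area = placed_area + objects[before].pixel_area
            # drop an object whose true union overshoots the density band
            # (class estimates are approximate) or lands farther from the
            # target than staying; smaller objects then fill the remainder
            if new_area > 1.08 * target or (
                new_area > target and (new_area - target) > (target - placed_area)
            ):
                undo_last()
                retries += 1
                if retries > 400:
                    break
                continue
            placed_area = new_area

        if target > 0:
            achieved = truth_mask.sum() / (h * w)
            if abs(achieved - spec.areal_density) > 0.10 * spec.areal_density:
                raise PlacementError(spec.areal_density, achieved)

    frame = ImageFrame(
        pixels=_render(truth_mask, spec, rng),
        shear_condition=spec.shear_condition,
    )
    truth = SceneGroundTruth(objects=objects, field_area_px=h * w, min_cells=spec.min_cells)
    return frame, truth


def truth_mask_from(truth: SceneGroundTruth, spec: SceneSpec) -> np.ndarray:
    """Re-rasterize the scene's truth mask from the stored disc layout."""
    h, w = spec.field_height_px, spec.field_width_px
    mask = np.zeros((h, w), dtype=bool)
    for obj in truth.objects:
        ras = rasterize_discs(obj.discs, spec.cell_radius_px, h, w)
        if ras is not None:
            m, y0, x0, _ = ras
            mask[y0 : y0 + m.shape[0], x0 : x0 + m.shape[1]] |= m
    return mask


# --------------------------------------------------------------------------
# High-shear dispersal
# --------------------------------------------------------------------------

def apply_high_shear(
    truth: SceneGroundTruth, spec: SceneSpec
) -> tuple[ImageFrame, SceneGroundTruth]:
    """Simulate the switch from low to high shear (8.9 → 446 s⁻¹).

    Each aggregate independently survives with probability
    ``spec.aggregate_stability``, keeping its exact geometry; dispersed
    aggregates are replaced by their constituent cells re-placed as
    non-touching singlets.  Total cell count is conserved.  The survival
    draws use a seed derived from ``spec.seed`` so the low/high pair is
    reproducible as a unit.
    """
    spec.validate()
    rng = np.random.default_rng((int(spec.seed) * 2654435761 + 0x9E3779B1) % 2**31)
    h, w = spec.field_height_px, spec.field_width_px
    truth_mask = np.zeros((h, w), dtype=bool)
    forbidden = np.zeros((h, w), dtype=bool)
    new_objects: list[SceneObject] = []
    dispersed_cells = 0

    keep: list[SceneObject] = []
    for obj in truth.objects:
        if obj.cell_count >= truth.min_cells:
            if rng.random() < spec.aggregate_stability:
                keep.append(obj)
            else:
                dispersed_cells += obj.cell_count
        else:
            keep.append(obj)

    for obj in keep:
        ras = rasterize_discs(obj.discs, spec.cell_radius_px, h, w)
        if ras is None:
            continue
        mask, y0, x0, border = ras
        sl = (slice(y0, y0 + mask.shape[0]), slice(x0, x0 + mask.shape[1]))
        truth_mask[sl] |= mask
        pad = OBJECT_GAP_PX
        py0, px0 = max(0, y0 - pad), max(0, x0 - pad)
        py1 = min(h, y0 + mask.shape[0] + pad)
        px1 = min(w, x0 + mask.shape[1] + pad)
        padded = np.zeros((py1 - py0, px1 - px0), dtype=bool)
        padded[y0 - py0 : y0 - py0 + mask.shape[0], x0 - px0 : x0 - px0 + mask.shape[1]] = mask
        forbidden[py0:py1, px0:px1] |= ndi.binary_dilation(padded, _DILATE_STRUCT, iterations=pad)
        new_objects.append(
            SceneObject(
                object_id=len(new_objects) + 1,
                cell_count=obj.cell_count,
                pixel_area=int(mask.sum()),
                morphology_class=obj.morphology_class,
                border_touching=border,
                discs=list(obj.discs),
            )
        )

    for _ in range(dispersed_cells):
        placed = _try_place(rng, [(0.0, 0.0)], spec, truth_mask, forbidden)
        if placed is None:
            raise PlacementError(spec.areal_density, truth_mask.mean())
        area, border, shifted = placed
        new_objects.append(
            SceneObject(
                object_id=len(new_objects) + 1,
                cell_count=1,
                pixel_area=area,
                morphology_class="singlet",
                border_touching=border,
                discs=shifted,
            )
        )

    frame = ImageFrame(pixels=_render(truth_mask, spec, rng), shear_condition=ShearCondition.HIGH)
    new_truth = SceneGroundTruth(
        objects=new_objects, field_area_px=h * w, min_cells=truth.min_cells
    )
    return frame, new_truth


# --------------------------------------------------------------------------
# Group datasets
# --------------------------------------------------------------------------

@dataclass
class GroupProfile:
    """One clinical-group recipe for dataset generation."""

    label: str
    template: SceneSpec
    n_samples: int
    images_per_sample: int = 5
    #: optional patient-like heterogeneity of the per-sample density target
    #: (lognormal coefficient of variation); 0 means samples differ only
    #: through their derived seeds.
    between_sample_cv: float = 0.0
    include_high_shear: bool = True


def aggregate_area_share(spec: SceneSpec) -> float:
    """Expected fraction of placed cell area that belongs to aggregates."""
    total = 0.0
    agg = 0.0
    for name, wgt in spec.morphology_weights.items():
        a = expected_object_area(name, spec) * wgt
        total += a
        if name != "singlet":
            agg += a
    return agg / total if total > 0 else 0.0


def density_for_target_ai(spec: SceneSpec, target_ai: float) -> float:
    """Areal density whose expected aggregate coverage equals ``target_ai``."""
    share = aggregate_area_share(spec)
    if share <= 0:
        raise ValueError("morphology_weights place no aggregates")
    return target_ai / share


def control_profile(**overrides) -> GroupProfile:
    """Healthy pregnant controls: rouleau-dominated, AI_L target ≈ 0.085."""
    spec = SceneSpec(
        morphology_weights={"singlet": 0.45, "rouleau": 0.42, "branched": 0.11, "network": 0.02},
        aggregate_stability=0.06,
        noise_sd=10.0,
        illumination_gradient=0.1,
    )
    spec = replace(spec, areal_density=density_for_target_ai(spec, 0.085))
    prof = GroupProfile(label="control", template=spec, n_samples=8)
    return replace(prof, **overrides)


def non_severe_pe_profile(**overrides) -> GroupProfile:
    """Non-severe preeclampsia: larger branched aggregates, AI_L ≈ 0.107."""
    spec = SceneSpec(
        morphology_weights={"singlet": 0.45, "rouleau": 0.30, "branched": 0.20, "network": 0.05},
        aggregate_stability=0.056,
        noise_sd=10.0,
        illumination_gradient=0.1,
    )
    spec = replace(spec, areal_density=density_for_target_ai(spec, 0.107))
    prof = GroupProfile(label="non_severe_pe", template=spec, n_samples=7)
    return replace(prof, **overrides)


def severe_pe_profile(**overrides) -> GroupProfile:
    """Severe preeclampsia: branched networks, AI_L target ≈ 0.149."""
    spec = SceneSpec(
        morphology_weights={"singlet": 0.50, "rouleau": 0.12, "branched": 0.20, "network": 0.18},
        aggregate_stability=0.074,
        noise_sd=10.0,
        illumination_gradient=0.1,
    )
    spec = replace(spec, areal_density=density_for_target_ai(spec, 0.149))
    prof = GroupProfile(label="severe_pe", template=spec, n_samples=6)
    return replace(prof, **overrides)


def derive_seed(master_seed: int, counter: int) -> int:
    """Deterministic per-image seed: ``(master * 1_000_003 + counter) mod 2³¹−1``."""
    return (int(master_seed) * 1_000_003 + int(counter)) % 2_147_483_647


def generate_sample_frames(
    template: SceneSpec,
    n_images: int,
    master_seed: int,
    counter_start: int,
    include_high_shear: bool = True,
):
    """Generate one sample's low-shear (and paired high-shear) frames in memory.

    Yields ``(frame, truth, spec)`` tuples; the high-shear frame of a pair
    shares the low-shear frame's spec (and thus its derived seed).
    """
    out = []
    for i in range(n_images):
        spec = replace(
            template,
            seed=derive_seed(master_seed, counter_start + i),
            shear_condition=ShearCondition.LOW,
        )
        frame, truth = generate_scene(spec)
        out.append((frame, truth, spec))
        if include_high_shear:
            hframe, htruth = apply_high_shear(truth, spec)
            out.append((hframe, htruth, spec))
    return out


def generate_group_dataset(
    group_profiles: Sequence[GroupProfile],
    out_dir: str | Path,
    seed: int,
) -> pd.DataFrame:
    """Write a ground-truthed multi-group image dataset to disk.

    Layout: ``images/*.tif`` (8-bit grayscale TIFF), ``truth/*.csv`` sidecars
    (``object_id,cell_count,pixel_area,class,border_touching``), and a
    ``manifest.csv`` with header ``sample_id,group,shear,path,seed``.  The
    manifest is committed last, so a failure never leaves a partial manifest.
    Per-image seeds follow :func:`derive_seed` with a global image counter.
    """
    out_dir = Path(out_dir)
    try:
        (out_dir / "images").mkdir(parents=True, exist_ok=True)
        (out_dir / "truth").mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}") from exc

    rows = []
    counter = 0
    sample_rng = np.random.default_rng(derive_seed(seed, 0))
    for prof in group_profiles:
        if prof.n_samples < 1 or prof.images_per_sample < 1:
            raise ValueError("n_samples and images_per_sample must be >= 1")
        for s in range(prof.n_samples):
            sample_id = f"{prof.label}_{s + 1:02d}"
            template = prof.template
            if prof.between_sample_cv > 0:
                sigma = math.sqrt(math.log(1.0 + prof.between_sample_cv**2))
                factor = float(sample_rng.lognormal(-0.5 * sigma**2, sigma))
                template = replace(
                    template,
                    areal_density=min(template.areal_density * factor, 0.35),
                )
            for i in range(prof.images_per_sample):
                img_seed = derive_seed(seed, counter)
                counter += 1
                spec = replace(template, seed=img_seed, shear_condition=ShearCondition.LOW)
                frame, truth = generate_scene(spec)
                pairs = [(frame, truth, ShearCondition.LOW)]
                if prof.include_high_shear:
                    hframe, htruth = apply_high_shear(truth, spec)
                    pairs.append((hframe, htruth, ShearCondition.HIGH))
                for fr, tr, shear in pairs:
                    stem = f"{sample_id}_{shear.value}_{i + 1:02d}"
                    rel = f"images/{stem}.tif"
                    tifffile.imwrite(out_dir / rel, fr.pixels)
                    tr.to_frame().to_csv(out_dir / "truth" / f"{stem}.csv", index=False)
                    rows.append(
                        {
                            "sample_id": sample_id,
                            "group": prof.label,
                            "shear": shear.value,
                            "path": rel,
                            "seed": img_seed,
                        }
                    )

    manifest = pd.DataFrame(rows, columns=["sample_id", "group", "shear", "path", "seed"])
    tmp = out_dir / "manifest.csv.tmp"
    manifest.to_csv(tmp, index=False)
    tmp.replace(out_dir / "manifest.csv")
    return manifest
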