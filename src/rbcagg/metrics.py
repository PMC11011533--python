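"""Aggregate selection, aggregation indices, and per-sample summaries.

The aggregate criterion is a minimum of three clumped cells.  Because the
measurement is a projected pixel area, the cell-count criterion is converted
to an area threshold through a packing factor: stacked cells overlap in
projection, so a three-cell rouleau covers only ≈ 2.43 singlet areas at the
generator's chain spacing of 1.2 radii.  The default packing factor 0.75
turns "≥ 3 cells" into "area ≥ 3 × single-cell area × 0.75" — safely below
every three-cell union (≥ ~2.43 areas) and safely above every two-cell
union (≤ ~1.72 areas).

The aggregation index of one field is AI = S_agg / S1, where S1 is the total
field area in pixels and S_agg is the summed pixel area of the selected
aggregates — S2 at low shear (AI_L) and S3 at high shear (AI_H).  NA is the
number of selected aggregates.  Per-sample values are the mean ± SD over
that sample's fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .segmentation import LabeledSegmentation
from .synthetic import ShearCondition

__all__ = [
    "AggregateRecord",
    "AggregationIndices",
    "SampleSummary",
    "StabilityReport",
    "aggregate_area_threshold",
    "select_aggregates",
    "selection_flips",
    "refine_selection",
    "compute_indices",
    "classify_morphology",
    "summarize_sample",
]


@dataclass
class AggregateRecord:
    """One region retained by the aggregate criterion."""

    label: int
    area_px: int
    cell_count_est: float
    morphology_class: str = "unclassified"
    border_touching: bool = False


@dataclass
class AggregationIndices:
    """Per-image aggregation measurement at one shear condition."""

    shear_condition: ShearCondition
    S1_px: int          # total field area
    S_agg_px: int       # S2 at low shear, S3 at high shear
    AI: float
    NA: int


@dataclass
class SampleSummary:
    """Mean ± SD of AI and NA over one sample's fields at one shear."""

    sample_id: str
    group_label: str
    shear_condition: ShearCondition
    mean_AI: float
    sd_AI: float
    mean_NA: float
    sd_NA: float
    n_images: int
    single_image: bool = False


@dataclass
class StabilityReport:
    """Outcome of the threshold-perturbation stability check."""

    stable: bool
    passes: int
    perturbation: float
    flipped_labels: list = field(default_factory=list)
    selected_at_low: list = field(default_factory=list)
    selected_at_high: list = field(default_factory=list)


def aggregate_area_threshold(
    single_cell_area_px: float, min_cells: int = 3, packing_factor: float = 0.75
) -> float:
    """Area threshold equivalent to the ≥ min_cells clumped-cell criterion."""
    if single_cell_area_px <= 0:
        raise ValueError("single_cell_area_px must be positive")
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    if not 0.0 < packing_factor <= 1.0:
        raise ValueError("packing_factor must lie in (0, 1]")
    return min_cells * single_cell_area_px * packing_factor


def classify_morphology(endpoints: int, branch_points: int, area_px: int) -> str:
    """Classify an aggregate's shape from its skeleton topology.

    Rouleaux are unbranched chains (≤ 2 skeleton endpoints, no branch
    points); 1–3 branch points marks a branched aggregate; more than 3, an
    interconnected network.  Degenerate regions are left unclassified.
    """
    if area_px < 4:
        return "unclassified"
    if branch_points == 0 and endpoints <= 2:
        return "rouleau"
    if 1 <= branch_points <= 3:
        return "branched"
    if branch_points > 3:
        return "network"
    return "unclassified"


def select_aggregates(
    segmentation: LabeledSegmentation,
    single_cell_area_px: float,
    min_cells: int = 3,
    packing_factor: float = 0.75,
    include_border: bool = True,
    classify: bool = True,
) -> list:
    """Retain regions meeting the aggregate criterion, ordered by label.

    A region is an aggregate iff its area is at least
    ``min_cells × single_cell_area_px × packing_factor`` (boundary
    inclusive).  ``cell_count_est = area / (single_cell_area × packing)``.
    """
    thr = aggregate_area_threshold(single_cell_area_px, min_cells, packing_factor)
    records = []
    for row in segmentation.regions.itertuples(index=False):
        if not include_border and row.border_touching:
            continue
        if row.area_px + 1e-9 >= thr:
            records.append(
                AggregateRecord(
                    label=int(row.label),
                    area_px=int(row.area_px),
                    cell_count_est=row.area_px / (single_cell_area_px * packing_factor),
                    morphology_class=(
                        classify_morphology(
                            int(row.skeleton_endpoints),
                            int(row.skeleton_branch_points),
                            int(row.area_px),
                        )
                        if classify
                        else "unclassified"
                    ),
                    border_touching=bool(row.border_touching),
                )
            )
    records.sort(key=lambda r: r.label)
    return records


def _labels_at_threshold(segmentation, thr, include_border=True):
    sel = set()
    for row in segmentation.regions.itertuples(index=False):
        if not include_border and row.border_touching:
            continue
        if row.area_px + 1e-9 >= thr:
            sel.add(int(row.label))
    return sel


def selection_flips(
    segmentation: LabeledSegmentation,
    single_cell_area_px: float,
    min_cells: int = 3,
    packing_factor: float = 0.75,
    perturbation: float = 0.05,
    include_border: bool = True,
) -> set:
    """Labels whose aggregate status flips when the area cutoff moves ±perturbation."""
    thr = aggregate_area_threshold(single_cell_area_px, min_cells, packing_factor)
    low = _labels_at_threshold(segmentation, thr * (1.0 - perturbation), include_border)
    high = _labels_at_threshold(segmentation, thr * (1.0 + perturbation), include_border)
    return low - high


def refine_selection(
    segmentation: LabeledSegmentation,
    single_cell_area_px: float,
    min_cells: int = 3,
    packing_factor: float = 0.75,
    threshold_perturbation: float = 0.05,
    include_border: bool = True,
    max_passes: int = 3,
    classify: bool = True,
) -> tuple:
    """Verify the selection is stable against small threshold perturbations.

    The selection is recomputed at threshold × (1 ± p).  If any region flips
    status, the check is repeated with the perturbation halved, up to
    ``max_passes`` passes; a selection that never stabilizes is flagged for
    review with both candidate label sets, rather than looping forever.
    Returns ``(records, StabilityReport)`` — records are always evaluated at
    the nominal threshold.
    """
    if threshold_perturbation < 0:
        raise ValueError("threshold_perturbation must be >= 0")
    records = select_aggregates(
        segmentation, single_cell_area_px, min_cells, packing_factor, include_border, classify
    )
    thr = aggregate_area_threshold(single_cell_area_px, min_cells, packing_factor)
    p = threshold_perturbation
    flips: set = set()
    passes = 0
    for passes in range(1, max_passes + 1):
        flips = selection_flips(
            segmentation, single_cell_area_px, min_cells, packing_factor, p, include_border
        )
        if not flips:
            break
        p /= 2.0
    report = StabilityReport(
        stable=not flips,
        passes=passes,
        perturbation=threshold_perturbation,
        flipped_labels=sorted(flips),
        selected_at_low=sorted(
            _labels_at_threshold(segmentation, thr * (1 - threshold_perturbation), include_border)
        ),
        selected_at_high=sorted(
            _labels_at_threshold(segmentation, thr * (1 + threshold_perturbation), include_border)
        ),
    )
    return records, report


def compute_indices(
    records: list, field_area_px: int, shear_condition: ShearCondition
) -> AggregationIndices:
    """AI = S_agg / S1 and NA = number of aggregates for one field."""
    if field_area_px <= 0:
        raise ValueError("field_area_px must be positive")
    s_agg = int(sum(r.area_px for r in records))
    return AggregationIndices(
        shear_condition=ShearCondition(shear_condition),
        S1_px=int(field_area_px),
        S_agg_px=s_agg,
        AI=s_agg / field_area_px,
        NA=len(records),
    )


def summarize_sample(
    per_image_indices: list, sample_id: str, group_label: str
) -> SampleSummary:
    """Mean and sample SD (n−1) of AI and NA over one sample's fields.

    All fields must share the shear condition.  A single field yields
    SD = 0 with the ``single_image`` flag set.
    """
    if not per_image_indices:
        raise ValueError("need at least one image's indices")
    shears = {ix.shear_condition for ix in per_image_indices}
    if len(shears) != 1:
        raise ValueError(f"mixed shear conditions in one summary: {sorted(s.value for s in shears)}")
    ai = np.array([ix.AI for ix in per_image_indices], dtype=float)
    na = np.array([ix.NA for ix in per_image_indices], dtype=float)
    n = len(ai)
    return SampleSummary(
        sample_id=sample_id,
        group_label=group_label,
        shear_condition=shears.pop(),
        mean_AI=float(ai.mean()),
        sd_AI=float(ai.std(ddof=1)) if n > 1 else 0.0,
        mean_NA=float(na.mean()),
        sd_NA=float(na.std(ddof=1)) if n > 1 else 0.0,
        n_images=n,
        single_image=(n == 1),
    )
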