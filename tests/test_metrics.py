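"""Aggregate criterion, indices, morphology classes and sample summaries."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from rbcagg import (
    AggregationIndices,
    SceneSpec,
    ShearCondition,
    analyze_frame,
    compute_indices,
    generate_scene,
    label_components,
    refine_selection,
    select_aggregates,
    selection_flips,
    summarize_sample,
)
from rbcagg.metrics import classify_morphology
from rbcagg.segmentation import LabeledSegmentation


def _fake_segmentation(areas, border=None):
    """A minimal LabeledSegmentation carrying only what selection needs."""
    n = len(areas)
    regions = pd.DataFrame(
        {
            "label": np.arange(1, n + 1),
            "area_px": np.asarray(areas, dtype=int),
            "skeleton_endpoints": np.zeros(n, dtype=int),
            "skeleton_branch_points": np.zeros(n, dtype=int),
            "border_touching": border if border is not None else np.zeros(n, bool),
        }
    )
    return LabeledSegmentation(
        foreground_mask=np.zeros((1, 1), bool), label_map=np.zeros((1, 1), int), regions=regions
    )


class TestSelectAggregates:
    def test_boundary_is_inclusive_at_three_cell_areas(self):
        """With packing 1, area 2.9× cell area is out and 3.0× is in."""
        seg = _fake_segmentation([290, 300])
        records = select_aggregates(seg, single_cell_area_px=100, min_cells=3, packing_factor=1.0)
        assert [r.label for r in records] == [2]
        assert records[0].cell_count_est == pytest.approx(3.0)

    def test_truth_aggregate_count_recovered(self, small_scene, pixel_exact_config):
        frame, truth = small_scene
        fa = analyze_frame(frame, pixel_exact_config)
        assert fa.indices.NA == truth.true_NA

    def test_border_exclusion_switch(self):
        seg = _fake_segmentation([400, 400], border=np.array([True, False]))
        assert len(select_aggregates(seg, 100, include_border=True)) == 2
        assert len(select_aggregates(seg, 100, include_border=False)) == 1

    def test_nonpositive_cell_area_rejected(self):
        with pytest.raises(ValueError):
            select_aggregates(_fake_segmentation([100]), 0.0)

    @pytest.mark.parametrize("min_cells", [1, 2, 3, 4, 6])
    def test_raising_min_cells_never_increases_na_or_ai(self, small_scene, min_cells):
        frame, truth = small_scene
        seg = _fake_segmentation([o.pixel_area for o in truth.objects])
        prev = select_aggregates(seg, 201.0, min_cells=min_cells)
        nxt = select_aggregates(seg, 201.0, min_cells=min_cells + 1)
        assert len(nxt) <= len(prev)
        assert sum(r.area_px for r in nxt) <= sum(r.area_px for r in prev)


class TestRefineSelection:
    def test_far_from_cutoff_accepted_first_pass(self):
        seg = _fake_segmentation([100, 1000])
        _, report = refine_selection(seg, 100.0, min_cells=3, packing_factor=1.0)
        assert report.stable and report.passes == 1 and not report.flipped_labels

    def test_region_exactly_at_cutoff_is_flagged(self):
        seg = _fake_segmentation([300])
        _, report = refine_selection(
            seg, 100.0, min_cells=3, packing_factor=1.0, threshold_perturbation=0.05
        )
        assert not report.stable
        assert report.flipped_labels == [1]
        assert report.selected_at_low == [1] and report.selected_at_high == []

    def test_flip_count_monotone_in_perturbation(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            seg = _fake_segmentation(rng.integers(100, 500, size=40))
            flips = [
                len(selection_flips(seg, 100.0, min_cells=3, packing_factor=1.0, perturbation=p))
                for p in (0.01, 0.05, 0.10)
            ]
            assert flips == sorted(flips)


class TestComputeIndices:
    def test_ai_ratio_of_areas(self):
        seg = _fake_segmentation([40800])
        records = select_aggregates(seg, 100.0, min_cells=3, packing_factor=1.0)
        idx = compute_indices(records, field_area_px=1600 * 300, shear_condition=ShearCondition.LOW)
        assert idx.AI == pytest.approx(0.085)
        assert idx.S1_px == 480000 and idx.S_agg_px == 40800 and idx.NA == 1

    def test_zero_records(self):
        idx = compute_indices([], 480000, ShearCondition.HIGH)
        assert idx.AI == 0.0 and idx.NA == 0

    def test_full_coverage_gives_ai_one(self):
        seg = _fake_segmentation([480000])
        records = select_aggregates(seg, 100.0, min_cells=3, packing_factor=1.0)
        idx = compute_indices(records, 480000, ShearCondition.LOW)
        assert idx.AI == 1.0

    def test_ai_invariant_to_image_flips(self, small_spec, small_scene, pixel_exact_config):
        frame, _ = small_scene
        base = analyze_frame(frame, pixel_exact_config).indices
        for flipped in (np.flipud(frame.pixels), np.fliplr(frame.pixels)):
            f = replace(frame, pixels=np.ascontiguousarray(flipped))
            idx = analyze_frame(f, pixel_exact_config).indices
            assert idx.AI == base.AI and idx.NA == base.NA


class TestMorphologyClasses:
    def _render_and_classify(self, weights, length_range=(5, 5), seed=0, branch_p=0.0):
        spec = SceneSpec(
            field_width_px=400, field_height_px=300,
            morphology_weights=weights,
            rouleau_length_range=length_range,
            branch_probability=branch_p,
            n_objects=1,
            seed=seed,
        )
        frame, truth = generate_scene(spec)
        from rbcagg import binarize

        seg = label_components(binarize(frame).mask)
        row = seg.regions.iloc[0]
        return classify_morphology(
            int(row.skeleton_endpoints), int(row.skeleton_branch_points), int(row.area_px)
        ), truth

    def test_straight_rouleau_classified_rouleau(self):
        w = {"singlet": 0.0, "rouleau": 1.0, "branched": 0.0, "network": 0.0}
        cls, _ = self._render_and_classify(w)
        assert cls == "rouleau"

    def test_branched_chain_classified_branched(self):
        w = {"singlet": 0.0, "rouleau": 0.0, "branched": 1.0, "network": 0.0}
        # branch probability 1 on an 8-cell chain guarantees side-chains
        cls, truth = self._render_and_classify(w, length_range=(8, 8), seed=4, branch_p=0.6)
        assert cls in ("branched", "network")
        assert truth.objects[0].morphology_class == "branched"

    def test_merged_units_classified_network(self):
        w = {"singlet": 0.0, "rouleau": 0.0, "branched": 0.0, "network": 1.0}
        for seed in (1, 2, 3):
            spec = SceneSpec(
                field_width_px=500, field_height_px=400,
                morphology_weights=w,
                rouleau_length_range=(7, 9),
                branch_probability=0.8,
                network_merge_probability=1.0,
                n_objects=1,
                seed=seed,
            )
            frame, _ = generate_scene(spec)
            from rbcagg import binarize

            seg = label_components(binarize(frame).mask)
            row = seg.regions.iloc[0]
            cls = classify_morphology(
                int(row.skeleton_endpoints), int(row.skeleton_branch_points), int(row.area_px)
            )
            if cls == "network":
                return
        pytest.fail("no merged multi-branch unit classified as network in 3 seeds")

    def test_degenerate_region_unclassified(self):
        assert classify_morphology(0, 0, 1) == "unclassified"


class TestSummarizeSample:
    def _indices(self, ai_values, shear=ShearCondition.LOW):
        return [
            AggregationIndices(shear, S1_px=1000, S_agg_px=int(a * 1000), AI=a, NA=1)
            for a in ai_values
        ]

    def test_identical_images_zero_sd(self):
        s = summarize_sample(self._indices([0.1] * 5), "s1", "g")
        assert s.mean_AI == pytest.approx(0.1) and s.sd_AI == 0.0

    def test_two_image_mean_and_sd(self):
        s = summarize_sample(self._indices([0.08, 0.09]), "s1", "g")
        assert s.mean_AI == pytest.approx(0.085)
        assert s.sd_AI == pytest.approx(0.00707, abs=1e-5)

    def test_single_image_flagged(self):
        s = summarize_sample(self._indices([0.1]), "s1", "g")
        assert s.single_image and s.sd_AI == 0.0 and s.n_images == 1

    def test_mixed_shear_conditions_rejected(self):
        ix = self._indices([0.1]) + self._indices([0.01], shear=ShearCondition.HIGH)
        with pytest.raises(ValueError):
            summarize_sample(ix, "s1", "g")
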