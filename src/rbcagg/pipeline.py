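"""Configurable end-to-end pipeline and standard-format readers/writers.

Stage order per field of view: illumination flattening (optional) →
percentile contrast stretch → light denoising (optional) → threshold
binarization → mask clean-up → connected-component labeling →
single-cell-area estimation → aggregate selection with a stability check →
aggregation indices.  Per-sample summaries and group comparisons follow.
Every output CSV carries a comment header embedding the configuration hash
and seed, so reruns are bit-identical and traceable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from . import metrics, segmentation, stats
from .synthetic import ImageFrame, ShearCondition

logger = logging.getLogger("rbcagg")

__all__ = [
    "RunConfig",
    "PipelineResult",
    "analyze_frame",
    "analyze_sample",
    "segment_frame",
    "measure_frame",
    "run_pipeline",
    "read_image",
    "read_group_means_table",
    "packaged_table",
]


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All pipeline tunables with documented defaults.

    Defaults suit noisy phase-contrast fields.  For noise-free validation
    scenes, disable the conditioning that trades pixel exactness for noise
    robustness: ``illumination_correction=False, median_size=0,
    fill_holes=False``.
    """

    # contrast conditioning
    low_pct: float = 1.0                # stretch percentiles, robust to hot pixels
    high_pct: float = 99.0
    illumination_correction: bool = True
    illumination_sigma: float = 25.0    # px; large vs a cell, small vs the field
    median_size: int = 3                # median-filter window; <= 1 disables
    # binarization
    threshold_method: str = "otsu"      # or "fixed"
    fixed_threshold: float | None = None
    polarity: str = "auto"              # "auto" | "dark" | "bright"
    # mask clean-up
    min_speck_area_px: int = 50
    fill_holes: bool = True
    # labeling / criterion
    connectivity: int = 8
    min_cells: int = 3                  # the >= 3 clumped-cell criterion
    packing_factor: float = 0.75
    expected_cell_area_px: float | None = None  # prior; None = estimate from data
    refine_perturbation: float = 0.05
    include_border: bool = True
    classify_morphology: bool = True
    #: "sample" pools the regions of all of a sample's fields for the
    #: single-cell-area estimate (one suspension, one optical calibration);
    #: "image" estimates independently per field
    cell_area_scope: str = "sample"
    # statistics
    alpha: float = 0.05
    holm_correction: bool = False
    # run behavior
    on_error: str = "abort"             # or "skip"
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.low_pct < self.high_pct <= 100:
            raise ValueError("need 0 <= low_pct < high_pct <= 100")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ValueError("threshold_method 'fixed' requires fixed_threshold")
        if self.polarity not in ("auto", "dark", "bright"):
            raise ValueError("polarity must be 'auto', 'dark' or 'bright'")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.min_cells < 1:
            raise ValueError("min_cells must be >= 1")
        if not 0 < self.packing_factor <= 1:
            raise ValueError("packing_factor must lie in (0, 1]")
        if self.min_speck_area_px < 0:
            raise ValueError("min_speck_area_px must be >= 0")
        if self.cell_area_scope not in ("sample", "image"):
            raise ValueError("cell_area_scope must be 'sample' or 'image'")
        if self.on_error not in ("abort", "skip"):
            raise ValueError("on_error must be 'abort' or 'skip'")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from a flat YAML key-value file; unknown keys are rejected."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must be a flat key-value mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


# --------------------------------------------------------------------------
# Per-image analysis
# --------------------------------------------------------------------------

@dataclass
class FrameAnalysis:
    indices: metrics.AggregationIndices
    records: list
    segmentation: segmentation.LabeledSegmentation
    stability: metrics.StabilityReport
    single_cell_area_px: float


def segment_frame(frame: ImageFrame, config: RunConfig | None = None) -> segmentation.LabeledSegmentation:
    """Intensity conditioning, binarization, clean-up and labeling of one field."""
    config = config or RunConfig()
    config.validate()
    f = frame
    if config.illumination_correction:
        f = segmentation.correct_illumination(f, sigma=config.illumination_sigma)
    f = segmentation.normalize_contrast(f, config.low_pct, config.high_pct)
    if config.median_size > 1:
        f = segmentation.denoise(f, size=config.median_size)
    binres = segmentation.binarize(
        f, method=config.threshold_method,
        fixed_threshold=config.fixed_threshold, polarity=config.polarity,
    )
    mask = segmentation.clean_mask(
        binres.mask, min_speck_area_px=config.min_speck_area_px, fill_holes=config.fill_holes
    )
    return segmentation.label_components(
        mask, connectivity=config.connectivity, compute_skeleton=config.classify_morphology
    )


def measure_frame(
    frame: ImageFrame,
    seg: segmentation.LabeledSegmentation,
    config: RunConfig,
    single_cell_area_px: float | None = None,
) -> FrameAnalysis:
    """Aggregate selection, stability check and indices for a segmented field."""
    cell_area = (
        single_cell_area_px
        if single_cell_area_px is not None
        else segmentation.estimate_single_cell_area(seg.regions, config.expected_cell_area_px)
    )
    records, stability = metrics.refine_selection(
        seg,
        cell_area,
        min_cells=config.min_cells,
        packing_factor=config.packing_factor,
        threshold_perturbation=config.refine_perturbation,
        include_border=config.include_border,
        classify=config.classify_morphology,
    )
    indices = metrics.compute_indices(records, frame.field_area_px, frame.shear_condition)
    return FrameAnalysis(indices, records, seg, stability, cell_area)


def analyze_frame(frame: ImageFrame, config: RunConfig | None = None) -> FrameAnalysis:
    """Run the full per-image stage chain on one field of view."""
    config = config or RunConfig()
    seg = segment_frame(frame, config)
    return measure_frame(frame, seg, config)


def analyze_sample(frames: list, config: RunConfig | None = None) -> list:
    """Analyze all fields of one sample with a shared single-cell area.

    The singlet population is identified on the pooled region table of every
    field (both shear conditions; high-shear fields are singlet-rich), since
    the cell size is a property of the suspension and the optics, not of one
    frame.  Returns one :class:`FrameAnalysis` per frame, in order.
    """
    config = config or RunConfig()
    config.validate()
    segs = [segment_frame(fr, config) for fr in frames]
    if config.expected_cell_area_px is not None or config.cell_area_scope == "image":
        cell_area = None
    else:
        pooled = pd.concat([s.regions for s in segs], ignore_index=True)
        cell_area = segmentation.estimate_single_cell_area(pooled, None)
    return [measure_frame(fr, sg, config, cell_area) for fr, sg in zip(frames, segs)]


# --------------------------------------------------------------------------
# Manifest-driven pipeline
# --------------------------------------------------------------------------

MANIFEST_COLUMNS = ["sample_id", "group", "shear", "path", "seed"]


@dataclass
class PipelineResult:
    per_image: pd.DataFrame
    per_region: pd.DataFrame
    per_sample: pd.DataFrame
    comparisons: pd.DataFrame
    config: RunConfig = field(repr=False, default=None)


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit grayscale TIFF or PNG field of view."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        img = tifffile.imread(path)
    else:
        img = iio.imread(path)
    img = np.asarray(img)
    if img.ndim == 3:  # collapse an accidental RGB save
        img = img[..., 0]
    return img


def _meta_header(config: RunConfig) -> str:
    return f"# rbcagg config_hash={config.config_hash()} seed={config.seed}\n"


def _write_csv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_meta_header(config))
        df.to_csv(fh, index=False)


def run_pipeline(
    manifest: pd.DataFrame | str | Path,
    config: RunConfig | None = None,
    images_root: str | Path | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Analyze every image in a manifest and compare the groups.

    ``manifest`` is a DataFrame or CSV path with columns
    ``sample_id,group,shear,path,seed``.  Image paths are resolved against
    ``images_root`` (defaulting to the manifest's directory).  Per
    ``config.on_error``, an unreadable image either aborts the run or is
    skipped with a logged warning.  When ``out_dir`` is given, four CSVs are
    written (per-image, per-region, per-sample, group comparisons), each
    headed by the config hash.
    """
    config = config or RunConfig()
    config.validate()
    root = Path(images_root) if images_root is not None else None
    if not isinstance(manifest, pd.DataFrame):
        mpath = Path(manifest)
        if root is None:
            root = mpath.parent
        manifest = pd.read_csv(mpath, comment="#")
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest is missing columns: {missing}")
    if len(manifest) == 0:
        raise ValueError("manifest is empty")
    if root is None:
        root = Path(".")

    image_rows = []
    region_rows = []
    analyses: dict[tuple, list] = {}
    processed: list = []
    for sample_id, sample_rows in manifest.groupby("sample_id", sort=False):
        frames = []
        kept = []
        for row in sample_rows.itertuples(index=False):
            path = root / row.path
            try:
                pixels = read_image(path)
            except Exception as exc:
                if config.on_error == "skip":
                    logger.warning("skipping %s: %s", path, exc)
                    continue
                raise
            frames.append(
                ImageFrame(
                    pixels=pixels,
                    shear_condition=ShearCondition(row.shear),
                    sample_id=str(row.sample_id),
                    group_label=str(row.group),
                )
            )
            kept.append(row)
        if not frames:
            continue
        try:
            fas = analyze_sample(frames, config)
        except Exception as exc:
            if config.on_error == "skip":
                logger.warning("skipping sample %s: %s", sample_id, exc)
                continue
            raise
        processed.extend(zip(kept, fas))

    for row, fa in processed:
        ix = fa.indices
        image_rows.append(
            {
                "sample_id": row.sample_id,
                "group": row.group,
                "shear": row.shear,
                "path": row.path,
                "S1_px": ix.S1_px,
                "S_agg_px": ix.S_agg_px,
                "AI": ix.AI,
                "NA": ix.NA,
                "single_cell_area_px": fa.single_cell_area_px,
                "selection_stable": fa.stability.stable,
            }
        )
        for rec in fa.records:
            region_rows.append(
                {
                    "sample_id": row.sample_id,
                    "group": row.group,
                    "shear": row.shear,
                    "path": row.path,
                    "label": rec.label,
                    "area_px": rec.area_px,
                    "cell_count_est": rec.cell_count_est,
                    "morphology_class": rec.morphology_class,
                    "border_touching": rec.border_touching,
                }
            )
        analyses.setdefault((str(row.sample_id), str(row.group), str(row.shear)), []).append(ix)

    if not image_rows:
        raise ValueError("no image in the manifest could be processed")

    per_image = pd.DataFrame(image_rows)
    per_region = pd.DataFrame(
        region_rows,
        columns=[
            "sample_id", "group", "shear", "path", "label", "area_px",
            "cell_count_est", "morphology_class", "border_touching",
        ],
    )

    sample_rows = []
    for (sample_id, group, shear), ix_list in analyses.items():
        summ = metrics.summarize_sample(ix_list, sample_id, group)
        sample_rows.append(
            {
                "sample_id": sample_id,
                "group": group,
                "shear": shear,
                "mean_AI": summ.mean_AI,
                "sd_AI": summ.sd_AI,
                "mean_NA": summ.mean_NA,
                "sd_NA": summ.sd_NA,
                "n_images": summ.n_images,
            }
        )
    per_sample = pd.DataFrame(sample_rows).sort_values(["shear", "group", "sample_id"]).reset_index(drop=True)

    comparisons = group_comparisons(per_sample, alpha=config.alpha, holm=config.holm_correction)

    result = PipelineResult(per_image, per_region, per_sample, comparisons, config)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        _write_csv(per_image, out_dir / "per_image.csv", config)
        _write_csv(per_region, out_dir / "per_region.csv", config)
        _write_csv(per_sample, out_dir / "per_sample.csv", config)
        _write_csv(comparisons, out_dir / "group_comparisons.csv", config)
    return result


def group_comparisons(per_sample: pd.DataFrame, alpha: float = 0.05, holm: bool = False) -> pd.DataFrame:
    """Rank-sum comparisons of AI and NA for every group pair at each shear."""
    rows = []
    for shear in sorted(per_sample["shear"].unique()):
        sub = per_sample[per_sample["shear"] == shear]
        groups = sorted(sub["group"].unique())
        for i, ga in enumerate(groups):
            for gb in groups[i + 1 :]:
                for metric_col, metric_name in (("mean_AI", "AI"), ("mean_NA", "NA")):
                    va = sub.loc[sub["group"] == ga, metric_col].to_numpy()
                    vb = sub.loc[sub["group"] == gb, metric_col].to_numpy()
                    if len(va) < 2 or len(vb) < 2:
                        continue
                    name = f"{metric_name}_{'L' if shear == 'LOW' else 'H'}"
                    cmp = stats.compare_groups(name, ga, va, gb, vb, alpha=alpha)
                    rows.append(dataclasses.asdict(cmp))
    df = pd.DataFrame(rows)
    if holm and len(df):
        df["p_adjusted"] = stats.holm_adjust(df["p_value"].to_numpy())
        df["significant"] = df["p_adjusted"] <= alpha
    return df


# --------------------------------------------------------------------------
# Group-means tables
# --------------------------------------------------------------------------

def read_group_means_table(path: str | Path) -> pd.DataFrame:
    """Read a group-means CSV (``group,AI_L,NA_L,AI_H,NA_H`` + extras).

    Returns the table indexed by group.  A missing metric column or a
    non-numeric cell raises with the offending name / position.
    """
    df = pd.read_csv(path, comment="#")
    if "group" not in df.columns:
        raise ValueError("means table is missing the 'group' column")
    for col in ("AI_L", "NA_L", "AI_H", "NA_H"):
        if col not in df.columns:
            raise ValueError(f"means table is missing column {col!r}")
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"non-numeric cell in column {col!r}, row {int(bad[0])} "
                f"(value {df.loc[bad[0], col]!r})"
            )
        df[col] = coerced
    return df.set_index("group")


def packaged_table(name: str) -> pd.DataFrame:
    """Load one of the packaged group-means fixtures.

    ``name`` is ``"patient_groups"`` (the three clinical groups) or
    ``"oxidation_series"`` (untreated plus three H₂O₂ doses).
    """
    fname = {
        "patient_groups": "table2_patient_groups.csv",
        "oxidation_series": "table3_oxidation_series.csv",
    }.get(name)
    if fname is None:
        raise KeyError(f"unknown packaged table {name!r}")
    ref = resources.files("rbcagg.data") / fname
    with resources.as_file(ref) as p:
        return read_group_means_table(p)
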