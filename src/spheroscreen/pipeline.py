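"""End-to-end batch pipeline: images -> per-structure tables -> screen reports.

`analyze_stack` runs the full per-image chain (projection, grayscale,
normalisation, valley thresholding, gap filling, structure labeling, optional
focus-plane refinement, substructural segmentation per channel and the
morphometry catalogue).  `run_batch` maps it over a directory of images and
writes result tables; `run_stats` runs the statistics layer on a result table
plus plate map.
"""

from __future__ import annotations

import dataclasses
import glob
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import imaging, morphometry, screen_stats, segmentation
from .imaging import ImageStack
from .morphometry import RESULT_COLUMNS
from .screen_stats import QCRules
from .segmentation import SegmentationConfig, Structure

log = logging.getLogger("spheroscreen")


@dataclass
class RunConfig:
    """Effective configuration of a batch run; echoed into the output dir."""

    inputs: str = "*.tif"
    layout: str = "auto"
    projection: str = "average"  # or "max"
    channel_weights: dict[str, float] | None = None
    normalize: bool = True
    norm_low: float = 5.0
    norm_high: float = 95.0
    denoise_method: str | None = None
    denoise_size: int = 3
    denoise_sigma: float = 1.0
    phase_contrast: bool = False
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    qc: QCRules = field(default_factory=QCRules)
    output_dir: str = "results"
    formats: tuple[str, ...] = ("csv",)
    overlay: bool = False
    log_level: str = "INFO"
    seed: int = 0


@dataclass
class ImageResult:
    image_id: str
    records: pd.DataFrame
    labels: np.ndarray
    structures: list[Structure]
    threshold: float
    focus_planes: dict[int, int] | None = None


def analyze_stack(
    stack: ImageStack, config: RunConfig | None = None, image_id: str = "image"
) -> ImageResult:
    """Run the whole per-image pipeline on an in-memory stack."""
    config = config or RunConfig()
    seg = config.segmentation

    project = imaging.average_projection if config.projection == "average" else imaging.max_projection
    proj = project(stack)
    gray = (
        imaging.to_grayscale(proj.color, config.channel_weights)
        if config.channel_weights
        else proj.gray
    )
    if config.phase_contrast:
        gray = imaging.phase_contrast_prepare(gray)
    if config.denoise_method:
        gray = imaging.denoise(
            gray, config.denoise_method, size=config.denoise_size, sigma=config.denoise_sigma
        )
    if config.normalize:
        gray = imaging.percentile_normalize(gray, config.norm_low, config.norm_high)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mask, cut = segmentation.histogram_valley_threshold(
            gray,
            seg.threshold_level,
            seg.hist_smooth_sigma,
            seg.level_step_fraction,
            return_threshold=True,
        )
    mask = segmentation.fill_gaps(mask, seg.gap_fill_max)
    labels = segmentation.segment_primary(mask, seg)

    focus = None
    depths = {stack.depth(c) for c in stack.channels}
    if max(depths) > 1:
        weights = config.channel_weights or {c: 1.0 for c in stack.channels}
        total = sum(weights.get(c, 0.0) for c in stack.channels) or 1.0
        depth = max(depths)
        gray3d = np.zeros((depth, stack.height, stack.width))
        for c, arr in stack.channels.items():
            w = weights.get(c, 0.0) / total
            for z in range(depth):
                gray3d[z] += w * arr[min(z, arr.shape[0] - 1)]
        adjusted, focus = segmentation.focus_adjust_threshold(gray3d, labels, mask, seg)
        labels = np.where(adjusted, labels, 0)

    structures = segmentation.structures_from_labels(labels)
    neighbor, cell_ratio = morphometry.neighbor_features(labels)

    channel_imgs = {
        "R": proj.color.get("R"),
        "G": proj.color.get("G", proj.color.get("gray")),
    }
    per_structure: dict[int, dict[str, float]] = {}
    for s in structures:
        geom = morphometry.geometry(s, seg.radius_quantile)
        body, appendages = segmentation.extract_body_appendages(s, seg)
        feats: dict[str, float] = {}
        feats.update(morphometry.shape_features(s, geom))
        feats.update(morphometry.appendage_features(s, body, appendages))
        feats.update(neighbor.get(s.label, {"Closest": -1.0, "Neighbors": 0.0, "SharedBound": 0.0}))
        feats["CellRatio"] = cell_ratio
        for ch in ("R", "G"):
            img = channel_imgs[ch]
            if img is None:
                cells = np.zeros(s.mask.shape, dtype=np.int32)
                img = np.zeros((stack.height, stack.width))
            else:
                cells = segmentation.segment_cells(s, img, seg)
            s.cells[ch] = cells
            cf = morphometry.channel_features(s, geom, img, cells)
            for k, v in cf.items():
                if k == "Deviation":
                    continue
                feats[f"{k}_{ch}"] = v
            if ch == seg.structure_channel:
                feats["Deviation"] = cf["Deviation"]
        feats.setdefault("Deviation", 0.0)
        per_structure[s.label] = feats

    records = morphometry.assemble_records(image_id, structures, per_structure)
    return ImageResult(image_id, records, labels, structures, cut, focus)


def analyze_file(path: str | Path, config: RunConfig) -> ImageResult:
    stack = imaging.load_image(path, layout=config.layout)
    return analyze_stack(stack, config, image_id=Path(path).stem)


def run_batch(config: RunConfig) -> int:
    """Analyse every input image; returns the number of failed images.

    Writes the combined per-structure table (CSV and optionally XLSX), a
    per-image summary, the effective config, and optional label overlays.
    Per-image failures are logged and skipped.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = sorted(glob.glob(config.inputs))
    if not paths:
        raise FileNotFoundError(f"no inputs match {config.inputs!r}")

    all_records = []
    summary = []
    failures = 0
    for path in paths:
        try:
            result = analyze_file(path, config)
        except Exception as exc:
            failures += 1
            log.error("failed on %s: %s", path, exc)
            summary.append({"image_id": Path(path).stem, "n_structures": -1, "error": str(exc)})
            continue
        all_records.append(result.records)
        summary.append(
            {
                "image_id": result.image_id,
                "n_structures": int(result.labels.max()),
                "threshold": result.threshold,
                "error": "",
            }
        )
        if config.overlay:
            _write_overlay(result, out / f"{result.image_id}_overlay.png")

    records = (
        pd.concat(all_records, ignore_index=True)
        if all_records
        else pd.DataFrame(columns=list(RESULT_COLUMNS))
    )
    if "csv" in config.formats:
        morphometry.write_records_csv(records, out / "structures.csv")
    if "xlsx" in config.formats:
        morphometry.write_records_xlsx(records, out / "structures.xlsx")
    pd.DataFrame(summary).to_csv(out / "images_summary.csv", index=False)
    (out / "run_config.yaml").write_text(yaml.safe_dump(config_to_dict(config)))
    return failures


def config_to_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["formats"] = list(d["formats"])
    return d


def config_from_dict(d: dict) -> RunConfig:
    d = dict(d)
    if isinstance(d.get("segmentation"), dict):
        d["segmentation"] = SegmentationConfig(**d["segmentation"])
    if isinstance(d.get("qc"), dict):
        qc = dict(d["qc"])
        qc["excluded"] = [tuple(e) for e in qc.get("excluded", [])]
        qc["ranges"] = {k: tuple(v) for k, v in qc.get("ranges", {}).items()}
        d["qc"] = QCRules(**qc)
    if isinstance(d.get("formats"), list):
        d["formats"] = tuple(d["formats"])
    return RunConfig(**d)


def _write_overlay(result: ImageResult, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from skimage.color import label2rgb

    fig, ax = plt.subplots(figsize=(8, 6))
    ax.imshow(label2rgb(result.labels, bg_label=0))
    for s in result.structures:
        r0, c0 = s.offset()
        rows, cols = np.nonzero(s.mask)
        ax.text(c0 + cols.mean(), r0 + rows.mean(), str(s.label), color="white", fontsize=6)
    ax.set_axis_off()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def run_stats(
    results_path: str | Path,
    plate_map_path: str | Path,
    output_dir: str | Path,
    features: list[str] | None = None,
    control_label: str = "DMSO",
    qc: QCRules | None = None,
    variance_features: list[str] | None = None,
    plots: bool = False,
) -> dict[str, object]:
    """Annotate, QC-filter and run the full statistics layer; write reports."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = pd.read_csv(results_path)
    plate_map = pd.read_csv(plate_map_path)

    table = screen_stats.annotate(records, plate_map)
    clean, rejected = screen_stats.qc_filter(table, qc or QCRules())
    if control_label not in set(clean["treatment"]):
        raise ValueError(f"expected control treatment {control_label!r} in the data")

    default_feats = [
        c for c in RESULT_COLUMNS if c not in ("image_id", "structure_id", "Closest")
    ]
    features = features or default_feats
    heat = screen_stats.median_diff_heatmap(clean, features, control_label)
    spear = screen_stats.spearman_map(clean, features)
    row_order, _ = screen_stats.cluster(heat.diff, axis=0)
    col_order, _ = screen_stats.cluster(heat.diff, axis=1)
    heat.row_order, heat.col_order = row_order, col_order

    vcs = []
    for feat in variance_features or ["Area"]:
        try:
            vcs.append(screen_stats.variance_components(clean, feat))
        except ValueError as exc:
            log.warning("variance components for %s skipped: %s", feat, exc)

    heat.diff.to_csv(out / "heatmap_median_diff.csv")
    heat.p_corrected.to_csv(out / "heatmap_p_corrected.csv")
    heat.significant.to_csv(out / "heatmap_significant.csv")
    spear.to_csv(out / "spearman_correlation.csv")
    rejected.to_csv(out / "qc_rejected.csv", index=False)
    (out / "cluster_orders.txt").write_text(
        "rows: " + " ".join(str(heat.diff.index[i]) for i in row_order) + "\n"
        "cols: " + " ".join(str(heat.diff.columns[i]) for i in col_order) + "\n"
    )
    if vcs:
        pd.DataFrame(
            [
                {
                    "feature": v.feature,
                    "sigma_well": v.sigma_well,
                    "sigma_position": v.sigma_position,
                    "sigma_residual": v.sigma_residual,
                    "well_to_residual": v.well_to_residual,
                    "position_to_residual": v.position_to_residual,
                }
                for v in vcs
            ]
        ).to_csv(out / "variance_components.csv", index=False)
    if plots:
        screen_stats.plot_heatmap(heat, out / "heatmap.png", mask_nonsignificant=True)
    return {"heatmap": heat, "spearman": spear, "variance": vcs, "rejected": rejected}
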