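"""Self-validation benchmarks: ground-truth recovery, calibration, robustness.

These routines generate synthetic inputs with known truth, run the pipeline
and measure how well the planted quantities are recovered.  They are shared
by the test suite and by ``scripts/acceptance.py``, which recomputes the
package's headline numbers from scratch.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .morphometry import channel_features, geometry, shape_features
from .pipeline import analyze_stack
from .screen_stats import median_diff_heatmap, variance_components
from .segmentation import (
    SegmentationConfig,
    Structure,
    fill_gaps,
    histogram_valley_threshold,
    segment_primary,
)
from .imaging import average_projection, percentile_normalize
from .synthetic import PhenotypeSpec, make_field


def locate_gap_fill_cutoff(max_size: int = 4096, cutoff_config: int | None = None) -> int:
    """Largest hole the default gap filling closes, located by bisection.

    Builds solid rectangles with an interior hole of exactly k pixels and
    bisects on whether ``fill_gaps`` closes it.
    """
    def filled(k: int) -> bool:
        side = int(np.ceil(np.sqrt(k))) + 2
        mask = np.ones((side + 20, side + 20), dtype=bool)
        hole = np.zeros_like(mask)
        cols = side
        rows, rem = divmod(k, cols)
        hole[10 : 10 + rows, 10 : 10 + cols] = True
        if rem:
            hole[10 + rows, 10 : 10 + rem] = True
        assert hole.sum() == k
        mask[hole] = False
        out = fill_gaps(mask) if cutoff_config is None else fill_gaps(mask, cutoff_config)
        return bool(out[hole].all())

    lo, hi = 1, max_size  # filled at lo, assumed unfilled at hi
    if filled(hi):
        return hi
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if filled(mid):
            lo = mid
        else:
            hi = mid
    return lo


def recovery_benchmark(n_fields: int = 50, seed: int = 0) -> dict[str, float]:
    """Recover planted structure/appendage/dot truths over seeded fields."""
    count_exact = 0
    app_total = app_exact = dot_exact = 0
    area_ratio_err: list[float] = []
    ious: list[float] = []
    for k in range(n_fields):
        stack, truth = make_field(PhenotypeSpec(seed=seed + k))
        result = analyze_stack(stack, image_id=f"f{k}")
        n = int(result.labels.max())
        if n != len(truth.structures):
            app_total += len(truth.structures)
            continue
        count_exact += 1
        cents = ndi.center_of_mass(result.labels > 0, result.labels, range(1, n + 1))
        for sid, c in enumerate(cents, start=1):
            j = int(
                np.argmin(
                    [np.hypot(c[0] - s.center[0], c[1] - s.center[1]) for s in truth.structures]
                )
            )
            s = truth.structures[j]
            row = result.records[result.records.structure_id == sid].iloc[0]
            app_total += 1
            app_exact += int(row["AppNumber"] == s.appendage_count)
            dot_exact += int(row["CellNumber_R"] == s.dot_count)
            area_ratio_err.append(abs(row["AreaRatio_R"] - 100 * s.dot_area / s.area))
            seg = result.labels == sid
            planted = truth.label_mask == j + 1
            ious.append(float((seg & planted).sum() / (seg | planted).sum()))
    return {
        "n_fields": n_fields,
        "n_structures": app_total,
        "count_exact_fraction": count_exact / n_fields,
        "appendage_exact_fraction": app_exact / app_total,
        "dot_exact_fraction": dot_exact / app_total,
        "area_ratio_max_abs_error": float(max(area_ratio_err)) if area_ratio_err else float("nan"),
        "mean_iou": float(np.mean(ious)) if ious else float("nan"),
    }


def _measure_shape(mask: np.ndarray, image: np.ndarray, config: SegmentationConfig):
    structure = Structure(1, (slice(0, mask.shape[0]), slice(0, mask.shape[1])), mask)
    geom = geometry(structure, config.radius_quantile)
    shape = shape_features(structure, geom)
    chan = channel_features(structure, geom, image, np.zeros(mask.shape, np.int32))
    return shape, chan


def shape_ordering_check(n_seeds: int = 50, seed: int = 0) -> dict[str, float]:
    """Roundness(disk) > Roundness(bar) and Hollowness(annulus) > (disk).

    Noisy renderings of the three reference shapes are thresholded and
    measured per seed; returns the fraction of seeds where each ordering
    holds.
    """
    config = SegmentationConfig()
    round_ok = hollow_ok = 0
    yy, xx = np.mgrid[0:120, 0:160]
    disk = (yy - 60) ** 2 + (xx - 80) ** 2 <= 40**2
    bar = np.zeros_like(disk)
    bar[54:66, 20:140] = True  # 120 x 12 bar
    rr = np.hypot(yy - 60, xx - 80)
    for k in range(n_seeds):
        rng = np.random.default_rng(seed + k)
        noise = rng.normal(0, 5.0, disk.shape)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            disk_mask = histogram_valley_threshold(np.where(disk, 200.0, 20.0) + noise)
            bar_mask = histogram_valley_threshold(np.where(bar, 200.0, 20.0) + noise)
        f_disk, _ = _measure_shape(disk_mask, np.where(disk, 200.0, 20.0), config)
        f_bar, _ = _measure_shape(bar_mask, np.where(bar, 200.0, 20.0), config)
        round_ok += int(f_disk["Roundness"] > f_bar["Roundness"])

        annulus_img = np.where(rr <= 20, 10.0, np.where(disk, 200.0, 20.0)) + noise
        filled_img = np.where(disk, 200.0, 20.0) + noise
        _, c_ann = _measure_shape(disk, annulus_img, config)
        _, c_fill = _measure_shape(disk, filled_img, config)
        hollow_ok += int(c_ann["Hollowness"] > c_fill["Hollowness"])
    return {
        "roundness_ordering_fraction": round_ok / n_seeds,
        "hollowness_ordering_fraction": hollow_ok / n_seeds,
    }


def monotonicity_benchmark(
    n_fields: int = 10,
    seed: int = 100,
    sensitivities: tuple[float, ...] = (5, 10, 20, 40),
    levels: tuple[int, ...] = (1, 2, 3, 4, 5),
) -> dict[str, float]:
    """Structure count non-increasing in sensitivity; foreground
    non-increasing in threshold level, over seeded fields."""
    sens_ok = level_ok = 0
    for k in range(n_fields):
        stack, _ = make_field(PhenotypeSpec(seed=seed + k))
        gray = percentile_normalize(average_projection(stack).gray)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            base = fill_gaps(histogram_valley_threshold(gray))
            counts = [
                int(segment_primary(base, SegmentationConfig(sensitivity=s)).max())
                for s in sensitivities
            ]
            areas = [
                int(histogram_valley_threshold(gray, threshold_level=l).sum())
                for l in levels
            ]
        sens_ok += int(all(a >= b for a, b in zip(counts, counts[1:])))
        level_ok += int(all(a >= b for a, b in zip(areas, areas[1:])))
    return {
        "sensitivity_monotone_fraction": sens_ok / n_fields,
        "threshold_monotone_fraction": level_ok / n_fields,
    }


def bonferroni_type1_error(
    n_reps: int = 500, n_treatments: int = 19, n_per_group: int = 100, seed: int = 0
) -> float:
    """Fraction of significant heatmap cells under the global null."""
    rng = np.random.default_rng(seed)
    sig = total = 0
    names = [f"t{i:02d}" for i in range(n_treatments)]
    for _ in range(n_reps):
        rows = {"treatment": [], "f": []}
        for t in ["ctrl"] + names:
            rows["treatment"] += [t] * n_per_group
            rows["f"].append(rng.normal(0, 1, n_per_group))
        table = pd.DataFrame(
            {"treatment": rows["treatment"], "f": np.concatenate(rows["f"])}
        )
        h = median_diff_heatmap(table, ["f"], "ctrl")
        sig += int(h.significant.to_numpy().sum())
        total += n_treatments
    return sig / total


def variance_recovery(
    sigma_well: float = 2.0,
    sigma_position: float = 1.0,
    sigma_residual: float = 1.0,
    wells: int = 20,
    positions: int = 4,
    obs: int = 25,
    n_seeds: int = 10,
    seed: int = 0,
) -> dict[str, float]:
    """Median REML estimates over seeds for a known nested design."""
    est = []
    for k in range(n_seeds):
        rng = np.random.default_rng(seed + k)
        rows = []
        for w in range(wells):
            bw = rng.normal(0, sigma_well)
            for p in range(positions):
                bp = rng.normal(0, sigma_position)
                for v in 10 + bw + bp + rng.normal(0, sigma_residual, obs):
                    rows.append({"well": f"w{w:02d}", "position": f"p{p}", "y": v})
        vc = variance_components(pd.DataFrame(rows), "y")
        est.append([vc.sigma_well, vc.sigma_position, vc.sigma_residual])
    med = np.median(est, axis=0)
    return {
        "sigma_well": float(med[0]),
        "sigma_position": float(med[1]),
        "sigma_residual": float(med[2]),
        "n_seeds": n_seeds,
        "n_obs": wells * positions * obs,
    }
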