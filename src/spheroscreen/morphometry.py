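"""Per-structure morphometric parameter catalogue.

Every segmented structure is summarised by 19 named parameters in three
classes: general (Area, neighbour relations, CellRatio), morphological
(roundness, roughness and appendage descriptors built on the edge-distance
set D — the Euclidean distances from the centre of mass to every boundary
pixel) and functional (per-channel density, hollowness and cell counts,
computed separately for the red and green channels).  The centre of mass and
the m-quantile radius are internal quantities and are not written to the
result file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .segmentation import SegmentationConfig, Structure

#: The 19 named output parameters; the last five are computed for both the
#: red and the green channel, giving 24 feature columns per structure.
PARAMETER_CATALOGUE: tuple[str, ...] = (
    "Area",
    "Roundness",
    "FiltRound",
    "RoundDiff",
    "AppIndex",
    "MaxApp",
    "MedApp",
    "AppNumber",
    "Roughness",
    "Deviation",
    "Closest",
    "Neighbors",
    "SharedBound",
    "CellRatio",
    "Density",
    "AreaRatio",
    "Hollowness",
    "CellNumber",
    "AveArea",
)

PER_CHANNEL: tuple[str, ...] = ("Density", "AreaRatio", "Hollowness", "CellNumber", "AveArea")

#: Fixed column order of the per-structure result table.
RESULT_COLUMNS: tuple[str, ...] = (
    "image_id",
    "structure_id",
    *(p for p in PARAMETER_CATALOGUE if p not in PER_CHANNEL),
    *(f"{p}_R" for p in PER_CHANNEL),
    *(f"{p}_G" for p in PER_CHANNEL),
)


def parameter_catalogue() -> tuple[str, ...]:
    """The named output parameters of the per-structure result schema."""
    return PARAMETER_CATALOGUE


@dataclass
class StructureGeometry:
    """Centre of mass, edge pixels and the edge-distance set of a structure."""

    center: tuple[float, float]  # (row, col), bbox-local
    edge_pixels: np.ndarray  # (n, 2) row/col, bbox-local
    distances: np.ndarray  # D, one entry per edge pixel
    radius: float  # m-quantile of D


def geometry(structure: Structure, m: float = 0.25) -> StructureGeometry:
    """Centre of mass, 4-connectivity edge pixels, edge-distance set and radius."""
    mask = structure.mask
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("empty structure")
    center = (float(rows.mean()), float(cols.mean()))
    edge = _edge_pixels(mask)
    d = np.hypot(edge[:, 0] - center[0], edge[:, 1] - center[1])
    return StructureGeometry(center, edge, d, float(np.quantile(d, m)))


def _edge_pixels(mask: np.ndarray) -> np.ndarray:
    """Foreground pixels with at least one background 4-neighbour."""
    cross = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    interior = ndimage.binary_erosion(mask, structure=cross, border_value=0)
    return np.argwhere(mask & ~interior)


def _roundness_from_distances(d: np.ndarray) -> float:
    mu = float(d.mean())
    if mu <= 0:
        return 100.0
    return 100.0 * max(0.0, 1.0 - float(d.std()) / mu)


def roundness_isoperimetric(structure: Structure) -> float:
    """Alternative roundness 100 * 4*pi*A / P^2 (perimeter via edge count)."""
    area = structure.area
    perimeter = len(_edge_pixels(structure.mask))
    if perimeter == 0:
        return 100.0
    return 100.0 * min(1.0, 4.0 * math.pi * area / perimeter**2)


def shape_features(
    structure: Structure,
    geom: StructureGeometry,
    config: SegmentationConfig | None = None,
    roughness_window: int = 15,
) -> dict[str, float]:
    """Area, Roundness, FiltRound, RoundDiff and Roughness.

    Roundness is 100 * max(0, 1 - sd(D)/mean(D)): a perfect disk has an
    almost constant edge-distance set and scores near 100%.  FiltRound is the
    same statistic on the opened body mask (rounder whenever appendages are
    removed), RoundDiff = FiltRound - Roundness.  Roughness compares D with a
    circularly smoothed copy ordered by polar angle, capturing small surface
    features distinct from appendages.
    """
    d = geom.distances
    roundness = _roundness_from_distances(d)

    if structure.body is not None and structure.body.any() and "all_appendage" not in structure.flags:
        body_struct = Structure(structure.label, structure.bbox, structure.body)
        filt = _roundness_from_distances(geometry(body_struct).distances)
        rounddiff = filt - roundness
    else:
        filt, rounddiff = roundness, 0.0

    # order D by polar angle around the centre, smooth circularly
    edge = geom.edge_pixels
    angles = np.arctan2(edge[:, 0] - geom.center[0], edge[:, 1] - geom.center[1])
    order = np.argsort(angles, kind="stable")
    ds = d[order]
    n = len(ds)
    window = min(roughness_window, n if n % 2 == 1 else n - 1)
    if window >= 3 and n >= 3:
        kernel = np.ones(window) / window
        smoothed = np.convolve(np.concatenate([ds[-(window // 2):], ds, ds[: window // 2]]), kernel, mode="valid")
        mu = float(d.mean())
        roughness = 100.0 * float(np.abs(ds - smoothed).mean()) / mu if mu > 0 else 0.0
    else:
        roughness = 0.0

    return {
        "Area": float(structure.area),
        "Roundness": roundness,
        "FiltRound": filt,
        "RoundDiff": rounddiff,
        "Roughness": roughness,
    }


def appendage_features(
    structure: Structure,
    body: np.ndarray,
    appendages: list[np.ndarray],
) -> dict[str, float]:
    """AppIndex, MaxApp, MedApp, AppNumber.

    The length of an appendage is the largest Euclidean distance from any of
    its pixels to the body; AppIndex is total appendage area over body area.
    """
    if not appendages:
        return {"AppIndex": 0.0, "MaxApp": 0.0, "MedApp": 0.0, "AppNumber": 0.0}
    dist_to_body = ndimage.distance_transform_edt(~body)
    lengths = [float(dist_to_body[a].max()) for a in appendages]
    app_area = float(sum(int(a.sum()) for a in appendages))
    body_area = float(body.sum())
    return {
        "AppIndex": app_area / body_area if body_area > 0 else 0.0,
        "MaxApp": float(max(lengths)),
        "MedApp": float(np.median(lengths)),
        "AppNumber": float(len(appendages)),
    }


def neighbor_features(labels: np.ndarray) -> tuple[dict[int, dict[str, float]], float]:
    """Closest / Neighbors / SharedBound per structure and the global CellRatio.

    Closest is the centre-of-mass distance to the nearest other structure
    (sentinel -1 for a lone structure); Neighbors counts distinct labels
    8-adjacent to the structure; SharedBound counts the structure's boundary
    pixels 8-adjacent to any neighbouring label; CellRatio is the summed
    structure area as a percentage of the image area.
    """
    labels = np.asarray(labels)
    ids = [int(l) for l in np.unique(labels) if l != 0]
    h, w = labels.shape
    total_area = float((labels > 0).sum())
    cell_ratio = 100.0 * total_area / (h * w)
    if not ids:
        return {}, cell_ratio

    centroids = ndimage.center_of_mass(labels > 0, labels, ids)
    coords = np.asarray(centroids, dtype=np.float64)
    out: dict[int, dict[str, float]] = {}

    # 8-neighbourhood shifts once, reused for all structures
    square = np.ones((3, 3), dtype=bool)
    for k, lab in enumerate(ids):
        mask = labels == lab
        if len(ids) > 1:
            dd = np.hypot(coords[:, 0] - coords[k, 0], coords[:, 1] - coords[k, 1])
            dd[k] = np.inf
            closest = float(dd.min())
        else:
            closest = -1.0
        ring = ndimage.binary_dilation(mask, structure=square) & ~mask
        touching = np.unique(labels[ring])
        touching = touching[touching != 0]
        neighbors = float(len(touching))
        if neighbors:
            other = np.isin(labels, touching)
            near_other = ndimage.binary_dilation(other, structure=square)
            shared = float((mask & near_other & ~ndimage.binary_erosion(mask, structure=square)).sum())
        else:
            shared = 0.0
        out[lab] = {"Closest": closest, "Neighbors": neighbors, "SharedBound": shared}
    return out, cell_ratio


def channel_features(
    structure: Structure,
    geom: StructureGeometry,
    channel_image: np.ndarray,
    cells: np.ndarray,
) -> dict[str, float]:
    """Density, Deviation, AreaRatio, Hollowness, CellNumber, AveArea.

    Hollowness contrasts the mean intensity of the core (pixels within half
    the structure radius of the centre of mass) against the rim:
    100 * max(0, 1 - mean_core / mean_rim).  A bright annulus with a dark
    lumen scores high; a uniformly filled structure scores near zero.
    """
    sub = np.asarray(channel_image, dtype=np.float64)[structure.bbox]
    values = sub[structure.mask]
    density = float(values.mean()) if values.size else 0.0
    deviation = float(values.std()) if values.size else 0.0

    sizes = np.bincount(np.asarray(cells).ravel())
    cell_areas = sizes[1:][sizes[1:] > 0] if sizes.size > 1 else np.array([], dtype=int)
    n_cells = int(cell_areas.size)
    total_cell_area = float(cell_areas.sum())
    area = float(structure.area)
    area_ratio = 100.0 * total_cell_area / area if area > 0 else 0.0
    ave_area = total_cell_area / n_cells if n_cells else 0.0

    rows, cols = np.nonzero(structure.mask)
    rr = np.hypot(rows - geom.center[0], cols - geom.center[1])
    core = rr <= 0.5 * geom.radius
    if core.any() and (~core).any():
        mu_core = float(values[core].mean())
        mu_rim = float(values[~core].mean())
        hollowness = 100.0 * max(0.0, 1.0 - mu_core / mu_rim) if mu_rim > 0 else 0.0
    else:
        hollowness = 0.0
        structure.flags.append("degenerate_core")

    return {
        "Density": density,
        "Deviation": deviation,
        "AreaRatio": area_ratio,
        "Hollowness": hollowness,
        "CellNumber": float(n_cells),
        "AveArea": ave_area,
    }


def assemble_records(
    image_id: str,
    structures: list[Structure],
    per_structure: dict[int, dict[str, float]],
) -> pd.DataFrame:
    """One result row per structure with the fixed documented column order."""
    rows = []
    for s in structures:
        feats = per_structure.get(s.label, {})
        row = {"image_id": image_id, "structure_id": s.label}
        for col in RESULT_COLUMNS[2:]:
            row[col] = feats.get(col, 0.0)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(RESULT_COLUMNS))


def write_records_csv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def write_records_xlsx(records: pd.DataFrame, path, sheet_name: str = "structures") -> None:
    with pd.ExcelWriter(path, engine="openpyxl") as xl:
        records.to_excel(xl, sheet_name=sheet_name, index=False)
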