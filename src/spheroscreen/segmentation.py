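"""Two-phase segmentation of spheroid fields.

Phase 1 (preliminary): a histogram-valley threshold separates bright
multicellular structures from the dark background, interior gaps below a size
cutoff are filled, and touching structures are split by a morphological
opening, Euclidean distance transform and marker-based watershed.  The two
user-facing knobs are ``sensitivity`` (the pixel distance within which
distance-map maxima are merged into one watershed seed — larger values give
fewer, larger structures) and ``threshold_level`` (stringency steps added on
top of the histogram valley — higher values give a tighter foreground).

Phase 2 (substructural): inside every structure, an Otsu threshold on the
requested channel followed by an adaptive opening, distance transform and
watershed extracts individual cells; the same adaptive opening splits each
structure into a smooth body and its invasive appendages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.ndimage import gaussian_filter1d
from skimage.filters import threshold_otsu
from skimage.morphology import disk


@dataclass
class SegmentationConfig:
    """Knobs of the two-phase segmentation.

    sensitivity           pixel distance used by the watershed seed merging
    threshold_level       histogram cut-off stringency, integer levels 1..5
    gap_fill_max          interior gaps strictly smaller than this are filled
    min_structure_size    structures below this pixel count are discarded
    opening_radius        disk radius of the single preliminary opening
    adaptive_kernel_scale adaptive opening radius as a fraction of a
                          structure's equivalent diameter (min 1 px)
    radius_quantile       quantile m of the edge-distance set defining the
                          structure radius
    min_appendage_size    smallest pixel count counted as an appendage
    """

    sensitivity: float = 20.0
    threshold_level: int = 1
    gap_fill_max: int = 1000
    min_structure_size: int = 100
    opening_radius: int = 3
    adaptive_kernel_scale: float = 0.05
    radius_quantile: float = 0.25
    min_appendage_size: int = 5
    min_appendage_length: float = 6.0
    min_cell_size: int = 4
    cell_merge_distance: float = 6.0
    min_cell_contrast: float = 30.0
    hist_smooth_sigma: float = 3.0
    level_step_fraction: float = 0.02
    structure_channel: str = "G"
    apoptosis_channel: str = "R"

    def __post_init__(self) -> None:
        if self.sensitivity <= 0:
            raise ValueError("sensitivity must be > 0")
        if self.gap_fill_max < 0:
            raise ValueError("gap_fill_max must be >= 0")
        if not (0 < self.radius_quantile < 1):
            raise ValueError("radius_quantile must lie in (0, 1)")


@dataclass
class Structure:
    """One segmented multicellular structure in bounding-box coordinates."""

    label: int
    bbox: tuple[slice, slice]
    mask: np.ndarray  # boolean, local to bbox
    body: np.ndarray | None = None
    appendages: list[np.ndarray] = field(default_factory=list)
    cells: dict[str, np.ndarray] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    @property
    def equivalent_diameter(self) -> float:
        return float(2.0 * np.sqrt(self.area / np.pi))

    def offset(self) -> tuple[int, int]:
        return self.bbox[0].start, self.bbox[1].start


def histogram_valley_threshold(
    gray: np.ndarray,
    threshold_level: int = 1,
    smooth_sigma: float = 3.0,
    level_step_fraction: float = 0.02,
    return_threshold: bool = False,
):
    """Binarise by the deepest valley of the smoothed 256-bin histogram.

    The histogram (256 bins over the image's intensity range) is smoothed with
    a Gaussian of ``smooth_sigma`` bins; the cut is the minimum between the
    two dominant smoothed peaks, shifted up by
    ``(threshold_level - 1) * level_step_fraction`` of the dynamic range so
    that higher levels give a more stringent foreground.  Unimodal histograms
    fall back to Otsu with a warning; a constant image yields an empty mask.
    """
    gray = np.asarray(gray, dtype=np.float64)
    lo, hi = float(gray.min()), float(gray.max())
    if hi <= lo:
        warnings.warn("constant image: returning empty mask", stacklevel=2)
        mask = np.zeros(gray.shape, dtype=bool)
        return (mask, np.inf) if return_threshold else mask

    nbins = 256
    hist, edges = np.histogram(gray, bins=nbins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    smoothed = gaussian_filter1d(hist.astype(np.float64), smooth_sigma)

    # dominant modes must be well separated; nearer maxima (e.g. a clipping
    # spike right next to the background hump) belong to the same mode
    peaks = _local_maxima_1d(smoothed, min_distance=30)
    fg_peak = None
    if len(peaks) >= 2:
        # background = the mode holding the most local histogram mass;
        # foreground = the dominant mode on its bright side
        mass = {
            p: float(smoothed[max(0, p - 30) : p + 31].sum()) for p in peaks
        }
        bg_peak = max(peaks, key=lambda p: (mass[p], -p))
        brighter = [p for p in peaks if p >= bg_peak + 30]
        if brighter:
            fg_peak = max(brighter, key=lambda p: (smoothed[p], -p))
    if fg_peak is None:
        warnings.warn("unimodal histogram: falling back to Otsu", stacklevel=2)
        cut = float(threshold_otsu(gray, nbins=nbins))
    else:
        between = smoothed[bg_peak : fg_peak + 1]
        low = np.nonzero(between <= between.min() + 1e-12)[0]
        valley = bg_peak + int(low[len(low) // 2])  # middle of a flat valley
        cut = float(centers[valley])
    cut += (threshold_level - 1) * level_step_fraction * (hi - lo)
    mask = gray > cut
    return (mask, cut) if return_threshold else mask


def _local_maxima_1d(y: np.ndarray, min_distance: int = 1) -> list[int]:
    """Indices of local maxima of y (endpoints included), thinned greedily."""
    idx = [i for i in range(1, len(y) - 1) if y[i] >= y[i - 1] and y[i] > y[i + 1] and y[i] > 0]
    if len(y) >= 2 and y[0] > y[1]:
        idx.append(0)
    if len(y) >= 2 and y[-1] > y[-2] and y[-1] > 0:
        idx.append(len(y) - 1)
    idx.sort(key=lambda i: (-y[i], i))
    kept: list[int] = []
    for i in idx:
        if all(abs(i - j) >= min_distance for j in kept):
            kept.append(i)
    return sorted(kept)


def fill_gaps(mask: np.ndarray, max_gap: int = 1000) -> np.ndarray:
    """Fill enclosed background gaps strictly smaller than ``max_gap`` pixels.

    Background components are 4-connected (the dual of the 8-connected
    foreground); components touching the image border are never filled, and a
    hole of exactly ``max_gap`` pixels is retained.
    """
    mask = np.asarray(mask).astype(bool)
    bg_labels, n = ndimage.label(~mask, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    if n == 0:
        return mask.copy()
    border = np.zeros(mask.shape, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    touching = np.unique(bg_labels[border & ~mask])
    sizes = np.bincount(bg_labels.ravel(), minlength=n + 1)
    fill = np.ones(n + 1, dtype=bool)
    fill[0] = False
    fill[touching] = False
    fill &= sizes < max_gap
    return mask | fill[bg_labels]


def nearest_seed_split(mask: np.ndarray, seeds: list[tuple[int, int]]) -> np.ndarray:
    """Assign every foreground pixel to its Euclidean-nearest seed.

    Seeds are numbered 1..k in the given order; ties go to the lower seed
    number.  This nearest-seed (Voronoi) partition is the discrete watershed
    of the distance transform: touching structures are split along the ridge
    equidistant from the two seeds.
    """
    mask = np.asarray(mask).astype(bool)
    labels = np.zeros(mask.shape, dtype=np.int32)
    if not seeds:
        return labels
    rows, cols = np.nonzero(mask)
    seed_arr = np.asarray(seeds, dtype=np.float64)
    d2 = (rows[:, None] - seed_arr[None, :, 0]) ** 2 + (cols[:, None] - seed_arr[None, :, 1]) ** 2
    labels[rows, cols] = np.argmin(d2, axis=1) + 1  # argmin ties -> lower index
    return labels


def segment_primary(mask: np.ndarray, config: SegmentationConfig) -> np.ndarray:
    """Label structures: opening -> EDT seeds -> nearest-seed split -> size filter.

    The singular opening (disk of ``opening_radius``) suppresses thin
    appendages and noise before seed detection.  Seeds are regional maxima of
    the opened mask's distance transform at depth at least
    sqrt(min_structure_size / pi) (the radius of the smallest acceptable
    structure), greedily merged so no two seeds lie within ``sensitivity``
    pixels (the deeper maximum wins).  Each 8-connected component of the
    *un-opened* mask is then partitioned among its own seeds by the
    nearest-seed rule, so appendages removed by the opening still belong to
    their structure; a component without any seed receives one at its
    distance-map argmax.  Structures below ``min_structure_size`` are dropped
    and labels are contiguous 1..N in raster order of first appearance.
    """
    mask = np.asarray(mask).astype(bool)
    labels = np.zeros(mask.shape, dtype=np.int32)
    if not mask.any():
        return labels
    opened = ndimage.binary_opening(mask, structure=disk(config.opening_radius))
    edt_open = ndimage.distance_transform_edt(opened) if opened.any() else np.zeros(mask.shape)
    seeds = _detect_seeds(edt_open, config)

    eight = np.ones((3, 3), dtype=int)
    comp, n_comp = ndimage.label(mask, structure=eight)
    seeds_by_comp: dict[int, list[tuple[int, int]]] = {}
    for r, c in seeds:
        seeds_by_comp.setdefault(int(comp[r, c]), []).append((r, c))
    edt_full = None
    next_label = 0
    for sl, idx in zip(ndimage.find_objects(comp), range(1, n_comp + 1)):
        local = comp[sl] == idx
        comp_seeds = [(r - sl[0].start, c - sl[1].start) for r, c in seeds_by_comp.get(idx, [])]
        if not comp_seeds:
            if edt_full is None:
                edt_full = ndimage.distance_transform_edt(mask)
            flat = np.where(local, edt_full[sl], -1.0)
            r, c = np.unravel_index(int(np.argmax(flat)), flat.shape)
            comp_seeds = [(int(r), int(c))]
        if len(comp_seeds) == 1:
            labels[sl][local] = next_label + 1
            next_label += 1
        else:
            part = nearest_seed_split(local, comp_seeds)
            part[part > 0] += next_label
            labels[sl][local] = part[local]
            next_label += len(comp_seeds)

    # size filter, then contiguous relabeling in raster order of first pixel
    flat = labels.ravel()
    sizes = np.bincount(flat, minlength=next_label + 1)
    keep = set(int(v) for v in np.where(sizes >= config.min_structure_size)[0]) - {0}
    vals, first = np.unique(flat, return_index=True)
    ordered = [int(v) for v in vals[np.argsort(first)] if int(v) in keep]
    remap = np.zeros(next_label + 1, dtype=np.int32)
    for new, lab in enumerate(ordered, start=1):
        remap[lab] = new
    return remap[labels]


def _detect_seeds(edt: np.ndarray, config: SegmentationConfig) -> list[tuple[int, int]]:
    """Regional EDT maxima above the depth floor, merged within sensitivity."""
    depth_floor = np.sqrt(config.min_structure_size / np.pi)
    smoothed = ndimage.gaussian_filter(edt, sigma=1.0)
    maxmask = (smoothed == ndimage.maximum_filter(smoothed, size=3)) & (edt >= depth_floor)
    plateau_labels, n_plateaus = ndimage.label(maxmask)
    candidates: list[tuple[float, int, int]] = []
    for idx in range(1, n_plateaus + 1):
        rows, cols = np.nonzero(plateau_labels == idx)
        k = len(rows) // 2
        candidates.append((float(edt[rows[k], cols[k]]), int(rows[k]), int(cols[k])))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    kept: list[tuple[int, int]] = []
    for v, r, c in candidates:
        if all((r - r2) ** 2 + (c - c2) ** 2 >= config.sensitivity**2 for r2, c2 in kept):
            kept.append((r, c))
    return kept


def structures_from_labels(labels: np.ndarray) -> list[Structure]:
    """Split a label map into per-structure bounding-box views."""
    out: list[Structure] = []
    objects = ndimage.find_objects(labels)
    for i, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        out.append(Structure(label=i, bbox=sl, mask=labels[sl] == i))
    return out


def focus_adjust_threshold(
    stack_gray: np.ndarray,
    labels: np.ndarray,
    base_mask: np.ndarray,
    config: SegmentationConfig,
) -> tuple[np.ndarray, dict[int, int]]:
    """Refine each structure's threshold on its own focus plane.

    The focus plane of a structure is the z-plane maximising the intensity
    variance over the structure's pixels.  The valley threshold is then
    recomputed on that plane restricted to the structure's bounding box and
    the structure's foreground pixels re-evaluated inside its own watershed
    region, so the number of structures never changes.  Depth-1 stacks are
    returned unchanged.

    Returns the adjusted mask and a {label: focus_plane} map.
    """
    stack_gray = np.asarray(stack_gray, dtype=np.float64)
    if stack_gray.ndim != 3:
        raise ValueError("stack_gray must be (planes, H, W)")
    base_mask = np.asarray(base_mask).astype(bool)
    if stack_gray.shape[0] == 1:
        return base_mask.copy(), {
            int(l): 0 for l in np.unique(labels) if l != 0
        }

    out = base_mask & (labels == 0)  # pixels outside any structure keep as-is
    focus: dict[int, int] = {}
    for struct in structures_from_labels(labels):
        sl = struct.bbox
        region = labels[sl] == struct.label
        sub = stack_gray[(slice(None),) + sl]
        variances = [float(np.var(plane[region])) for plane in sub]
        z = int(np.argmax(variances))
        focus[struct.label] = z
        plane = sub[z]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            local, cut = histogram_valley_threshold(
                plane,
                config.threshold_level,
                config.hist_smooth_sigma,
                config.level_step_fraction,
                return_threshold=True,
            )
        refined = local & region
        if not refined.any():
            refined = base_mask[sl] & region  # keep original rather than lose it
        out[sl] |= refined
    return out, focus


def segment_cells(
    structure: Structure, channel_image: np.ndarray, config: SegmentationConfig
) -> np.ndarray:
    """Label individual cells inside one structure for one channel.

    Otsu's threshold is computed on the channel intensities of the structure's
    own pixels (256 bins).  If the separation between the two Otsu classes is
    below ``min_cell_contrast`` gray levels the channel is treated as empty
    (thresholding pure noise would otherwise fabricate cells).  An adaptive
    opening (disk radius = adaptive_kernel_scale x equivalent diameter, min
    1 px) cleans the foreground for seed detection; cells are then the
    nearest-seed partition of the un-opened Otsu foreground, so cell areas
    are the thresholded areas.  Foreground components without any seed stay
    unlabeled; cells below ``min_cell_size`` pixels are dropped.

    Returns a label map local to the structure's bounding box.
    """
    sub = np.asarray(channel_image, dtype=np.float64)[structure.bbox]
    values = sub[structure.mask]
    zeros = np.zeros(structure.mask.shape, dtype=np.int32)
    if values.size == 0 or values.max() <= values.min():
        structure.flags.append("uniform_channel")
        return zeros
    try:
        cut = float(threshold_otsu(values, nbins=256))
    except ValueError:
        structure.flags.append("uniform_channel")
        return zeros
    fg_vals = values[values > cut]
    bg_vals = values[values <= cut]
    if fg_vals.size == 0 or bg_vals.size == 0 or (
        float(fg_vals.mean()) - float(bg_vals.mean()) < config.min_cell_contrast
    ):
        structure.flags.append("low_contrast_channel")
        return zeros
    fg = (sub > cut) & structure.mask
    if not fg.any():
        return zeros

    radius = adaptive_kernel_radius(structure, config)
    opened = ndimage.binary_opening(fg, structure=disk(radius))
    seed_base = opened if opened.any() else fg
    edt = ndimage.distance_transform_edt(seed_base)
    maxmask = (edt == ndimage.maximum_filter(edt, size=3)) & seed_base & (edt >= 1.0)
    plateau_labels, n_plateaus = ndimage.label(maxmask)
    candidates: list[tuple[float, int, int]] = []
    for idx in range(1, n_plateaus + 1):
        rows, cols = np.nonzero(plateau_labels == idx)
        k = len(rows) // 2
        candidates.append((float(edt[rows[k], cols[k]]), int(rows[k]), int(cols[k])))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    seeds: list[tuple[int, int]] = []
    for v, r, c in candidates:
        if all((r - r2) ** 2 + (c - c2) ** 2 >= config.cell_merge_distance**2 for r2, c2 in seeds):
            seeds.append((r, c))
    if not seeds:
        return zeros

    # partition each foreground component among its own seeds
    eight = np.ones((3, 3), dtype=int)
    comp, _ = ndimage.label(fg, structure=eight)
    seeds_by_comp: dict[int, list[tuple[int, int]]] = {}
    for r, c in seeds:
        seeds_by_comp.setdefault(int(comp[r, c]), []).append((r, c))
    cells = np.zeros(fg.shape, dtype=np.int32)
    next_label = 0
    for idx, comp_seeds in sorted(seeds_by_comp.items()):
        local = comp == idx
        if len(comp_seeds) == 1:
            cells[local] = next_label + 1
            next_label += 1
        else:
            part = nearest_seed_split(local, comp_seeds)
            part[part > 0] += next_label
            cells[local] = part[local]
            next_label += len(comp_seeds)

    sizes = np.bincount(cells.ravel(), minlength=next_label + 1)
    keep = np.where(sizes >= config.min_cell_size)[0]
    keep = keep[keep != 0]
    remap = np.zeros(sizes.size, dtype=np.int32)
    remap[keep] = np.arange(1, keep.size + 1, dtype=np.int32)
    return remap[cells]


def adaptive_kernel_radius(structure: Structure, config: SegmentationConfig) -> int:
    """Opening radius scaled to the structure: scale x equivalent diameter.

    Floored at 3 px: smaller disk footprints slip through thin strands at
    diagonal orientations (their extent along the diagonal is under 2 px), so
    the opening would fail to separate thin protrusions from the body for
    small structures.  A radius-3 opening still preserves compact blobs of
    radius >= 3.
    """
    return max(3, int(round(config.adaptive_kernel_scale * structure.equivalent_diameter)))


def extract_body_appendages(
    structure: Structure, config: SegmentationConfig
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Split a structure into its opened body and invasive appendages.

    The body is the adaptive morphological opening of the structure mask;
    sub-kernel boundary ripple is absorbed into the body by this construction.
    Appendage components are the 8-connected pieces of (mask minus body) that
    touch the body, cover at least ``min_appendage_size`` pixels and extend at
    least ``min_appendage_length`` pixels away from the body (shallow arcs of
    outline variance fail the length test and are not counted).  If the
    opening empties the mask entirely (thin structures), the whole structure
    is used as the body and flagged.
    """
    radius = adaptive_kernel_radius(structure, config)
    body = ndimage.binary_opening(structure.mask, structure=disk(radius))
    if not body.any():
        structure.flags.append("all_appendage")
        body = structure.mask.copy()
        structure.body, structure.appendages = body, []
        return body, []
    eight = np.ones((3, 3), dtype=int)
    residual = structure.mask & ~body
    res_comp, _ = ndimage.label(residual, structure=eight)
    dist_to_body = ndimage.distance_transform_edt(~body)

    # candidate appendages live beyond the shallow ripple zone next to the
    # body; this disconnects protrusions whose bases are bridged by ripple arcs
    far = residual & (dist_to_body > 2.5)
    far_labels, n_far = ndimage.label(far, structure=eight)
    accepted = [
        idx
        for idx in range(1, n_far + 1)
        if (far_labels == idx).sum() >= config.min_appendage_size
        and float(dist_to_body[far_labels == idx].max()) >= config.min_appendage_length
    ]
    appendages: list[np.ndarray] = []
    if accepted:
        # attach the remaining residual pixels to their nearest accepted
        # candidate, staying within the same residual component
        keep = np.isin(far_labels, accepted)
        _, (ir, ic) = ndimage.distance_transform_edt(~keep, return_indices=True)
        nearest = far_labels[ir, ic]
        for idx in accepted:
            anchor = far_labels == idx
            comp_ids = np.unique(res_comp[anchor])
            piece = residual & (nearest == idx) & np.isin(res_comp, comp_ids)
            appendages.append(piece)
    structure.body, structure.appendages = body, appendages
    return body, appendages
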