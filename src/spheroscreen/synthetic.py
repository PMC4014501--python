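"""Seeded synthetic spheroid fields with exhaustive ground truth.

The generator emulates low-magnification fluorescence fields of 3D spheroid
cultures: bright blob-like multicellular structures on a dark background, with
variable size, radial deformation (mass phenotype), surface roughness, thin
invasive appendages (stellate phenotype), hollow cores (acinar lumen) and a
sparse second-channel signal of apoptotic "red dots" inside the green bodies,
plus additive Gaussian noise.  Structures are placed with enough spacing that
every planted structure is recoverable by segmentation independently of the
watershed splitting path; a "touching" fixture for the splitting path is
built directly in the tests from overlapping disks.

A multi-well screen generator lays such fields out over wells and positions,
applies per-treatment effects on the phenotype parameters and draws random
well/position offsets for variance-component checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .imaging import ImageStack


@dataclass
class PhenotypeSpec:
    """Parameters of one synthetic field; defaults model an untreated culture.

    Geometry is in pixels, intensities in 8-bit gray levels.
    """

    height: int = 512
    width: int = 672
    n_structures: int = 25
    radius_mean: float = 18.0
    radius_sd: float = 3.0
    radius_min: float = 10.0
    deform_amp: float = 0.08       # low-frequency radial deformation (fraction of R)
    roughness_amp: float = 0.02    # high-frequency surface ripple (fraction of R)
    appendage_mean: float = 1.5    # Poisson rate of invasive protrusions
    appendage_max: int = 4
    appendage_length: tuple[float, float] = (12.0, 28.0)
    appendage_half_width: float = 1.6
    hollow_fraction: float = 0.2   # probability of a hollow (lumen-bearing) structure
    core_dim: float = 0.25         # core intensity as a fraction of the rim level
    dot_mean: float = 2.0          # Poisson rate of red apoptotic dots per structure
    dot_radius: float = 3.0
    background: float = 20.0
    rim_level: float = 200.0
    dot_level: float = 220.0
    noise_sd: float = 5.0
    n_planes: int = 1
    defocus_sigma: float = 1.5     # blur per plane of defocus in a z-stack
    min_gap: float = 6.0           # clearance between structure reach envelopes
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.height, self.width) <= 0 or self.n_structures < 0:
            raise ValueError("field dimensions and structure count must be positive")
        if self.radius_mean <= 0 or self.radius_min <= 0:
            raise ValueError("radii must be positive")


@dataclass
class StructureTruth:
    center: tuple[float, float]  # (row, col)
    radius: float
    appendage_count: int
    appendage_lengths: list[float]
    hollow: bool
    dot_count: int
    dot_area: int
    area: int
    focus_plane: int


@dataclass
class GroundTruth:
    structures: list[StructureTruth]
    label_mask: np.ndarray  # planted structure ids, 0 background


def make_field(spec: PhenotypeSpec) -> tuple[ImageStack, GroundTruth]:
    """Render one two-channel field (G: viability, R: apoptotic dots).

    Same spec (same seed) gives a bit-identical stack.  Raises if the
    requested number of structures cannot be packed with the required
    spacing after bounded retries.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width

    # draw structure geometry first; bodies are packed so their deformed
    # envelopes never touch, while appendage directions are chosen afterwards
    # so that no appendage comes close to another structure
    radii = np.clip(
        rng.normal(spec.radius_mean, spec.radius_sd, spec.n_structures),
        spec.radius_min,
        None,
    )
    app_counts = np.minimum(
        rng.poisson(spec.appendage_mean, spec.n_structures), spec.appendage_max
    )
    app_lengths = [
        sorted(rng.uniform(*spec.appendage_length, int(k))) for k in app_counts
    ]
    env = radii * (1 + spec.deform_amp + spec.roughness_amp) + 3
    margin = np.array(
        [
            e + (max(L) + 4 if L else 0.0)
            for e, L in zip(env, app_lengths)
        ]
    )
    centers = _pack_centers(rng, h, w, env, margin, spec.min_gap)
    app_angles = _plant_appendage_angles(
        rng, centers, env, app_lengths, spec.min_gap
    )
    # honour what actually fitted
    app_lengths = [
        [L for L, a in zip(Ls, angs) if a is not None]
        for Ls, angs in zip(app_lengths, app_angles)
    ]
    app_angles = [[a for a in angs if a is not None] for angs in app_angles]

    hollow = rng.random(spec.n_structures) < spec.hollow_fraction
    focus_planes = rng.integers(0, max(1, spec.n_planes), spec.n_structures)

    green = np.full((h, w), spec.background, dtype=np.float64)
    red = np.full((h, w), spec.background, dtype=np.float64)
    label_mask = np.zeros((h, w), dtype=np.int32)
    sprites = []  # (sl, mask, g_level_map, dot_map) for optional z-stack rendering
    truths: list[StructureTruth] = []

    for i in range(spec.n_structures):
        r0, c0 = centers[i]
        sprite, offs, lengths_planted, dot_map, n_dots = _render_structure(
            rng, spec, radii[i], app_lengths[i], app_angles[i], bool(hollow[i])
        )
        sl = (
            slice(offs[0] + int(r0), offs[0] + int(r0) + sprite.shape[0]),
            slice(offs[1] + int(c0), offs[1] + int(c0) + sprite.shape[1]),
        )
        body = sprite > 0
        green[sl] = np.maximum(green[sl], np.where(body, sprite, 0))
        red[sl] = np.maximum(red[sl], np.where(dot_map > 0, spec.dot_level, 0))
        label_mask[sl][body] = i + 1
        sprites.append((sl, sprite, dot_map))
        truths.append(
            StructureTruth(
                center=(float(r0), float(c0)),
                radius=float(radii[i]),
                appendage_count=int(len(lengths_planted)),
                appendage_lengths=[float(x) for x in lengths_planted],
                hollow=bool(hollow[i]),
                dot_count=int(n_dots),
                dot_area=int((dot_map > 0).sum()),
                area=int(body.sum()),
                focus_plane=int(focus_planes[i]),
            )
        )

    channels: dict[str, np.ndarray] = {}
    if spec.n_planes <= 1:
        g = green + rng.normal(0, spec.noise_sd, (h, w))
        r = red + rng.normal(0, spec.noise_sd, (h, w))
        channels["G"] = np.clip(g, 0, 255)[None].astype(np.float64)
        channels["R"] = np.clip(r, 0, 255)[None].astype(np.float64)
    else:
        g_stack = np.empty((spec.n_planes, h, w))
        r_stack = np.empty((spec.n_planes, h, w))
        for z in range(spec.n_planes):
            gz = np.full((h, w), spec.background, dtype=np.float64)
            rz = np.full((h, w), spec.background, dtype=np.float64)
            for i, (sl, sprite, dot_map) in enumerate(sprites):
                sigma = spec.defocus_sigma * abs(z - truths[i].focus_plane)
                s = ndimage.gaussian_filter(sprite, sigma) if sigma > 0 else sprite
                d = ndimage.gaussian_filter(
                    np.where(dot_map > 0, spec.dot_level - spec.background, 0.0), sigma
                ) if sigma > 0 else np.where(dot_map > 0, spec.dot_level - spec.background, 0.0)
                gz[sl] = np.maximum(gz[sl], s)
                rz[sl] = np.maximum(rz[sl], spec.background + d)
            g_stack[z] = np.clip(gz + rng.normal(0, spec.noise_sd, (h, w)), 0, 255)
            r_stack[z] = np.clip(rz + rng.normal(0, spec.noise_sd, (h, w)), 0, 255)
        channels["G"] = g_stack
        channels["R"] = r_stack

    return ImageStack(channels, bit_depth=8), GroundTruth(truths, label_mask)


def _pack_centers(
    rng: np.random.Generator,
    h: int,
    w: int,
    env: np.ndarray,
    margin: np.ndarray,
    min_gap: float,
) -> list[tuple[int, int]]:
    """Rejection-sample centres so body envelopes stay ``min_gap`` apart.

    Sequential placement can dead-lock on tight fields, so the whole packing
    is restarted from scratch a bounded number of times before giving up.
    """
    order = np.argsort(-margin)  # place the widest structures first
    for _restart in range(25):
        centers: list[tuple[int, int] | None] = [None] * len(env)
        failed = False
        for idx in order:
            m = int(np.ceil(margin[idx])) + 1
            if m >= h - m or m >= w - m:
                raise ValueError("structure reach exceeds field size")
            for _ in range(2000):
                r = int(rng.integers(m, h - m))
                c = int(rng.integers(m, w - m))
                ok = True
                for jdx, other in enumerate(centers):
                    if other is None:
                        continue
                    if np.hypot(r - other[0], c - other[1]) < env[idx] + env[jdx] + min_gap:
                        ok = False
                        break
                if ok:
                    centers[idx] = (r, c)
                    break
            else:
                failed = True
                break
        if not failed:
            return centers  # type: ignore[return-value]
    raise ValueError(f"could not pack {len(env)} structures into a {h}x{w} field")


def _plant_appendage_angles(
    rng: np.random.Generator,
    centers: list[tuple[int, int]],
    env: np.ndarray,
    app_lengths: list[list[float]],
    min_gap: float,
) -> list[list[float | None]]:
    """Choose appendage directions that keep clear of every other structure.

    An appendage of length L starting at structure i's envelope is accepted
    when every point along its centreline stays at least ``min_gap`` from the
    envelope of every other structure.  Appendages for which no direction is
    found after bounded retries are dropped (the ground truth records what
    was actually planted).
    """
    out: list[list[float | None]] = []
    for i, lengths in enumerate(app_lengths):
        r0, c0 = centers[i]
        chosen: list[float] = []
        result: list[float | None] = []
        for L in lengths:
            found = None
            for _try in range(300):
                a = float(rng.uniform(-np.pi, np.pi))
                if any(
                    min(abs(a - b), 2 * np.pi - abs(a - b)) < 0.9 for b in chosen
                ):
                    continue
                ts = np.linspace(0, env[i] + L + 2, 12)
                py = r0 + ts * np.sin(a)
                px = c0 + ts * np.cos(a)
                ok = True
                for j, (rj, cj) in enumerate(centers):
                    if j == i:
                        continue
                    if np.hypot(py - rj, px - cj).min() < env[j] + min_gap:
                        ok = False
                        break
                if ok:
                    found = a
                    chosen.append(a)
                    break
            result.append(found)
        out.append(result)
    return out


def _render_structure(
    rng: np.random.Generator,
    spec: PhenotypeSpec,
    radius: float,
    lengths: list[float],
    angles: list[float],
    hollow: bool,
):
    """Render one structure sprite; returns (intensity, offset, lengths, dots, n_dots)."""
    reach = radius * (1 + spec.deform_amp + spec.roughness_amp) + (max(lengths) if lengths else 0.0) + 3
    n = int(np.ceil(reach)) * 2 + 3
    cy = cx = n // 2
    yy, xx = np.mgrid[0:n, 0:n]
    dy, dx = yy - cy, xx - cx
    rho = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)

    # radial profile r(theta): low-frequency harmonics plus smoothed ripple
    tgrid = np.linspace(-np.pi, np.pi, 361)
    profile = np.ones_like(tgrid)
    for k in (2, 3, 4):
        profile += (spec.deform_amp / 1.5) * rng.uniform(0.3, 1.0) * np.sin(
            k * tgrid + rng.uniform(0, 2 * np.pi)
        )
    ripple = rng.normal(0, 1.0, 361)
    ripple = ndimage.gaussian_filter1d(ripple, 3, mode="wrap")
    profile += spec.roughness_amp * ripple / max(1e-9, np.abs(ripple).std())
    r_theta = radius * np.interp(theta, tgrid, profile, period=2 * np.pi)
    body = rho <= r_theta

    # appendages: thin rays from the boundary outward, well separated in angle
    for ang, length in zip(angles, lengths):
        base = radius * np.interp(ang, tgrid, profile, period=2 * np.pi)
        steps = np.arange(base - 2.0, base + length, 0.7)
        for s in steps:
            py, px = cy + s * np.sin(ang), cx + s * np.cos(ang)
            body |= (yy - py) ** 2 + (xx - px) ** 2 <= spec.appendage_half_width**2

    level = np.where(body, spec.rim_level, 0.0)
    if hollow:
        core = rho <= 0.5 * radius
        level[body & core] = spec.background + spec.core_dim * (
            spec.rim_level - spec.background
        )

    # red apoptotic dots inside the body, non-overlapping
    n_dots_wanted = int(rng.poisson(spec.dot_mean))
    dot_map = np.zeros_like(level)
    placed: list[tuple[float, float]] = []
    for _ in range(n_dots_wanted):
        for _try in range(200):
            ang = rng.uniform(0, 2 * np.pi)
            rr = rng.uniform(0, 0.65 * radius)
            py, px = cy + rr * np.sin(ang), cx + rr * np.cos(ang)
            if any(np.hypot(py - q[0], px - q[1]) < 2 * spec.dot_radius + 4 for q in placed):
                continue
            dot = (yy - py) ** 2 + (xx - px) ** 2 <= spec.dot_radius**2
            if (dot & ~body).any():
                continue
            dot_map[dot] = 1.0
            placed.append((py, px))
            break
    return level, (-cy, -cx), lengths, dot_map, len(placed)


# ---------------------------------------------------------------------------
# multi-well screens


@dataclass
class ScreenDesign:
    """Layout of a synthetic screen: treatments over wells and positions.

    The study layout this mirrors runs each treatment in triplicate wells
    with four fields (positions) imaged per well.
    """

    treatments: tuple[str, ...] = ("DMSO", "drugA", "drugB")
    control: str = "DMSO"
    wells_per_treatment: int = 3
    positions_per_well: int = 4
    cell_line: str = "PC-3"
    concentration: str = "10uM"
    time_point: str = "d10"
    sigma_well: float = 0.05      # sd of the per-well log-scale size offset
    sigma_position: float = 0.02  # sd of the per-position log-scale size offset


#: Effect models map treatment -> multiplicative factors on PhenotypeSpec
#: fields, e.g. {"drugA": {"dot_mean": 3.0}} for a cytotoxic compound or
#: {"drugB": {"appendage_mean": 0.2, "deform_amp": 0.5}} for an anti-invasive.
EffectModel = dict[str, dict[str, float]]


def make_screen(
    design: ScreenDesign,
    effects: EffectModel,
    base_spec: PhenotypeSpec | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[dict[str, tuple[ImageStack, GroundTruth]], pd.DataFrame, pd.DataFrame]:
    """Generate one field per (well, position) with planted treatment effects.

    Returns (fields by image id, plate map, applied-effects table).  When
    ``out_dir`` is given the fields are also written as multi-page TIFF
    stacks next to plate_map.csv so the batch CLI can run on them.
    """
    base_spec = base_spec or PhenotypeSpec()
    rng = np.random.default_rng(seed)
    fields: dict[str, tuple[ImageStack, GroundTruth]] = {}
    rows = []
    effect_rows = []
    well_no = 0
    for treatment in design.treatments:
        factors = effects.get(treatment, {})
        effect_rows.append({"treatment": treatment, **factors})
        for _ in range(design.wells_per_treatment):
            well_no += 1
            well = f"W{well_no:02d}"
            well_offset = rng.normal(0, design.sigma_well)
            for pos in range(1, design.positions_per_well + 1):
                pos_offset = rng.normal(0, design.sigma_position)
                scale = float(np.exp(well_offset + pos_offset))
                overrides = {}
                for k, v in factors.items():
                    base_val = getattr(base_spec, k)
                    scaled = base_val * v
                    overrides[k] = int(round(scaled)) if isinstance(base_val, int) else scaled
                spec = replace(
                    base_spec,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    **overrides,
                )
                spec = replace(spec, radius_mean=spec.radius_mean * scale)
                image_id = f"{well}_P{pos}"
                fields[image_id] = make_field(spec)
                rows.append(
                    {
                        "image_id": image_id,
                        "well": well,
                        "position": pos,
                        "cell_line": design.cell_line,
                        "treatment": treatment,
                        "concentration": design.concentration,
                        "time_point": design.time_point,
                    }
                )
    plate_map = pd.DataFrame(rows)
    effect_table = pd.DataFrame(effect_rows).fillna(1.0)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for image_id, (stack, _) in fields.items():
            write_field_tiff(stack, out / f"{image_id}.tif")
        plate_map.to_csv(out / "plate_map.csv", index=False)
        truth_rows = []
        for image_id, (_, truth) in fields.items():
            for sid, s in enumerate(truth.structures, start=1):
                truth_rows.append(
                    {
                        "image_id": image_id,
                        "structure_id": sid,
                        "row": s.center[0],
                        "col": s.center[1],
                        "radius": s.radius,
                        "appendages": s.appendage_count,
                        "hollow": s.hollow,
                        "dots": s.dot_count,
                        "dot_area": s.dot_area,
                        "area": s.area,
                    }
                )
        pd.DataFrame(truth_rows).to_csv(out / "ground_truth.csv", index=False)
    return fields, plate_map, effect_table


def write_field_tiff(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as a multi-page RGB TIFF (pages = z-planes)."""
    h, w = stack.height, stack.width
    depth = max(stack.depth(c) for c in stack.channels)
    pages = np.zeros((depth, h, w, 3), dtype=np.uint8)
    order = {"R": 0, "G": 1, "B": 2, "gray": 1}
    for c, arr in stack.channels.items():
        idx = order.get(c, 1)
        a = np.clip(arr, 0, 255).astype(np.uint8)
        for z in range(depth):
            pages[z, :, :, idx] = a[min(z, a.shape[0] - 1)]
    tifffile.imwrite(path, pages, photometric="rgb")
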