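"""Image input, projection, grayscale conversion, normalisation and denoising.

Confocal fields arrive as multi-page TIFF stacks (one page per z-plane,
optionally RGB per page) or as pre-projected 2D images.  Everything downstream
of this module works on 2D arrays: stacks are reduced by an intensity
projection (average by default), multi-channel projections are collapsed to a
weighted grayscale image, and intensities are optionally re-spread by
percentile normalisation before thresholding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import imageio.v3 as iio
from scipy import ndimage


class FormatError(ValueError):
    """Raised when an input file does not decode to a consistent stack."""


@dataclass
class ImageStack:
    """Per-channel 3D voxel arrays sharing XY dimensions.

    channels maps a channel id ("R", "G", "B" or "gray") to an array of shape
    (planes, height, width).  2D inputs become depth-1 stacks.
    """

    channels: dict[str, np.ndarray]
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("ImageStack needs at least one channel")
        shapes = {c: a.shape for c, a in self.channels.items()}
        hw = {(h, w) for (_, h, w) in shapes.values()}
        if len(hw) != 1:
            raise FormatError(f"channels disagree on XY size: {shapes}")
        for c, a in self.channels.items():
            if a.ndim != 3 or a.shape[0] < 1:
                raise FormatError(f"channel {c!r} is not a (planes, H, W) array")

    @property
    def height(self) -> int:
        return next(iter(self.channels.values())).shape[1]

    @property
    def width(self) -> int:
        return next(iter(self.channels.values())).shape[2]

    def depth(self, channel: str) -> int:
        return self.channels[channel].shape[0]


@dataclass
class ProjectedImage:
    """2D per-channel projections plus their weighted grayscale collapse."""

    color: dict[str, np.ndarray]
    gray: np.ndarray
    weights: dict[str, float] = field(default_factory=dict)


_CHANNEL_NAMES = ("R", "G", "B")


def load_image(path: str | Path, layout: str = "auto") -> ImageStack:
    """Read a TIFF/PNG/JPEG file into an :class:`ImageStack`.

    layout:
      "auto"        -- pages are z-planes; an RGB last axis becomes channels
      "planes-gray" -- force a 3D page series to a single gray channel
      "pages-rgb"   -- force exactly 3 pages to be the R, G, B channels
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoder-specific exceptions vary
        raise FormatError(f"cannot decode {path}: {exc}") from exc
    return stack_from_array(np.asarray(arr), layout=layout)


def stack_from_array(arr: np.ndarray, layout: str = "auto") -> ImageStack:
    """Build an ImageStack from a decoded array of 2-4 dimensions."""
    bit_depth = 16 if arr.dtype.itemsize >= 2 and arr.dtype.kind in "ui" else 8
    if arr.ndim == 2:
        return ImageStack({"gray": arr[None]}, bit_depth)
    if arr.ndim == 3:
        if layout == "pages-rgb":
            if arr.shape[0] != 3:
                raise FormatError("pages-rgb layout needs exactly 3 pages")
            return ImageStack(
                {c: arr[i][None] for i, c in enumerate(_CHANNEL_NAMES)}, bit_depth
            )
        if layout != "planes-gray" and arr.shape[-1] in (3, 4):
            # single RGB(A) page
            return ImageStack(
                {c: arr[None, :, :, i] for i, c in enumerate(_CHANNEL_NAMES)},
                bit_depth,
            )
        return ImageStack({"gray": arr}, bit_depth)
    if arr.ndim == 4:
        if arr.shape[-1] not in (3, 4):
            raise FormatError(f"cannot interpret 4D array of shape {arr.shape}")
        return ImageStack(
            {c: arr[:, :, :, i] for i, c in enumerate(_CHANNEL_NAMES)}, bit_depth
        )
    raise FormatError(f"cannot interpret array of shape {arr.shape}")


def average_projection(stack: ImageStack) -> ProjectedImage:
    """Average intensity projection, applied to each channel separately."""
    return _project(stack, np.mean)


def max_projection(stack: ImageStack) -> ProjectedImage:
    """Maximum intensity projection across z, per channel."""
    return _project(stack, np.max)


def _project(stack: ImageStack, reducer) -> ProjectedImage:
    color = {c: reducer(a.astype(np.float64), axis=0) for c, a in stack.channels.items()}
    w = {c: 1.0 / len(color) for c in color}
    return ProjectedImage(color=color, gray=to_grayscale(color, w), weights=w)


def to_grayscale(
    color: dict[str, np.ndarray], weights: dict[str, float] | None = None
) -> np.ndarray:
    """Collapse per-channel 2D arrays to one gray image by weighted sum.

    Weights default to equal across the present channels and are normalised to
    sum to 1 internally.
    """
    if weights is None:
        weights = {c: 1.0 for c in color}
    total = float(sum(weights.get(c, 0.0) for c in color))
    if total <= 0:
        raise ValueError("channel weights must have a positive sum")
    out = np.zeros(next(iter(color.values())).shape, dtype=np.float64)
    for c, img in color.items():
        w = weights.get(c, 0.0) / total
        if w:
            out += w * np.asarray(img, dtype=np.float64)
    return out


def percentile_normalize(
    image: np.ndarray,
    low: float = 5.0,
    high: float = 95.0,
    full_scale: float | None = None,
) -> np.ndarray:
    """Clip at the low/high percentiles and rescale linearly to [0, full_scale].

    The defaults discard the 5th and 95th percentile tails.  A constant image
    (no spread between the two percentiles) is returned unchanged.
    """
    if not (0 <= low < high <= 100):
        raise ValueError("need 0 <= low < high <= 100")
    image = np.asarray(image, dtype=np.float64)
    if full_scale is None:
        full_scale = 255.0
    lo, hi = np.percentile(image, [low, high])
    if hi <= lo:
        return image.copy()
    return np.clip((image - lo) / (hi - lo), 0.0, 1.0) * full_scale


def denoise(
    image: np.ndarray,
    method: str = "median",
    size: int = 3,
    sigma: float = 1.0,
    amount: float = 1.0,
) -> np.ndarray:
    """Apply one of the supported noise filters.

    method "gaussian" uses `sigma`, "median" uses the odd window `size`, and
    "edge_enhance" is an unsharp mask (image + amount * (image - blurred)).
    """
    image = np.asarray(image, dtype=np.float64)
    if method == "gaussian":
        return ndimage.gaussian_filter(image, sigma=sigma)
    if method == "median":
        if size < 1 or size % 2 == 0:
            raise ValueError("median window size must be odd and >= 1")
        return ndimage.median_filter(image, size=size, mode="nearest")
    if method == "edge_enhance":
        blurred = ndimage.gaussian_filter(image, sigma=sigma)
        return image + amount * (image - blurred)
    raise ValueError(f"unknown denoise method {method!r}")


def flatten_background(image: np.ndarray, window: int = 101) -> np.ndarray:
    """Subtract a large-kernel median background estimate (phase contrast).

    The median is computed on a 4x-downsampled copy and upsampled back, a
    close approximation that avoids the quadratic cost of a full-size large
    median window.  Output is clipped at zero.
    """
    image = np.asarray(image, dtype=np.float64)
    step = 4 if min(image.shape) >= 64 else 1
    small = image[::step, ::step]
    bg_small = ndimage.median_filter(small, size=max(3, window // step), mode="nearest")
    if step > 1:
        bg = ndimage.zoom(bg_small, (image.shape[0] / bg_small.shape[0],
                                     image.shape[1] / bg_small.shape[1]), order=1)
        bg = bg[: image.shape[0], : image.shape[1]]
    else:
        bg = bg_small
    return np.clip(image - bg, 0.0, None)


def phase_contrast_prepare(image: np.ndarray, window: int = 101) -> np.ndarray:
    """Pre-process a phase-contrast image for the valley thresholding path.

    Background flattening followed by a mild median filter; the result has the
    dark-background / bright-structure polarity the thresholder expects.
    """
    flat = flatten_background(image, window=window)
    return denoise(flat, "median", size=3)
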