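"""Dual-threshold density measurement on grayscale mammogram-like images.

The measurement mimics computer-assisted thresholding of a digitised
film mammogram (12-bit intensities): a first, lower threshold separates
the breast from the background (the superlevel set at that intensity is
the breast), and a second, higher threshold delimits the dense tissue.
Density at increasing thresholds gives nested superlevel regions -- the
conventional, higher and highest-threshold measures -- whose areas are
weakly decreasing.

Pixel inclusion is by ``intensity >= threshold`` (inclusive) for both
thresholds; this convention is fixed and documented here because the
original interactive software does not state one.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

__all__ = [
    "GrayImage",
    "ThresholdPair",
    "DensityMeasure",
    "measure_density",
    "measure_nested",
    "synth_mammogram",
    "read_image",
]


class ImagingError(ValueError):
    pass


@dataclasses.dataclass
class GrayImage:
    """2-D integer intensity array with bit depth and physical pixel spacing."""

    pixels: np.ndarray
    bit_depth: int = 12
    pixel_spacing: float = 0.01  # cm per pixel side

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ImagingError("pixels must be a 2-D array")
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise ImagingError("pixels must be integer-valued")
        if self.pixel_spacing <= 0:
            raise ImagingError("pixel_spacing must be positive")
        top = 2 ** self.bit_depth
        if self.pixels.min() < 0 or self.pixels.max() >= top:
            raise ImagingError(
                f"intensities must lie in [0, {top - 1}] for bit depth {self.bit_depth}")

    @property
    def pixel_area(self) -> float:
        return self.pixel_spacing ** 2


@dataclasses.dataclass
class ThresholdPair:
    background_threshold: int
    density_threshold: int

    def __post_init__(self):
        if self.background_threshold > self.density_threshold:
            raise ImagingError("background threshold must not exceed density threshold")


@dataclasses.dataclass
class DensityMeasure:
    """Areas in cm^2 and the derived percent density."""

    dense_area: float
    total_area: float

    def __post_init__(self):
        if self.total_area <= 0:
            raise ImagingError("total (breast) area must be positive")
        if self.dense_area > self.total_area + 1e-12:
            raise ImagingError("dense area cannot exceed total area")

    @property
    def nondense_area(self) -> float:
        return self.total_area - self.dense_area

    @property
    def percent_density(self) -> float:
        return 100.0 * self.dense_area / self.total_area


def _largest_component_mask(mask: np.ndarray) -> np.ndarray:
    from scipy import ndimage

    labels, n = ndimage.label(mask)
    if n <= 1:
        return mask
    counts = np.bincount(labels.ravel())[1:]
    return labels == (1 + int(np.argmax(counts)))


def measure_density(img: GrayImage, thr: ThresholdPair,
                    largest_component: bool = False) -> DensityMeasure:
    """Total and dense areas from the two superlevel sets.

    total = #{pixels >= background threshold} * spacing^2,
    dense = #{pixels >= density threshold} * spacing^2.  An empty breast
    mask is an error, never a silent 0%.
    """
    top = 2 ** img.bit_depth
    for t in (thr.background_threshold, thr.density_threshold):
        if not 0 <= t < top:
            raise ImagingError(f"threshold {t} outside intensity range [0, {top - 1}]")
    breast = img.pixels >= thr.background_threshold
    if largest_component:
        breast = _largest_component_mask(breast)
    n_total = int(breast.sum())
    if n_total == 0:
        raise ImagingError(
            f"no pixels at or above background threshold {thr.background_threshold}: "
            "empty breast mask")
    dense = breast & (img.pixels >= thr.density_threshold)
    return DensityMeasure(dense_area=int(dense.sum()) * img.pixel_area,
                          total_area=n_total * img.pixel_area)


def measure_nested(img: GrayImage, bg_threshold: int,
                   density_thresholds: Sequence[int],
                   largest_component: bool = False) -> list[DensityMeasure]:
    """Density at a weakly increasing ladder of thresholds over one breast mask.

    Thresholds must be sorted ascending and all >= the background
    threshold; the resulting dense areas are weakly decreasing and share
    one total area.
    """
    ts = list(density_thresholds)
    if any(b > a for b, a in zip(ts, ts[1:])):
        raise ImagingError(f"density thresholds must be ascending, got {ts}")
    if ts and ts[0] < bg_threshold:
        raise ImagingError("density thresholds must be >= the background threshold")
    return [measure_density(img, ThresholdPair(bg_threshold, t),
                            largest_component=largest_component) for t in ts]


@dataclasses.dataclass
class Region:
    """Axis-aligned rectangle (row0, col0, height, width) at an intensity."""

    row: int
    col: int
    height: int
    width: int
    intensity: int


def synth_mammogram(shape: tuple[int, int], regions: Sequence[Region],
                    background: int = 0, noise_sd: float = 0.0,
                    seed=None, bit_depth: int = 12,
                    pixel_spacing: float = 0.01):
    """Phantom image with known per-region ground truth.

    Regions must fit inside the canvas and are drawn in order.  A brighter
    region may be painted inside a dimmer one (nested superlevel
    structure); overlap at an intensity at or below what is already
    painted is rejected as contradictory ground truth.  Gaussian noise of
    the given SD is added and intensities clipped to the bit depth.

    Returns ``(GrayImage, counts)`` where ``counts[i]`` is region i's
    pixel count.
    """
    h, w = shape
    canvas = np.full((h, w), background, dtype=np.int64)
    occupied = np.full((h, w), -1, dtype=np.int64)  # intensity already painted
    counts = []
    for reg in regions:
        if reg.row < 0 or reg.col < 0 or reg.row + reg.height > h or reg.col + reg.width > w:
            raise ImagingError(f"region {reg} does not fit in canvas {shape}")
        sl = (slice(reg.row, reg.row + reg.height), slice(reg.col, reg.col + reg.width))
        prev = occupied[sl]
        clash = (prev >= 0) & (prev > reg.intensity)
        if clash.any():
            raise ImagingError(
                f"region {reg} overlaps an already-painted brighter region of "
                f"intensity {int(prev[clash][0])}: contradictory ground truth")
        canvas[sl] = reg.intensity
        occupied[sl] = reg.intensity
        counts.append(reg.height * reg.width)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        canvas = np.rint(canvas + rng.normal(0.0, noise_sd, size=canvas.shape)).astype(np.int64)
    canvas = np.clip(canvas, 0, 2 ** bit_depth - 1)
    return GrayImage(pixels=canvas, bit_depth=bit_depth,
                     pixel_spacing=pixel_spacing), counts


def read_image(path, bit_depth: int = 12, pixel_spacing: float = 0.01) -> GrayImage:
    """Read a grayscale PNG/TIFF (8- or 16-bit container, data right-aligned)."""
    from PIL import Image

    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.ndim == 3:
        if arr.shape[2] > 1 and not np.all(arr[..., 0:1] == arr[..., :3]):
            raise ImagingError(f"{path}: not a grayscale image")
        arr = arr[..., 0]
    arr = arr.astype(np.int64)
    if arr.max() >= 2 ** bit_depth:
        raise ImagingError(
            f"{path}: intensities exceed declared bit depth {bit_depth}")
    return GrayImage(pixels=arr, bit_depth=bit_depth, pixel_spacing=pixel_spacing)
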