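"""Nuclei counting on 2D grayscale images: threshold, label, area-filter.

Re-implements the classic "analyze particles" workflow used for
DAPI-stained cell-density patches: binarize at a fixed global threshold,
label connected components (8-connectivity by default), discard components
below a minimum area, and report counts, centroids and areas in physical
units.  Density over a measurement rectangle counts a nucleus if its
centroid falls inside the half-open rectangle, so adjacent rectangles never
double-count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage import filters, measure

from .errors import ParameterError


@dataclass
class NucleiImage:
    """A 2D grayscale image with intensities in [0, 1] and a pixel size in μm."""

    pixels: np.ndarray
    pixel_size: float = 1.0  # μm per pixel

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ParameterError("pixels must be a non-empty 2D array")
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be positive")

    @property
    def shape_um(self) -> tuple[float, float]:
        return (self.pixels.shape[0] * self.pixel_size,
                self.pixels.shape[1] * self.pixel_size)


@dataclass
class ParticleResult:
    """Labelled particles surviving the area filter."""

    count: int
    centroids: np.ndarray  # (n, 2) in μm, (row, col) order
    areas: np.ndarray  # μm²
    mask: np.ndarray  # binary grid after thresholding (pre-filter)


def count_nuclei(image: NucleiImage, threshold: float = 0.5,
                 min_area: float = 0.0, connectivity: int = 8,
                 otsu: bool = False) -> ParticleResult:
    """Count bright particles: binarize, label, filter by area.

    Parameters
    ----------
    image
        Grayscale image with intensities in [0, 1].
    threshold
        Global intensity cut; pixels ≥ threshold are foreground.  Ignored
        when ``otsu=True``, in which case Otsu's method picks the cut.
    min_area
        Minimum particle area in μm²; smaller components are discarded.
    connectivity
        4 (edge-adjacent) or 8 (edge- or corner-adjacent, the particle
        analysis default).
    """
    if not otsu and not (0.0 < threshold < 1.0):
        raise ParameterError(f"threshold must be in (0, 1), got {threshold}")
    if min_area < 0:
        raise ParameterError("min_area must be non-negative")
    if connectivity not in (4, 8):
        raise ParameterError(f"connectivity must be 4 or 8, got {connectivity}")
    if otsu:
        threshold = float(filters.threshold_otsu(image.pixels))
    mask = image.pixels >= threshold
    if mask.all():
        warnings.warn(
            "image saturated at threshold: a single component spans the frame",
            stacklevel=2,
        )
    labels = measure.label(mask, connectivity=1 if connectivity == 4 else 2)
    px_area = image.pixel_size ** 2
    centroids, areas = [], []
    for region in measure.regionprops(labels):
        area_um2 = region.area * px_area
        if area_um2 < min_area:
            continue
        centroids.append(np.asarray(region.centroid) * image.pixel_size)
        areas.append(area_um2)
    return ParticleResult(
        count=len(areas),
        centroids=np.array(centroids, dtype=float).reshape(-1, 2),
        areas=np.array(areas, dtype=float),
        mask=mask,
    )


def density_from_image(image: NucleiImage, rect: tuple[float, float, float, float],
                       threshold: float = 0.5, min_area: float = 0.0,
                       connectivity: int = 8) -> float:
    """Nuclei per μm² inside a measurement rectangle.

    ``rect`` is (row0, col0, row1, col1) in μm; a particle is counted if its
    centroid lies in the half-open rectangle [row0, row1) × [col0, col1).
    """
    r0, c0, r1, c1 = rect
    h_um, w_um = image.shape_um
    if not (0 <= r0 < r1 <= h_um and 0 <= c0 < c1 <= w_um):
        raise ParameterError(
            f"rect {rect} falls outside the {h_um:g}x{w_um:g} μm image or is empty"
        )
    result = count_nuclei(image, threshold=threshold, min_area=min_area,
                          connectivity=connectivity)
    if result.count == 0:
        return 0.0
    inside = (
        (result.centroids[:, 0] >= r0) & (result.centroids[:, 0] < r1)
        & (result.centroids[:, 1] >= c0) & (result.centroids[:, 1] < c1)
    )
    area = (r1 - r0) * (c1 - c0)
    return float(inside.sum()) / area
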