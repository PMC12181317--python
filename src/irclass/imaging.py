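"""FT-IR spectroscopic image handling: mosaics, outlier filtering, contrast
images and mean spectra."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GridError, SpectralImage, Spectrum, SpectrumSet
from .preprocessing import area_normalize

__all__ = [
    "ImageFilterSpec",
    "assemble_mosaic",
    "filter_image_outliers",
    "contrast_image",
    "mean_spectrum",
]


@dataclass
class ImageFilterSpec:
    """Outlier rules for FPA pixel spectra.

    A pixel is rejected when the sum of its absorbance values is below
    ``sum_threshold`` (strict) or the absorbance at the amide-I band is below
    ``amide_threshold`` (strict).  The default sum threshold of 20 is
    meaningful only on raw transmission-mode spectra; it scales with the
    number of grid points and is therefore a configurable default, not a
    constant.
    """

    sum_threshold: float = 20.0
    amide_wavenumber: float = 1650.0
    amide_threshold: float = 0.01

    def __post_init__(self) -> None:
        if self.sum_threshold < 0 or self.amide_threshold < 0:
            raise ValueError("thresholds must be nonnegative")


def assemble_mosaic(
    tiles: list[SpectralImage], layout: tuple[int, int]
) -> SpectralImage:
    """Place 64×64 FPA tiles row-major into a (rows, cols) mosaic.

    Pixel (r, c) of tile (i, j) lands at mosaic pixel (64·i + r, 64·j + c).
    """
    rows, cols = layout
    if len(tiles) != rows * cols:
        raise ValueError(f"layout {layout} needs {rows * cols} tiles, got {len(tiles)}")
    first = tiles[0]
    th, tw = first.spatial_shape
    for t in tiles:
        if t.spatial_shape != (th, tw):
            raise ValueError("all tiles must share one spatial shape")
        if t.grid != first.grid:
            raise GridError("all tiles must share one wavenumber grid")
    cube = np.zeros((rows * th, cols * tw, len(first.grid)))
    mask = np.zeros((rows * th, cols * tw), dtype=bool)
    for k, t in enumerate(tiles):
        i, j = divmod(k, cols)
        cube[i * th:(i + 1) * th, j * tw:(j + 1) * tw] = t.cube
        mask[i * th:(i + 1) * th, j * tw:(j + 1) * tw] = t.outlier_mask
    return SpectralImage(cube=cube, grid=first.grid,
                         pixel_size_um=first.pixel_size_um, outlier_mask=mask)


def filter_image_outliers(image: SpectralImage, spec: ImageFilterSpec) -> SpectralImage:
    """Mark outlier pixels (gaps, empty measurement points) in the mask.

    Cube values are left untouched; rejected pixels only get mask = True and
    are rendered white downstream.
    """
    amide_idx = image.grid.nearest_index(spec.amide_wavenumber)
    if abs(image.grid.values[amide_idx] - spec.amide_wavenumber) > 3.0:
        raise GridError("grid has no point within 3 cm-1 of the amide-I band")
    sums = image.cube.sum(axis=2)
    amide = image.cube[:, :, amide_idx]
    mask = (sums < spec.sum_threshold) | (amide < spec.amide_threshold)
    return SpectralImage(cube=image.cube, grid=image.grid,
                         pixel_size_um=image.pixel_size_um,
                         outlier_mask=image.outlier_mask | mask)


def contrast_image(
    image: SpectralImage, lo: float = 950.0, hi: float = 1800.0
) -> np.ndarray:
    """Per-pixel absorbance sum over the closed interval [lo, hi].

    Masked pixels come out as NaN (rendered white).
    """
    idx = image.grid.window_indices(lo, hi)
    if idx.size == 0:
        raise GridError(f"range [{lo}, {hi}] contains no grid points")
    out = image.cube[:, :, idx].sum(axis=2)
    out[image.outlier_mask] = np.nan
    return out


def mean_spectrum(
    source: SpectrumSet | SpectralImage,
    area_normalize_first: bool = True,
    norm_range: tuple[float, float] = (950.0, 1800.0),
) -> tuple[Spectrum, Spectrum]:
    """Per-wavenumber mean µ and sample standard deviation σ (n−1).

    For an image, only unmasked pixels enter.  When ``area_normalize_first``
    each spectrum is area-normalized over ``norm_range`` before averaging, as
    is standard for section-thickness compensation.
    """
    if isinstance(source, SpectralImage):
        keep = ~source.outlier_mask
        mat = source.cube[keep]
        grid = source.grid
    else:
        mat = source.to_matrix()
        grid = source.grid
    if mat.shape[0] < 1:
        raise ValueError("need at least one spectrum")
    if area_normalize_first:
        idx = grid.window_indices(*norm_range)
        areas = mat[:, idx].sum(axis=1)
        if np.any(areas <= 0):
            raise ValueError("nonpositive area in at least one spectrum")
        mat = mat / areas[:, None]
    mu = mat.mean(axis=0)
    if mat.shape[0] < 2:
        raise ValueError("need at least two spectra for a standard deviation")
    sigma = mat.std(axis=0, ddof=1)
    from .core import SpectrumMeta

    return (
        Spectrum(grid, mu, SpectrumMeta(patient_id="-", class_label="unknown")),
        Spectrum(grid, sigma, SpectrumMeta(patient_id="-", class_label="unknown")),
    )
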