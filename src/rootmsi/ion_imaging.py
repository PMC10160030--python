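"""Single-ion images, %TIC normalization and per-pixel ratio images.

Each peak in the acquired spectra corresponds to one MS image: the image
value at a pixel is the summed intensity inside a relative mass window
``target_mz * (1 +- ppm * 1e-6)`` (both ends inclusive). Images are either
raw window sums or normalized per pixel as a percentage of that pixel's
total ion current (TIC). Both modes are first-class: TIC normalization is
susceptible to matrix effects, and the unnormalized images are how one
checks that normalization did not invent a distribution pattern.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .imzml_io import MSIDataset, PixelSpectrum, RasterGeometry

__all__ = [
    "IonImage",
    "RatioImage",
    "pixel_tic",
    "extract_window",
    "build_ion_image",
    "ratio_image",
    "tic_image",
    "write_grid",
    "read_grid",
]


def pixel_tic(spectrum: PixelSpectrum) -> float:
    """Total ion current of one pixel: the sum of all its intensities."""
    return spectrum.tic


def extract_window(
    spectrum: PixelSpectrum, target_mz: float, tolerance_ppm: float
) -> float:
    """Summed intensity in the inclusive window target_mz*(1 +- ppm*1e-6).

    Binary search over the ascending m/z array; peaks exactly on a window
    boundary are included.
    """
    if spectrum.mz_values.size == 0:
        return 0.0
    half = target_mz * tolerance_ppm * 1e-6
    lo = np.searchsorted(spectrum.mz_values, target_mz - half, side="left")
    hi = np.searchsorted(spectrum.mz_values, target_mz + half, side="right")
    if hi <= lo:
        return 0.0
    return float(spectrum.intensities[lo:hi].sum())


@dataclass
class IonImage:
    """2D intensity map of one m/z window over the raster."""

    values: np.ndarray
    target_mz: float
    tolerance_ppm: float
    normalization: str  # "none" | "tic_percent"
    source_id: str = ""
    geometry: RasterGeometry | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("ion image values must be 2D")
        if self.normalization not in {"none", "tic_percent"}:
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if np.any(self.values < 0):
            raise ValueError("ion image values must be non-negative")
        if self.normalization == "tic_percent" and np.any(self.values > 100 + 1e-9):
            raise ValueError("tic_percent values must lie in [0, 100]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def build_ion_image(
    dataset: MSIDataset,
    target_mz: float,
    tolerance_ppm: float = 5.0,
    normalization: str = "tic_percent",
) -> IonImage:
    """Per-pixel window intensity over the raster.

    With ``normalization="tic_percent"`` each pixel's value is
    ``100 * window / TIC`` (0 where the pixel TIC is 0); with ``"none"`` the
    raw window sum. A target outside the dataset's acquired m/z range yields
    an all-zero image with a warning rather than an error, so batch
    extraction over a registry proceeds.
    """
    low, high = dataset.geometry.mz_range
    values = np.zeros((dataset.n_rows, dataset.n_cols), dtype=np.float64)
    if not (low <= target_mz <= high):
        warnings.warn(
            f"target m/z {target_mz} outside acquired range [{low}, {high}]; "
            "returning zero image",
            stacklevel=2,
        )
    else:
        for spec in dataset.iter_pixels():
            window = extract_window(spec, target_mz, tolerance_ppm)
            if normalization == "tic_percent":
                tic = spec.tic
                window = 100.0 * window / tic if tic > 0 else 0.0
            values[spec.row_index, spec.col_index] = window
    return IonImage(
        values=values,
        target_mz=target_mz,
        tolerance_ppm=tolerance_ppm,
        normalization=normalization,
        source_id=dataset.metadata.get("source", ""),
        geometry=dataset.geometry,
    )


def tic_image(dataset: MSIDataset) -> np.ndarray:
    """Per-pixel TIC as a 2D array (the reference image for matrix effects)."""
    out = np.zeros((dataset.n_rows, dataset.n_cols), dtype=np.float64)
    for spec in dataset.iter_pixels():
        out[spec.row_index, spec.col_index] = spec.tic
    return out


@dataclass
class RatioImage:
    """Per-pixel ratio of two ion images with a validity mask.

    ``mask`` is True where the denominator fell below the floor and the
    ratio is undefined. Stored values are never clipped; ``scale_max`` only
    caps the color scale at render/export time.
    """

    values: np.ndarray
    numerator_mz: float
    denominator_mz: float
    mask: np.ndarray
    scale_max: float = 11.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("ratio values and mask shapes differ")
        if self.scale_max <= 0:
            raise ValueError("scale_max must be positive")


def ratio_image(
    num: IonImage,
    den: IonImage,
    denominator_floor: float = 0.0,
    scale_max: float = 11.0,
) -> RatioImage:
    """Elementwise num/den with masking where the denominator is at or below
    the floor (default floor 0: zero denominators are masked, never inflated
    by an epsilon)."""
    if num.shape != den.shape:
        raise ValueError(f"shape mismatch: {num.shape} vs {den.shape}")
    if num.normalization != den.normalization:
        raise ValueError(
            "numerator and denominator must share a normalization mode "
            f"({num.normalization!r} vs {den.normalization!r})"
        )
    mask = den.values <= denominator_floor
    values = np.zeros_like(num.values)
    np.divide(num.values, den.values, out=values, where=~mask)
    return RatioImage(
        values=values,
        numerator_mz=num.target_mz,
        denominator_mz=den.target_mz,
        mask=mask,
        scale_max=scale_max,
    )


def write_grid(values: np.ndarray, path, geometry: RasterGeometry | None = None) -> None:
    """Write a 2D grid as delimited text with a two-line header
    (dimensions; pixel geometry)."""
    values = np.asarray(values)
    n_rows, n_cols = values.shape
    if geometry is not None:
        geo = (f"pixel_width_um={geometry.pixel_width_um!r} "
               f"pixel_height_um={geometry.pixel_height_um!r}")
    else:
        geo = "pixel_width_um=unknown pixel_height_um=unknown"
    header = f"n_rows={n_rows} n_cols={n_cols}\n{geo}"
    np.savetxt(path, values, delimiter="\t", header=header, fmt="%.17g")


def read_grid(path) -> np.ndarray:
    return np.loadtxt(path, delimiter="\t", ndmin=2)
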