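"""Background-subtracted average spectra per developmental zone.

For each zone (root tip, meristem, differentiation zone) one raster row is
designated: scans across the on-tissue columns of that row are averaged,
and the background spectrum — averaged from off-tissue scans on the
adjacent glass slide in the same row (default eight scans) — is subtracted,
with negative results floored at zero.

Centroid m/z positions jitter from scan to scan, so averaging accumulates
peaks onto a shared log-spaced axis with a fixed relative (ppm) bin width,
consistent with the ppm windows used for imaging. Two average spectra can
be subtracted only if they were binned with the same anchor and bin width.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imzml_io import MSIDataset

__all__ = [
    "ZoneDefinition",
    "AverageSpectrum",
    "average_scans",
    "subtract_background",
    "zone_average_spectrum",
]


@dataclass(frozen=True)
class ZoneDefinition:
    """One developmental zone: a row, its tissue columns, and glass columns."""

    zone_name: str
    row_index: int
    on_tissue_cols: tuple[int, int]  # inclusive interval
    background_cols: tuple[int, ...]  # off-tissue glass columns

    def __post_init__(self) -> None:
        lo, hi = self.on_tissue_cols
        if lo > hi:
            raise ValueError(f"invalid on-tissue interval {self.on_tissue_cols}")
        if len(self.background_cols) < 1:
            raise ValueError("need at least one background column")
        overlap = [c for c in self.background_cols if lo <= c <= hi]
        if overlap:
            raise ValueError(
                f"background columns {overlap} overlap the on-tissue interval"
            )

    def tissue_columns(self) -> list[int]:
        lo, hi = self.on_tissue_cols
        return list(range(lo, hi + 1))


@dataclass
class AverageSpectrum:
    """Mean spectrum over n scans on a shared ppm-binned axis.

    ``mz_axis`` holds the geometric centers of the occupied bins;
    ``bin_indices``, ``anchor_mz`` and ``bin_ppm`` identify the binning so
    two spectra can be aligned bin-by-bin.
    """

    mz_axis: np.ndarray
    mean_intensity: np.ndarray
    n_scans: int
    bin_indices: np.ndarray
    anchor_mz: float
    bin_ppm: float

    def __post_init__(self) -> None:
        self.mz_axis = np.asarray(self.mz_axis, dtype=np.float64)
        self.mean_intensity = np.asarray(self.mean_intensity, dtype=np.float64)
        self.bin_indices = np.asarray(self.bin_indices, dtype=np.int64)
        if not (len(self.mz_axis) == len(self.mean_intensity) == len(self.bin_indices)):
            raise ValueError("axis, intensity and bin-index lengths differ")
        if self.mz_axis.size and np.any(np.diff(self.mz_axis) <= 0):
            raise ValueError("m/z axis must be strictly ascending")
        if np.any(self.mean_intensity < 0):
            raise ValueError("average intensities must be non-negative")


def _bin_index(mz: np.ndarray, anchor: float, bin_ppm: float) -> np.ndarray:
    width = np.log1p(bin_ppm * 1e-6)
    return np.floor(np.log(mz / anchor) / width).astype(np.int64)


def _bin_center(idx: np.ndarray, anchor: float, bin_ppm: float) -> np.ndarray:
    f = 1.0 + bin_ppm * 1e-6
    return anchor * f ** (idx.astype(np.float64) + 0.5)


def average_scans(
    dataset: MSIDataset,
    row: int,
    cols,
    bin_ppm: float = 5.0,
) -> AverageSpectrum:
    """Mean spectrum over the selected pixels of one row.

    Peaks are accumulated onto bins of relative width ``bin_ppm`` anchored
    at the dataset's low m/z limit; each bin's value is the summed intensity
    divided by the number of scans (a scan without a peak in a bin
    contributes zero there).
    """
    cols = list(cols)
    if not cols:
        raise ValueError("empty column selection")
    if not 0 <= row < dataset.n_rows:
        raise IndexError(f"row {row} out of range")
    for c in cols:
        if not 0 <= c < dataset.n_cols:
            raise IndexError(f"column {c} out of range")

    anchor = dataset.geometry.mz_range[0]
    sums: dict[int, float] = {}
    for c in cols:
        spec = dataset.spectrum(row, c)
        if spec.mz_values.size == 0:
            continue
        for idx, inten in zip(
            _bin_index(spec.mz_values, anchor, bin_ppm), spec.intensities
        ):
            sums[int(idx)] = sums.get(int(idx), 0.0) + float(inten)
    n_scans = len(cols)
    indices = np.array(sorted(sums), dtype=np.int64)
    means = np.array([sums[i] / n_scans for i in indices])
    return AverageSpectrum(
        mz_axis=_bin_center(indices, anchor, bin_ppm),
        mean_intensity=means,
        n_scans=n_scans,
        bin_indices=indices,
        anchor_mz=anchor,
        bin_ppm=bin_ppm,
    )


def subtract_background(
    tissue: AverageSpectrum,
    background: AverageSpectrum,
    floor_negative: bool = True,
) -> AverageSpectrum:
    """Elementwise tissue - background on the shared binned axis.

    Negative differences are floored at zero by default (set
    ``floor_negative=False`` for diagnostics). Spectra binned with a
    different anchor or bin width cannot be aligned and raise.
    """
    if tissue.anchor_mz != background.anchor_mz or tissue.bin_ppm != background.bin_ppm:
        raise ValueError(
            "m/z axis mismatch: spectra binned with different anchor/bin width"
        )
    union = np.union1d(tissue.bin_indices, background.bin_indices)
    t = np.zeros(len(union))
    b = np.zeros(len(union))
    t[np.searchsorted(union, tissue.bin_indices)] = tissue.mean_intensity
    b[np.searchsorted(union, background.bin_indices)] = background.mean_intensity
    diff = t - b
    if floor_negative:
        diff = np.maximum(diff, 0.0)
        return AverageSpectrum(
            mz_axis=_bin_center(union, tissue.anchor_mz, tissue.bin_ppm),
            mean_intensity=diff,
            n_scans=tissue.n_scans,
            bin_indices=union,
            anchor_mz=tissue.anchor_mz,
            bin_ppm=tissue.bin_ppm,
        )
    # diagnostics mode keeps negative bins, bypassing the >=0 invariant check
    out = AverageSpectrum.__new__(AverageSpectrum)
    out.mz_axis = _bin_center(union, tissue.anchor_mz, tissue.bin_ppm)
    out.mean_intensity = diff
    out.n_scans = tissue.n_scans
    out.bin_indices = union
    out.anchor_mz = tissue.anchor_mz
    out.bin_ppm = tissue.bin_ppm
    return out


def zone_average_spectrum(
    dataset: MSIDataset,
    zone: ZoneDefinition,
    bin_ppm: float = 5.0,
    floor_negative: bool = True,
) -> AverageSpectrum:
    """Background-subtracted average spectrum for one zone definition."""
    tissue = average_scans(dataset, zone.row_index, zone.tissue_columns(), bin_ppm)
    background = average_scans(dataset, zone.row_index, zone.background_cols, bin_ppm)
    return subtract_background(tissue, background, floor_negative=floor_negative)
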