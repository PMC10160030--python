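"""Lateral spatial resolution from single-ion row chromatograms (80-20% rule).

The lateral resolution of an MSI acquisition can be estimated from the
sharpness of the signal edge where the scan crosses the tissue boundary:
extract a single-ion chromatogram along one raster row (scan time converted
to distance via the stage speed), fit a straight line to the measured
points on the rising or falling edge, solve the fitted line for the x
coordinates of the 20% and 80% intensity levels by the point-slope formula,
and report ``|x80 - x20|``. On an ideal linear ramp of physical width L this
gives 0.6*L; across a Gaussian-blurred edge of scale sigma it approaches
(z_0.8 - z_0.2)*sigma ~= 1.683*sigma.

Rising- and falling-edge estimates are aggregated (several rows per tissue
section, several sections) and compared with a two-tailed, two-sample
equal-variance Student's t-test; symmetric edges should accept the null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .axis_profiling import student_t_two_sample
from .imzml_io import MSIDataset
from .ion_imaging import extract_window

__all__ = [
    "RowChromatogram",
    "EdgeFit",
    "EdgeResolutionSet",
    "EdgeTooSharpError",
    "row_chromatogram",
    "fit_edge",
    "aggregate_resolution",
]


class EdgeTooSharpError(ValueError):
    """The edge has no measurable interior points; resolution is bounded by
    the pixel pitch, carried in :attr:`upper_bound_um`."""

    def __init__(self, message: str, upper_bound_um: float):
        super().__init__(message)
        self.upper_bound_um = upper_bound_um


@dataclass
class RowChromatogram:
    """Window intensity of one target ion along one raster row."""

    distances_um: np.ndarray
    intensities: np.ndarray
    row: int = 0
    target_mz: float = 0.0
    pixel_width_um: float | None = None

    def __post_init__(self) -> None:
        self.distances_um = np.asarray(self.distances_um, dtype=np.float64)
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.distances_um.shape != self.intensities.shape:
            raise ValueError("distance and intensity lengths differ")
        if self.distances_um.size < 3:
            raise ValueError("chromatogram needs at least 3 points")
        steps = np.diff(self.distances_um)
        if np.any(steps <= 0):
            raise ValueError("distances must be strictly ascending")
        if self.pixel_width_um is None:
            self.pixel_width_um = float(steps[0])


def row_chromatogram(
    dataset: MSIDataset,
    row: int,
    target_mz: float,
    tolerance_ppm: float = 5.0,
) -> RowChromatogram:
    """Per-column window intensity for one row, distance = col * pixel width."""
    if not 0 <= row < dataset.n_rows:
        raise IndexError(f"row {row} out of range [0, {dataset.n_rows})")
    width = dataset.geometry.pixel_width_um
    intensities = np.array(
        [
            extract_window(dataset.spectrum(row, c), target_mz, tolerance_ppm)
            for c in range(dataset.n_cols)
        ]
    )
    return RowChromatogram(
        distances_um=np.arange(dataset.n_cols, dtype=float) * width,
        intensities=intensities,
        row=row,
        target_mz=target_mz,
        pixel_width_um=width,
    )


@dataclass
class EdgeFit:
    """A fitted 20-80% edge of one row chromatogram."""

    edge_kind: str  # "rising" | "falling"
    fit_points: np.ndarray  # (k, 2) columns: distance_um, baseline-subtracted I
    slope: float
    intercept: float
    x20_um: float
    x80_um: float
    resolution_um: float
    baseline: float
    amplitude: float


def _edge_fit_indices(
    sub: np.ndarray, amplitude: float, edge_kind: str, n_points: int
) -> list[int]:
    """Indices used to fit the edge line.

    Interior points are the consecutive run strictly between 20% and 80% of
    the amplitude gathered outward from the edge's 50% crossing (first
    crossing for the rising edge, last for the falling), stopping where the
    signal stops changing monotonically — this keeps noisy plateau points
    that dip back into the band from flattening the fit. With exactly one
    interior point its two bracketing neighbors join the fit; with none,
    the two points straddling the 50% crossing are used.
    """
    lo, mid, hi = 0.2 * amplitude, 0.5 * amplitude, 0.8 * amplitude
    above = np.nonzero(sub >= mid)[0]
    if above.size == 0 or above.size == sub.size:
        raise ValueError(f"no 50% crossing found for {edge_kind} edge")
    if edge_kind == "rising":
        cross = int(above[0])  # first point at/above 50%
        if cross == 0:
            raise ValueError("rising edge starts at/above 50%; no edge to fit")
    else:
        cross = int(above[-1])  # last point at/above 50%
        if cross == n_points - 1:
            raise ValueError("falling edge ends at/above 50%; no edge to fit")

    interior = (sub > lo) & (sub < hi)
    # contiguous interior run around the crossing, gathered outward while the
    # signal keeps moving in the edge's direction
    seeds = [cross, cross - 1] if edge_kind == "rising" else [cross, cross + 1]
    seed = next((s for s in seeds if 0 <= s < n_points and interior[s]), None)
    if seed is None:
        return []
    sign = 1.0 if edge_kind == "rising" else -1.0
    left = seed
    while (left - 1 >= 0 and interior[left - 1]
           and sign * (sub[left] - sub[left - 1]) > 0):
        left -= 1
    right = seed
    while (right + 1 < n_points and interior[right + 1]
           and sign * (sub[right + 1] - sub[right]) > 0):
        right += 1
    return list(range(left, right + 1))


def fit_edge(
    chrom: RowChromatogram,
    edge_kind: str,
    baseline_points: int = 8,
) -> EdgeFit:
    """Fit a straight line to one edge and solve it at the 20%/80% levels.

    The baseline is the mean of the ``baseline_points`` off-tissue points on
    the edge's own side of the row (leading points for the rising edge,
    trailing for the falling); the amplitude is the chromatogram maximum
    minus the baseline. An ordinary least-squares line through the interior
    (20-80%) points is solved by the point-slope formula for the x
    coordinates of exactly 20% and 80%; the resolution is ``|x80 - x20|``.
    """
    if edge_kind not in {"rising", "falling"}:
        raise ValueError(f"edge_kind must be 'rising' or 'falling', got {edge_kind!r}")
    x = chrom.distances_um
    y = chrom.intensities
    n = len(y)
    k = min(baseline_points, n)
    baseline = float(y[:k].mean() if edge_kind == "rising" else y[-k:].mean())
    sub = y - baseline
    amplitude = float(sub.max())
    if amplitude <= 0:
        raise ValueError("no signal above baseline; cannot fit an edge")

    idx = _edge_fit_indices(sub, amplitude, edge_kind, n)
    pitch = chrom.pixel_width_um or float(np.diff(x).mean())
    if len(idx) == 0:
        # no interior point: fall back to the pair straddling the 50% level
        above = np.nonzero(sub >= 0.5 * amplitude)[0]
        i = int(above[0]) if edge_kind == "rising" else int(above[-1])
        pair = [i - 1, i] if edge_kind == "rising" else [i, i + 1]
        if sub[pair[0]] == sub[pair[1]]:
            raise EdgeTooSharpError(
                f"edge too sharp to fit; resolution <= pixel width ({pitch} um)",
                upper_bound_um=pitch,
            )
        idx = pair
    elif len(idx) == 1:
        i = idx[0]
        idx = [j for j in (i - 1, i, i + 1) if 0 <= j < n]

    fit_x = x[idx]
    fit_y = sub[idx]
    slope, intercept = np.polyfit(fit_x, fit_y, 1)
    if slope == 0:
        raise EdgeTooSharpError(
            f"flat edge fit (zero slope); resolution <= pixel width ({pitch} um)",
            upper_bound_um=pitch,
        )
    x20 = (0.2 * amplitude - intercept) / slope
    x80 = (0.8 * amplitude - intercept) / slope
    return EdgeFit(
        edge_kind=edge_kind,
        fit_points=np.column_stack([fit_x, fit_y]),
        slope=float(slope),
        intercept=float(intercept),
        x20_um=float(x20),
        x80_um=float(x80),
        resolution_um=float(abs(x80 - x20)),
        baseline=baseline,
        amplitude=amplitude,
    )


@dataclass
class EdgeResolutionSet:
    """Aggregate rising/falling edge resolutions with their comparison."""

    rising_um: np.ndarray
    falling_um: np.ndarray
    mean_rising: float
    sd_rising: float
    n_rising: int
    mean_falling: float
    sd_falling: float
    n_falling: int
    t: float
    p: float


def aggregate_resolution(fits: list[EdgeFit]) -> EdgeResolutionSet:
    """Per-edge mean, sample s.d. and n over individual measurements
    (multiple rows per tissue section allowed), plus a two-tailed,
    two-sample equal-variance Student's t-test between the edges."""
    rising = np.array([f.resolution_um for f in fits if f.edge_kind == "rising"])
    falling = np.array([f.resolution_um for f in fits if f.edge_kind == "falling"])
    if len(rising) < 2 or len(falling) < 2:
        raise ValueError(
            f"need >= 2 fits per edge kind, got {len(rising)} rising / "
            f"{len(falling)} falling"
        )
    t, p = student_t_two_sample(rising, falling)
    return EdgeResolutionSet(
        rising_um=rising,
        falling_um=falling,
        mean_rising=float(rising.mean()),
        sd_rising=float(rising.std(ddof=1)),
        n_rising=len(rising),
        mean_falling=float(falling.mean()),
        sd_falling=float(falling.std(ddof=1)),
        n_falling=len(falling),
        t=float(t),
        p=float(p),
    )
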