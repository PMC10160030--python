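"""Intensity profiles along the root's developmental axis.

A root section is profiled by drawing a line through its center and, at
each point along the line, averaging the image over a band of pixels
perpendicular to it (default band width ten pixels: the line point plus
five raster pixels to each side, nearest-pixel sampling). Each section's
profile is scaled to its own maximum, profiles from replicate sections are
averaged pointwise (mean +- sample s.d.), and two metabolites' profiles are
compared position-by-position with a two-tailed unpaired Student's t-test
(equal variance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .imzml_io import RasterGeometry
from .ion_imaging import IonImage

__all__ = [
    "ProfileLine",
    "AxisProfile",
    "ProfileComparison",
    "sample_band",
    "line_distances_um",
    "scale_to_max",
    "aggregate_profiles",
    "compare_profiles",
    "student_t_two_sample",
]


@dataclass(frozen=True)
class ProfileLine:
    """A straight profile line in pixel coordinates with a sampling band."""

    start: tuple[float, float]  # (row, col)
    end: tuple[float, float]
    band_width_px: int = 10
    n_samples: int | None = None

    def __post_init__(self) -> None:
        if tuple(self.start) == tuple(self.end):
            raise ValueError("profile line start and end coincide")
        if self.band_width_px < 1:
            raise ValueError("band width must be >= 1 pixel")
        if self.n_samples is not None and self.n_samples < 2:
            raise ValueError("need at least 2 samples along the line")

    @property
    def length_px(self) -> float:
        dr = self.end[0] - self.start[0]
        dc = self.end[1] - self.start[1]
        return float(np.hypot(dr, dc))

    def resolved_n_samples(self) -> int:
        if self.n_samples is not None:
            return self.n_samples
        return int(np.ceil(self.length_px)) + 1

    def band_offsets(self) -> np.ndarray:
        """Signed perpendicular offsets (px). An even width w samples the
        center point plus w/2 pixels to each side; an odd width samples w
        centered integers."""
        w = self.band_width_px
        # odd w: w centered integers; even w: center plus w/2 on each side
        return np.arange(-(w // 2), w // 2 + 1, dtype=float)


def sample_band(image: IonImage, line: ProfileLine) -> np.ndarray:
    """Band-averaged image values at equally spaced points along the line.

    At each sample point, the image is read at the nearest pixel of each
    band offset along the perpendicular and averaged. Band points falling
    outside the image are dropped (the sample is a truncated-band average);
    a warning reports how many samples were truncated.
    """
    values = image.values
    n_rows, n_cols = values.shape
    start = np.asarray(line.start, dtype=float)
    end = np.asarray(line.end, dtype=float)
    for pt, name in ((start, "start"), (end, "end")):
        if not (0 <= pt[0] <= n_rows - 1 and 0 <= pt[1] <= n_cols - 1):
            raise ValueError(f"line {name} {tuple(pt)} outside image bounds")

    direction = (end - start) / np.linalg.norm(end - start)
    normal = np.array([-direction[1], direction[0]])
    n_samples = line.resolved_n_samples()
    ts = np.linspace(0.0, 1.0, n_samples)
    offsets = line.band_offsets()

    out = np.empty(n_samples)
    n_truncated = 0
    for i, t in enumerate(ts):
        point = start + t * (end - start)
        band = point[None, :] + offsets[:, None] * normal[None, :]
        rows = np.rint(band[:, 0]).astype(int)
        cols = np.rint(band[:, 1]).astype(int)
        inside = (rows >= 0) & (rows < n_rows) & (cols >= 0) & (cols < n_cols)
        if not inside.all():
            n_truncated += 1
        if not inside.any():
            raise ValueError(f"entire band outside image at sample {i}")
        out[i] = values[rows[inside], cols[inside]].mean()
    if n_truncated:
        warnings.warn(
            f"band truncated at image bounds for {n_truncated} of "
            f"{n_samples} samples",
            stacklevel=2,
        )
    return out


def line_distances_um(line: ProfileLine, geometry: RasterGeometry) -> np.ndarray:
    """Physical distance (um) of each sample point from the line start."""
    dr = (line.end[0] - line.start[0]) * geometry.pixel_height_um
    dc = (line.end[1] - line.start[1]) * geometry.pixel_width_um
    length = float(np.hypot(dr, dc))
    return np.linspace(0.0, length, line.resolved_n_samples())


def scale_to_max(values: np.ndarray) -> np.ndarray:
    """Divide a profile by its maximum so the output peaks at exactly 1."""
    values = np.asarray(values, dtype=np.float64)
    peak = values.max() if values.size else 0.0
    if peak <= 0:
        raise ValueError("cannot scale all-zero profile")
    return values / peak


@dataclass
class AxisProfile:
    """Per-section and aggregated intensity-vs-distance curves."""

    distances_um: np.ndarray
    per_section_values: dict[str, np.ndarray]
    mean: np.ndarray
    sd: np.ndarray

    @property
    def n_sections(self) -> int:
        return len(self.per_section_values)


def _resample(distances: np.ndarray, values: np.ndarray, n: int) -> np.ndarray:
    """Linear resampling to n points at equal fractions of the section length."""
    frac = (distances - distances[0]) / (distances[-1] - distances[0])
    return np.interp(np.linspace(0.0, 1.0, n), frac, values)


def aggregate_profiles(
    per_section: dict[str, np.ndarray | tuple[np.ndarray, np.ndarray]],
    distances_um: np.ndarray | None = None,
    scale: bool = True,
) -> AxisProfile:
    """Average per-section profiles into one mean +- s.d. curve.

    Sections may be supplied either as plain value arrays sharing
    ``distances_um``, or as ``(distances_um, values)`` pairs of unequal
    length; unequal sections are aligned by fractional position along the
    axis and linearly resampled to the longest section's sample count. Each
    section is scaled to its own maximum first (disable with
    ``scale=False``). The s.d. is the sample standard deviation (ddof=1),
    so at least two sections are required.
    """
    if len(per_section) < 2:
        raise ValueError(
            f"need >= 2 sections for a sample s.d., got {len(per_section)}"
        )
    items = list(per_section.items())
    if isinstance(items[0][1], tuple):
        n = max(len(v[1]) for _, v in items)
        lengths = [float(d[-1] - d[0]) for _, (d, _v) in items]
        grid = np.linspace(0.0, float(np.mean(lengths)), n)
        resampled = {k: _resample(np.asarray(d, float), np.asarray(v, float), n)
                     for k, (d, v) in items}
    else:
        arrays = {k: np.asarray(v, dtype=np.float64) for k, v in items}
        n = len(next(iter(arrays.values())))
        if any(len(v) != n for v in arrays.values()):
            raise ValueError(
                "sections of unequal length must be supplied as "
                "(distances, values) pairs for resampling"
            )
        if distances_um is None:
            grid = np.arange(n, dtype=float)
        else:
            grid = np.asarray(distances_um, dtype=np.float64)
            if len(grid) != n:
                raise ValueError("distances_um length does not match sections")
        resampled = arrays
    if scale:
        resampled = {k: scale_to_max(v) for k, v in resampled.items()}
    stack = np.vstack(list(resampled.values()))
    return AxisProfile(
        distances_um=grid,
        per_section_values=resampled,
        mean=stack.mean(axis=0),
        sd=stack.std(axis=0, ddof=1),
    )


def student_t_two_sample(
    a: np.ndarray, b: np.ndarray, axis: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-sample, equal-variance, two-tailed Student's t-test.

    Degenerate cases follow deterministic contracts: identical zero-variance
    groups give t=0, p=1; zero pooled variance with unequal means gives
    t=+-inf, p=0.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    na, nb = a.shape[axis], b.shape[axis]
    if na < 2 or nb < 2:
        raise ValueError("need n >= 2 per group")
    ma, mb = a.mean(axis=axis), b.mean(axis=axis)
    va = a.var(axis=axis, ddof=1)
    vb = b.var(axis=axis, ddof=1)
    df = na + nb - 2
    pooled = ((na - 1) * va + (nb - 1) * vb) / df
    se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    zero_se = se == 0
    t = np.where(zero_se & (diff == 0), 0.0, t)
    t = np.where(zero_se & (diff > 0), np.inf, t)
    t = np.where(zero_se & (diff < 0), -np.inf, t)
    p = np.where(np.isinf(t), 0.0, 2.0 * stats.t.sf(np.abs(np.where(np.isinf(t), 0, t)), df))
    p = np.where(zero_se & (diff == 0), 1.0, p)
    return t, p


@dataclass
class ProfileComparison:
    """Per-position t statistics between two metabolites' profiles."""

    distances_um: np.ndarray
    t: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    alpha: float = 0.05


def compare_profiles(
    a: AxisProfile,
    b: AxisProfile,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> ProfileComparison:
    """Position-by-position two-tailed unpaired Student's t-test between the
    per-section scaled values of two profiles.

    Raw per-position p-values are flagged at ``alpha`` by default, matching
    per-point asterisk significance; ``bonferroni=True`` divides alpha by
    the number of positions instead.
    """
    if len(a.distances_um) != len(b.distances_um) or not np.allclose(
        a.distances_um, b.distances_um
    ):
        raise ValueError("profiles are on different distance grids")
    mat_a = np.vstack(list(a.per_section_values.values()))
    mat_b = np.vstack(list(b.per_section_values.values()))
    t, p = student_t_two_sample(mat_a, mat_b, axis=0)
    threshold = alpha / len(a.distances_um) if bonferroni else alpha
    return ProfileComparison(
        distances_um=a.distances_um,
        t=t,
        p=p,
        significant=p < threshold,
        alpha=alpha,
    )
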