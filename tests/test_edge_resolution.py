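import numpy as np
import pytest
from scipy.special import ndtr

from rootmsi import (
    RowChromatogram,
    aggregate_resolution,
    fit_edge,
    row_chromatogram,
)


def ramp_chromatogram(ramp_um=600.0, pitch_um=10.0, plateau=100.0,
                      lead_um=200.0, tail_um=200.0):
    """Baseline 0 -> linear rise over ramp_um -> plateau -> linear fall."""
    x = []
    y = []
    pos = 0.0
    while pos < lead_um:
        x.append(pos); y.append(0.0); pos += pitch_um
    rise_start = pos
    while pos < rise_start + ramp_um:
        x.append(pos); y.append(plateau * (pos - rise_start) / ramp_um)
        pos += pitch_um
    plateau_start = pos
    while pos < plateau_start + 400.0:
        x.append(pos); y.append(plateau); pos += pitch_um
    fall_start = pos
    while pos < fall_start + ramp_um:
        x.append(pos); y.append(plateau * (1 - (pos - fall_start) / ramp_um))
        pos += pitch_um
    end = pos
    while pos < end + tail_um:
        x.append(pos); y.append(0.0); pos += pitch_um
    return RowChromatogram(np.array(x), np.maximum(np.array(y), 0.0))


def gaussian_edge_chromatogram(sigma_um, pitch_um=10.0, amplitude=100.0):
    """Rising and falling erf edges, well separated relative to sigma."""
    edge_um = max(500.0, 6.0 * sigma_um)
    total_um = 4.0 * edge_um
    x = np.arange(0.0, total_um, pitch_um)
    y = amplitude * (ndtr((x - edge_um) / sigma_um)
                     * ndtr((total_um - edge_um - x) / sigma_um))
    return RowChromatogram(x, y)


class TestFitEdge:
    @pytest.mark.parametrize("ramp_um", [300.0, 600.0, 900.0])
    def test_linear_ramp_closed_form(self, ramp_um):
        """On an ideal linear ramp of width L the 20-80% span is 0.6 L."""
        chrom = ramp_chromatogram(ramp_um=ramp_um, pitch_um=5.0)
        for kind in ("rising", "falling"):
            fit = fit_edge(chrom, kind)
            assert fit.resolution_um == pytest.approx(0.6 * ramp_um, rel=0.02)

    def test_step_with_single_intermediate_point(self):
        """A step sampled at pitch p with one 50% point: the interior point
        and its two bracketing samples are collinear with slope max/(2p),
        so the point-slope solution spans 1.2 p."""
        p = 10.0
        x = np.arange(0.0, 300.0, p)
        y = np.zeros_like(x)
        y[x >= 150.0] = 100.0
        y[x == 150.0] = 50.0
        fit = fit_edge(RowChromatogram(x, y), "rising")
        assert fit.slope == pytest.approx(100.0 / (2 * p))
        assert fit.resolution_um == pytest.approx(1.2 * p)

    def test_hard_step_falls_back_to_straddling_pair(self):
        """A step with no interior point is fit through the two samples
        straddling the 50% level: slope max/p, span 0.6 p (below the pixel
        pitch, as a hard edge must be)."""
        p = 10.0
        x = np.arange(0.0, 300.0, p)
        y = np.where(x >= 150.0, 100.0, 0.0)
        fit = fit_edge(RowChromatogram(x, y), "rising")
        assert fit.resolution_um == pytest.approx(0.6 * p)
        assert fit.resolution_um <= p

    @pytest.mark.parametrize("sigma_um", [150.0, 250.0, 400.0])
    def test_gaussian_edge_recovers_1683_sigma(self, sigma_um):
        """The 20-80% span of an erf edge is (z80-z20) sigma ~= 1.683 sigma."""
        chrom = gaussian_edge_chromatogram(sigma_um, pitch_um=10.0)
        for kind in ("rising", "falling"):
            fit = fit_edge(chrom, kind)
            assert fit.resolution_um == pytest.approx(1.6832 * sigma_um, rel=0.10)

    def test_invariance_under_scaling_and_translation(self):
        chrom = gaussian_edge_chromatogram(200.0)
        base = fit_edge(chrom, "rising").resolution_um
        scaled = RowChromatogram(chrom.distances_um, chrom.intensities * 37.5)
        shifted = RowChromatogram(chrom.distances_um + 5000.0, chrom.intensities)
        assert fit_edge(scaled, "rising").resolution_um == pytest.approx(base)
        assert fit_edge(shifted, "rising").resolution_um == pytest.approx(base)

    @pytest.mark.parametrize("pitch_um", [5.0, 10.0, 20.0, 40.0])
    def test_grid_convergence_on_wide_ramps(self, pitch_um):
        """For ramps wider than 3 pixels the estimate errs by < 1 pixel."""
        ramp = 160.0  # >= 4 pixels at the coarsest pitch
        chrom = ramp_chromatogram(ramp_um=ramp, pitch_um=pitch_um,
                                  lead_um=160.0, tail_um=160.0)
        fit = fit_edge(chrom, "rising")
        assert abs(fit.resolution_um - 0.6 * ramp) < pitch_um


class TestRowChromatogram:
    def test_single_spike(self, unit_geometry):
        from tests.conftest import make_dataset

        ds = make_dataset(
            lambda r, c: ([150.0], [9.0]) if (r, c) == (1, 3) else ([], []),
            unit_geometry, 3, 6,
        )
        chrom = row_chromatogram(ds, 1, 150.0, 5.0)
        assert chrom.intensities.tolist() == [0, 0, 0, 9, 0, 0]
        assert chrom.distances_um[3] == pytest.approx(3 * 10.0)
        with pytest.raises(IndexError):
            row_chromatogram(ds, 5, 150.0)

    def test_synthetic_row_has_tissue_plateau(self, default_sim):
        """The lipid chromatogram of a central row is non-zero exactly over
        (a neighborhood of) the programmed tissue columns."""
        ds, truth = default_sim
        cfg = truth.config
        pg = next(g.metabolite.theoretical_mz for g in cfg.gradients
                  if g.metabolite.name.startswith("PG"))
        row = int(cfg.resolved_center_row)
        chrom = row_chromatogram(ds, row, pg, 5.0)
        on = chrom.intensities > 0.25 * chrom.intensities.max()
        cols = np.nonzero(on)[0]
        assert cols.min() >= cfg.tip_col - 3
        assert cols.max() <= cfg.end_col + 3


class TestAggregateResolution:
    def test_identical_sets_accept_null(self):
        chrom = gaussian_edge_chromatogram(200.0)
        fits = []
        for offset in (0.0, 3.0, 6.0):
            shifted = RowChromatogram(chrom.distances_um,
                                      np.roll(chrom.intensities, int(offset)))
            for kind in ("rising", "falling"):
                fits.append(fit_edge(shifted, kind))
        agg = aggregate_resolution(fits)
        assert agg.n_rising == agg.n_falling == 3
        assert agg.p > 0.05

    def test_replicate_design_arithmetic(self):
        """4 rows per section x 10 sections -> n = 40 measurements per edge."""
        rng = np.random.default_rng(31)
        fits = []
        for _section in range(10):
            for _row in range(4):
                sigma = rng.uniform(150, 250)
                chrom = gaussian_edge_chromatogram(sigma)
                fits.append(fit_edge(chrom, "rising"))
                fits.append(fit_edge(chrom, "falling"))
        agg = aggregate_resolution(fits)
        assert agg.n_rising == 40
        assert agg.n_falling == 40

    def test_separated_groups_reject_null(self):
        fits = []
        rng = np.random.default_rng(37)
        for _ in range(10):
            fits.append(fit_edge(
                gaussian_edge_chromatogram(100.0 + rng.uniform(-5, 5)), "rising"))
            fits.append(fit_edge(
                gaussian_edge_chromatogram(400.0 + rng.uniform(-5, 5)), "falling"))
        agg = aggregate_resolution(fits)
        assert agg.p < 0.001

    def test_insufficient_fits_rejected(self):
        chrom = gaussian_edge_chromatogram(200.0)
        with pytest.raises(ValueError, match=">= 2 fits"):
            aggregate_resolution([fit_edge(chrom, "rising")])


def test_symmetric_edges_accept_null_in_most_replicates():
    """With symmetric Gaussian blur and measurement noise, the rising-vs-
    falling equal-variance t-test accepts the null in >= 90% of replicates."""
    rng = np.random.default_rng(41)
    accepted = 0
    n_reps = 100
    for _ in range(n_reps):
        fits = []
        for _measurement in range(8):
            sigma = rng.uniform(180, 220)
            chrom = gaussian_edge_chromatogram(sigma, pitch_um=20.0)
            noisy = RowChromatogram(
                chrom.distances_um,
                np.maximum(
                    chrom.intensities
                    + rng.normal(0, 2.0, chrom.intensities.size),
                    0.0,
                ),
            )
            fits.append(fit_edge(noisy, "rising"))
            fits.append(fit_edge(noisy, "falling"))
        if aggregate_resolution(fits).p >= 0.05:
            accepted += 1
    assert accepted >= 0.90 * n_reps
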