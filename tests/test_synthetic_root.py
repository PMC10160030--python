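import json
from dataclasses import replace

import numpy as np
import pytest

from rootmsi import (
    GradientSpec,
    MetaboliteRecord,
    ProfileLine,
    SimulationConfig,
    aggregate_profiles,
    build_ion_image,
    compare_profiles,
    default_root_config,
    fit_edge,
    line_distances_um,
    row_chromatogram,
    sample_band,
    simulate,
    simulate_sections,
    write_imzml,
)
from rootmsi.synthetic_root import config_from_dict


def target_mz(truth, name):
    return next(g.metabolite.theoretical_mz for g in truth.config.gradients
                if g.metabolite.name == name)


def test_default_config_valid_and_fast(default_sim):
    ds, truth = default_sim
    assert (ds.n_rows, ds.n_cols) == (40, 150)
    assert truth.config.geometry.pixel_width_um == pytest.approx(72.6)
    assert truth.config.geometry.pixel_height_um == pytest.approx(80.0)
    # session fixture already simulated; here just bound a fresh run
    import time

    t0 = time.time()
    simulate(default_root_config(seed=3))
    assert time.time() - t0 < 60.0


def test_constant_noiseless_pixels_identical(unit_geometry):
    met = MetaboliteRecord.from_formula("succinate", "C4H6O4")
    config = SimulationConfig(
        n_rows=8, n_cols=30, tip_col=5, end_col=25, taper_cols=0,
        max_half_width_rows=3.0,
        gradients=(GradientSpec(met, 100.0, profile="constant"),),
        noise="none", mz_jitter_ppm=0.0, edge_blur_sigma_um=0.0,
        tic_drift=0.0, seed=1,
    )
    ds, truth = simulate(config)
    on = np.argwhere(truth.binary_mask)
    ref = ds.spectrum(*on[0])
    for r, c in on[1:]:
        spec = ds.spectrum(r, c)
        np.testing.assert_array_equal(spec.mz_values, ref.mz_values)
        np.testing.assert_array_equal(spec.intensities, ref.intensities)


def test_fixed_seed_gives_identical_imzml_bytes(tmp_path):
    config = replace(default_root_config(seed=5), n_rows=10, n_cols=40,
                     tip_col=4, end_col=35)
    paths = []
    for tag in ("a", "b"):
        ds, _ = simulate(config)
        p = tmp_path / f"{tag}.imzML"
        write_imzml(ds, p)
        paths.append(p)
    assert paths[0].with_suffix(".ibd").read_bytes() == \
        paths[1].with_suffix(".ibd").read_bytes()


def test_seed_split_stable_under_grid_growth():
    """Growing the grid never changes the draws of earlier pixels."""
    small = replace(default_root_config(seed=9), n_rows=6, n_cols=40,
                    tip_col=4, end_col=35, center_row=2.5,
                    max_half_width_rows=2.0)
    large = replace(small, n_rows=12)
    ds_small, _ = simulate(small)
    ds_large, _ = simulate(large)
    for r in range(6):
        for c in range(0, 40, 7):
            a, b = ds_small.spectrum(r, c), ds_large.spectrum(r, c)
            np.testing.assert_array_equal(a.intensities, b.intensities)
            np.testing.assert_array_equal(a.mz_values, b.mz_values)


def test_noiseless_pipeline_identity(noiseless_sim):
    """With noise disabled, the unnormalized ion image of each programmed
    species equals the generator's expected grid exactly."""
    ds, truth = noiseless_sim
    for gradient in truth.config.gradients:
        img = build_ion_image(ds, gradient.metabolite.theoretical_mz, 5.0, "none")
        np.testing.assert_array_equal(
            img.values, truth.expected[gradient.metabolite.name]
        )


def test_poisson_images_track_ground_truth(default_sim):
    """%TIC images correlate with noiseless expectation at r > 0.98 over
    on-tissue pixels despite Poisson noise and TIC drift."""
    ds, truth = default_sim
    mask = truth.binary_mask
    for name in ("malate", "aconitate"):
        img = build_ion_image(ds, target_mz(truth, name), 5.0, "tic_percent")
        expected = truth.expected[name] / np.maximum(
            sum(truth.expected.values()), 1e-12
        )
        r = np.corrcoef(img.values[mask], expected[mask])[0, 1]
        assert r > 0.98


def test_succinate_and_aconitate_peak_in_opposite_thirds(default_sim):
    """The succinate image peaks in the meristem (tip) third of the axis,
    aconitate in the differentiation (shank) third."""
    ds, truth = default_sim
    cfg = truth.config
    axis_cols = np.arange(cfg.tip_col, cfg.end_col + 1)
    third = len(axis_cols) // 3

    def peak_position(name):
        img = build_ion_image(ds, target_mz(truth, name), 5.0, "tic_percent")
        on = np.where(truth.binary_mask, img.values, 0.0)
        col_means = on[:, axis_cols].sum(axis=0) / np.maximum(
            truth.binary_mask[:, axis_cols].sum(axis=0), 1
        )
        return int(np.argmax(col_means))

    assert peak_position("succinate") < third
    assert peak_position("aconitate") >= 2 * third


def test_edge_blur_recovered_by_resolution_estimator():
    """Programmed boundary blur sigma is recovered as ~1.683 sigma by the
    80-20% estimator (within 10%) for sigma >= 1.5 pixel widths."""
    base = default_root_config(seed=13)
    sigma = 1.6 * base.geometry.pixel_width_um  # 116 um
    config = replace(base, edge_blur_sigma_um=sigma, noise="none",
                     tic_drift=0.0)
    ds, truth = simulate(config)
    pg = target_mz(truth, "PG(16:0/18:2)")
    row = int(config.resolved_center_row)
    estimates = []
    for r in (row - 2, row, row + 2):
        chrom = row_chromatogram(ds, r, pg, 5.0)
        estimates.append(fit_edge(chrom, "falling").resolution_um)
    assert np.mean(estimates) == pytest.approx(1.6832 * sigma, rel=0.10)


def test_profile_recovery_over_ten_sections():
    """Succinate vs aconitate profiles from 10 simulated sections flag
    >= 80% of the designed-divergence region at alpha = 0.05."""
    config = default_root_config(seed=21)
    sections = simulate_sections(config, n_sections=10)
    profiles = {}
    for name in ("succinate", "aconitate"):
        per_section = {}
        for i, (ds, truth) in enumerate(sections):
            cfg = truth.config
            row = cfg.resolved_center_row
            line = ProfileLine((row, cfg.tip_col), (row, cfg.end_col),
                               band_width_px=10, n_samples=60)
            img = build_ion_image(ds, target_mz(truth, name), 5.0, "tic_percent")
            per_section[f"s{i}"] = sample_band(img, line)
        distances = line_distances_um(line, config.geometry)
        profiles[name] = aggregate_profiles(per_section, distances)
    comparison = compare_profiles(
        profiles["succinate"], profiles["aconitate"], alpha=0.05
    )
    _, truth0 = sections[0]
    region = truth0.divergence_region("succinate", "aconitate", threshold=0.3)
    cfg = truth0.config
    # map profile sample positions onto axis columns
    cols = np.linspace(cfg.tip_col, cfg.end_col, 60).round().astype(int)
    in_region = region[cols]
    flagged = comparison.significant[in_region]
    assert flagged.mean() >= 0.80


def test_config_validation():
    met = MetaboliteRecord.from_formula("x", "C4H6O4")
    narrow = replace(default_root_config().geometry, mz_range=(200.0, 1000.0))
    with pytest.raises(ValueError, match="outside acquired range"):
        SimulationConfig(geometry=narrow, gradients=(GradientSpec(met, 1.0),))
    with pytest.raises(ValueError, match="tip_col"):
        SimulationConfig(tip_col=50, end_col=40)
    with pytest.raises(ValueError):
        GradientSpec(met, amplitude=-1.0)
    with pytest.raises(ValueError):
        GradientSpec(met, 1.0, profile="spline")


def test_gradient_profile_shapes():
    met = MetaboliteRecord.from_formula("x", "C4H6O4")
    frac = np.linspace(0, 1, 11)
    bump = GradientSpec(met, 1.0, "gaussian_bump", center_frac=0.5,
                        width_frac=0.1).evaluate(frac)
    assert np.argmax(bump) == 5
    rising = GradientSpec(met, 1.0, "logistic", center_frac=0.5,
                          direction="shankward").evaluate(frac)
    assert np.all(np.diff(rising) > 0)
    falling = GradientSpec(met, 1.0, "logistic", center_frac=0.5,
                           direction="tipward").evaluate(frac)
    np.testing.assert_allclose(falling, rising[::-1], rtol=1e-12)
    np.testing.assert_allclose(
        GradientSpec(met, 1.0, "constant").evaluate(frac), 1.0
    )


def test_ground_truth_ratio_profile_monotone(default_sim):
    _, truth = default_sim
    succ = truth.scaled_axis_profile("succinate")
    acon = truth.scaled_axis_profile("aconitate")
    frac = truth.axis_frac
    central = (frac >= 0.2) & (frac <= 0.8)
    ratio = succ[central] / acon[central]
    assert np.all(np.diff(ratio) < 0)


def test_ground_truth_json_rle_roundtrip(default_sim):
    _, truth = default_sim
    payload = json.loads(truth.to_json(include_expected=False))
    rle = payload["mask_rle"]
    flat = []
    value = rle["first_value"]
    for run in rle["run_lengths"]:
        flat.extend([value] * run)
        value = 1 - value
    decoded = np.array(flat, dtype=bool).reshape(payload["shape"])
    np.testing.assert_array_equal(decoded, truth.binary_mask)


def test_config_from_dict_roundtrip():
    config = config_from_dict({
        "n_rows": 12, "n_cols": 50, "tip_col": 5, "end_col": 45,
        "geometry": {"stage_speed_um_s": 53.69, "cycle_time_s": 72.6 / 53.69,
                     "pixel_height_um": 80.0},
        "gradients": [
            {"metabolite": "succinate", "amplitude": 100.0,
             "profile": "gaussian_bump", "center_frac": 0.15,
             "width_frac": 0.1, "direction": "tipward"},
            {"name": "custom", "formula": "C5H6O5", "amplitude": 10.0},
        ],
        "matrix_peaks": [[311.1687, 5.0, False]],
        "seed": 3,
    })
    assert config.geometry.pixel_width_um == pytest.approx(72.6)
    assert config.gradients[0].metabolite.nominal_mz == 117
    assert config.gradients[1].metabolite.nominal_mz == 145
    ds, _ = simulate(config)
    assert ds.n_cols == 50
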