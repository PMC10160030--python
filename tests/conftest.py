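import numpy as np
import pytest

from rootmsi import (
    MSIDataset,
    PixelSpectrum,
    RasterGeometry,
    default_root_config,
    simulate,
)


@pytest.fixture(scope="session")
def unit_geometry():
    return RasterGeometry.from_kinematics(
        stage_speed_um_s=10.0, cycle_time_s=1.0, pixel_height_um=10.0,
        mz_range=(50.0, 1000.0),
    )


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic section with ground truth (seed fixed)."""
    return simulate(default_root_config(seed=7))


@pytest.fixture(scope="session")
def noiseless_sim():
    """Default root with all stochastic elements disabled."""
    from dataclasses import replace

    config = replace(
        default_root_config(seed=7),
        noise="none", tic_drift=0.0, mz_jitter_ppm=0.0,
    )
    return simulate(config)


def make_dataset(peaks_per_pixel, geometry, n_rows, n_cols):
    """Grid dataset from a callable (row, col) -> (mz_array, intensity_array)."""
    pixels = []
    for r in range(n_rows):
        row = []
        for c in range(n_cols):
            mzs, ints = peaks_per_pixel(r, c)
            row.append(
                PixelSpectrum(
                    row_index=r, col_index=c,
                    mz_values=np.asarray(mzs, dtype=float),
                    intensities=np.asarray(ints, dtype=float),
                )
            )
        pixels.append(row)
    return MSIDataset(pixels=pixels, geometry=geometry)
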