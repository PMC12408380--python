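import numpy as np
import pytest

import phenoasync as pa


@pytest.fixture(scope="session")
def small_grid():
    return pa.GridSpec(8, 8, 0.05, (1.0, 0.0))


@pytest.fixture(scope="session")
def gradient_scene(small_grid):
    """Noise-free west-east phase gradient spanning pi radians."""
    return pa.gen_harmonic_field(small_grid, "gradient", noise_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def discontinuity_scene():
    """Two-phase scene (opposite seasons east/west), mild observation noise."""
    grid = pa.GridSpec(12, 12, 0.05, (1.0, 0.0))
    return pa.gen_harmonic_field(
        grid, "discontinuity", noise_sd=0.01, seed=7, semiannual_amplitude=0.02
    )


@pytest.fixture(scope="session")
def fitted_discontinuity(discontinuity_scene):
    fits = pa.fit_cube(discontinuity_scene.cube)
    valid = np.array([f.ok for f in fits])
    curves = pa.standardized_curves(fits, valid)
    return fits, valid, curves
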