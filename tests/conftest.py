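import numpy as np
import pandas as pd
import pytest

from imagerylink import synth, volumes


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def grid2mm():
    """Odd-shaped 2 mm grid whose center voxel sits at the world origin."""
    return volumes.VoxelGrid.isotropic((25, 29, 25), 2.0)


@pytest.fixture
def grid15mm():
    return volumes.VoxelGrid.isotropic((24, 28, 24), 1.5)


@pytest.fixture
def small_synth_config():
    """Desk-scale generator configuration for fast end-to-end tests."""
    return synth.SynthConfig(
        n_structural=24,
        n_functional=20,
        struct_shape=(24, 28, 24),
        func_shape=(25, 29, 25),
        effect_center_mm=(0.0, 0.0, 6.0),
        effect_semiaxes_mm=(8.0, 9.0, 8.0),
        sphere_center_mm=(0.0, 0.0, 0.0),
        sphere_radius_mm=8.0,
    )


@pytest.fixture
def tiny_cohort(rng):
    n = 16
    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i:03d}" for i in range(n)],
            "age": rng.uniform(20, 80, n),
            "gender": rng.integers(0, 2, n),
            "total_gm": rng.normal(620, 60, n),
            "digit_span": rng.integers(4, 10, n),
            "music_years": rng.uniform(0, 20, n),
            "bais_vividness": rng.uniform(2.9, 7, n),
            "bais_control": rng.uniform(2, 7, n),
            "vviq_vividness": rng.uniform(1.2, 5, n),
        }
    ).assign(bais_total=lambda d: (d.bais_vividness + d.bais_control) / 2)
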