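import numpy as np
import pytest

import petcbda.io_wrangle as iw
import petcbda.synthetic_pet as sp


@pytest.fixture(scope="session")
def grid():
    return sp.default_test_grid()


@pytest.fixture(scope="session")
def atlas(grid):
    return sp.build_default_atlas(grid, seed=1)


@pytest.fixture(scope="session")
def masks(atlas):
    return sp.build_masks(atlas)


@pytest.fixture(scope="session")
def default_sessions():
    return sp.generate_cohort(sp.default_cohort_spec())


@pytest.fixture(scope="session")
def cfn_images(atlas):
    """Default-effect CFN cohort (138 images) on the test grid."""
    effects = sp.default_effect_spec(seed=3, noise_sd=0.3)
    images = sp.simulate_cohort(sp.default_cohort_spec(), effects, atlas)
    return [im for im in images if im.tracer == "CFN"]


@pytest.fixture(scope="session")
def cfn_matrix(cfn_images, masks):
    return iw.assemble_matrix_from_images(
        cfn_images, masks["CFN"], iw.ThresholdSpec(2.0, 0.8)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_toy_matrix(n=24, p=60, n_signal=0, seed=0, delta=3.0):
    """Small random VoxelMatrix; optional perfectly separating signal columns."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(2.0, 0.3, size=(n, p))
    for c in range(n_signal):
        X[:, c] = 2.0 + delta * y
    meta = pd.DataFrame(
        {
            "subject_id": [f"s{i // 2:03d}" for i in range(n)],
            "tracer": "CFN",
            "group": np.where(y == 1, "EM", "HC"),
            "state": np.where(y == 1, "interictal", "none"),
            "phase": ["early", "late"] * (n // 2),
            "sex": "F",
        }
    )
    return iw.VoxelMatrix(
        X=X, y=y, row_meta=meta, col_flat=np.arange(p), dims=(8, 8, 8)
    )
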