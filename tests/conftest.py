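import numpy as np
import pandas as pd
import pytest

import omixaug as oa


@pytest.fixture(scope="session")
def toy_stage_data() -> pd.DataFrame:
    """200 samples of a 2-gene stage: the GAN's toy convergence target."""
    rng = np.random.default_rng(0)
    return pd.DataFrame(rng.normal([2.0, -1.0], [1.0, 0.5], size=(200, 2)),
                        columns=["g1", "g2"])


@pytest.fixture(scope="session")
def default_cohort():
    """The standard balanced synthetic cohort (240 samples, 200 genes)."""
    return oa.make_synthetic_cohort(oa.SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def bench_cohort():
    """Reduced-scale cohort for harness tests (100 genes, 20 informative)."""
    return oa.make_synthetic_cohort(oa.preset_config("bench", seed=0))


@pytest.fixture()
def tiny_cohort():
    """Small 4-stage cohort for fast structural tests."""
    cohort, _ = oa.make_synthetic_cohort(
        oa.SyntheticConfig(stage_counts=(8, 8, 8, 8), n_genes=16,
                           n_informative=4, seed=7))
    return cohort
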