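import numpy as np
import pandas as pd
import pytest

import seasonscan as ss
from seasonscan.envglm import build_env_covariates


@pytest.fixture(scope="session")
def small_study():
    """Synthetic seasonal study with a planted responsive inversion block."""
    return ss.gen_study(
        n_snps=400, n_samples_per_year=6, n_years=3, n_planted=30, seed=11
    )


@pytest.fixture(scope="session")
def small_cov(small_study):
    return build_env_covariates(small_study.weather, small_study.meta)


@pytest.fixture(scope="session")
def null_study():
    """Same design with all planted effects zero (pure drift + noise)."""
    return ss.gen_study(
        n_snps=400,
        n_samples_per_year=6,
        n_years=3,
        n_planted=30,
        effect_size=0.0,
        seed=12,
    )


@pytest.fixture(scope="session")
def toy_afm():
    """Tiny deterministic 5-SNP x 4-sample AF matrix."""
    rng = np.random.default_rng(5)
    af = rng.uniform(0.1, 0.9, size=(5, 4))
    depth = np.full((5, 4), 60.0)
    snps = pd.DataFrame(
        {
            "chrom": ["2L"] * 3 + ["2R"] * 2,
            "pos": [100, 200, 300, 150, 250],
            "ref": "A",
            "alt": "T",
        }
    )
    return ss.AlleleFrequencyMatrix(
        snps=snps,
        samples=["s1", "s2", "s3", "s4"],
        af=af,
        depth=depth,
        n_chrs=np.array([80.0, 80.0, 80.0, 80.0]),
    )
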