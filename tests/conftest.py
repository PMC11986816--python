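import numpy as np
import pandas as pd
import pytest

from fairscreen.cohort import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """Unbiased cohort, large enough for every group/outcome cell."""
    return generate_cohort(SimConfig(n=6000, seed=42))


@pytest.fixture(scope="session")
def biased_cohort() -> pd.DataFrame:
    """Cohort with injected race bias (feature shift + label noise)."""
    return generate_cohort(
        SimConfig(
            n=20_000,
            seed=43,
            bias_mechanisms={
                "feature_shift": 0.5,
                "differential_label_noise": 0.45,
            },
        )
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_scores_labels(rng, n, ties=False):
    """Random score/label pair with both classes present."""
    scores = rng.random(n)
    if ties:
        scores = np.round(scores, 1)
    labels = rng.integers(0, 2, n)
    labels[0], labels[1] = 0, 1  # ensure both classes
    return scores, labels
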