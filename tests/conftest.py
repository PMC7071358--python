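import numpy as np
import pytest

from ironmr import datasets
from ironmr.summary_data import HarmonizedPair, HarmonizedSet


@pytest.fixture(scope="session")
def exposure_tables():
    return datasets.exposure_tables()


@pytest.fixture(scope="session")
def harmonized_sets():
    return datasets.harmonized_sets()


@pytest.fixture
def liver_iron(harmonized_sets):
    return harmonized_sets[("serum_iron", "liver_cancer")]


@pytest.fixture
def liver_transferrin(harmonized_sets):
    return harmonized_sets[("transferrin", "liver_cancer")]


def random_harmonized_set(rng: np.random.Generator, n_variants: int) -> HarmonizedSet:
    """A well-conditioned random set for oracle-equivalence checks."""
    beta = rng.uniform(0.05, 0.6, n_variants) * rng.choice([-1.0, 1.0], n_variants)
    gamma = rng.normal(0.0, 0.3, n_variants)
    se_b = rng.uniform(0.005, 0.05, n_variants)
    se_g = rng.uniform(0.02, 0.5, n_variants)
    pairs = tuple(
        HarmonizedPair(
            variant_id=f"rs{i}",
            beta_exposure=float(beta[i]),
            se_exposure=float(se_b[i]),
            beta_outcome=float(gamma[i]),
            se_outcome=float(se_g[i]),
        )
        for i in range(n_variants)
    )
    return HarmonizedSet(exposure_id="x", outcome_id="y", pairs=pairs)
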