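"""Shared fixtures: small synthetic providers, ground truths and PCP sets."""

import numpy as np
import pytest
from hypothesis import settings

from abselect import synthetic_data as sd
from abselect.neutral import NucleotideRates, TableNeutralProvider

settings.register_profile("suite", max_examples=25, deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def kmer_provider():
    return sd.gen_kmer_table(rng=2)


@pytest.fixture(scope="session")
def context_truth():
    return sd.gen_ground_truth(sd.GroundTruthSpec(family="context"))


@pytest.fixture(scope="session")
def neutral_truth():
    return sd.gen_ground_truth(sd.GroundTruthSpec(family="constant", baseline=1.0))


@pytest.fixture(scope="session")
def small_pcps(kmer_provider, context_truth):
    """~600 filtered PCPs from a handful of simulated clonal trees."""
    return sd.gen_pcp_dataset(600, context_truth, kmer_provider, seed=101)


@pytest.fixture()
def uniform_rates():
    """Deterministic per-site rates: lambda = (0.1, 0.2, 0.3, ...) cycling,
    uniform substitution distribution."""

    def make(n_nt: int) -> TableNeutralProvider:
        lam = np.array([0.1 + 0.1 * (i % 3) for i in range(n_nt)])
        sub = np.full((n_nt, 4), 0.25)
        return TableNeutralProvider(NucleotideRates(lam, sub))

    return make
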