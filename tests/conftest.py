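import numpy as np
import pytest

from aatcensus import simulate as sim


@pytest.fixture
def rng():
    return np.random.default_rng(20240911)


@pytest.fixture(scope="session")
def small_bundle():
    """A small noise-free synthetic bundle shared by integration tests."""
    cfg = sim.SimConfig(
        seed=424242,
        n_taxa=4,
        baseline={"APC": 3.0, "AAAP": 2.5},
        delta=2.0,
        sigma2=0.5,
        background_n=6,
    )
    return sim.simulate_bundle(cfg)


def random_cds(rng, n_codons):
    from aatcensus.seqio import SENSE_CODONS

    return "ATG" + "".join(
        SENSE_CODONS[i] for i in rng.integers(len(SENSE_CODONS), size=n_codons - 1)
    )
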