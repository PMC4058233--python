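import numpy as np
import pytest

from stressnet import (
    AlignerConfig,
    HomologyThresholds,
    generate_proteome,
    generate_reference_network,
    generate_unigenes,
)

AA = "ACDEFGHIKLMNPQRSTVWY"
NT = "ACGT"


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(AA))[rng.integers(20, size=length)])


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(NT))[rng.integers(4, size=length)])


@pytest.fixture(scope="session")
def thresholds():
    return HomologyThresholds()


@pytest.fixture(scope="session")
def aligner_cfg():
    return AlignerConfig()


@pytest.fixture(scope="session")
def small_world():
    """A small noiseless synthetic world shared across tests."""
    net = generate_reference_network(30, 2, "spA", seed=101)
    proteome = generate_proteome(net, 100, 160, seed=102)
    unigenes, truth = generate_unigenes(
        proteome, target_identity=1.0, source_fraction=1.0,
        n_decoys=5, seed=103,
    )
    return {
        "network": net,
        "proteome": proteome,
        "unigenes": unigenes,
        "truth": truth,
    }
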