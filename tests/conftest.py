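import numpy as np
import pytest

from structfunc.structure import AMINO_ACIDS, ContactGraph, Residue, ResidueChain


def random_chain(rng: np.random.Generator, n: int, box: float = 30.0,
                 protein_id: str = "RND") -> ResidueChain:
    """Random coordinates in a box — not physical, ideal for oracle tests."""
    coords = rng.uniform(0, box, size=(n, 3))
    aas = rng.choice(list(AMINO_ACIDS), size=n)
    return ResidueChain(protein_id, [Residue(a, c) for a, c in zip(aas, coords)])


def random_graph(rng: np.random.Generator, n: int, p: float = 0.4,
                 protein_id: str = "G") -> ContactGraph:
    edges = {
        (i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < p
    }
    return ContactGraph(protein_id, n, edges)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_bundle(tmp_path_factory):
    """Small synthetic dataset shared by I/O and CLI tests."""
    from structfunc.synth import SynthConfig, gen_dataset

    root = tmp_path_factory.mktemp("bundle")
    cfg = SynthConfig(n_proteins=12, chain_length_range=(20, 30),
                      motif_length=10, n_terms=8, dag_depth=3, seed=11)
    return gen_dataset(cfg, root)
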