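import numpy as np
import pytest

from solugat.fixtures import FixtureSpec, make_helix_trace, make_labeled_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def random_trace(rng, L):
    """Random coordinate cloud trace (not helical) for geometry tests."""
    from solugat.graphs import CalphaTrace
    coords = rng.uniform(-20, 20, size=(L, 3))
    seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=L))
    return CalphaTrace(protein_id=f"rand{L}",
                       residues=[(i + 1, aa) for i, aa in enumerate(seq)],
                       coords=coords)


def random_graph(rng, L, p=0.4):
    """Random symmetric adjacency with self-loops, as bool array."""
    A = rng.random((L, L)) < p
    A = A | A.T
    np.fill_diagonal(A, True)
    return A


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small noise-free fixture dataset shared by training tests."""
    spec = FixtureSpec(n_proteins=12, length_range=(10, 24), seed=3,
                       noise_sd=0.0)
    records, traces, truth = make_labeled_dataset(spec)
    return records, traces, truth
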