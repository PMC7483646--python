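import numpy as np
import pytest

from mutassess import synthetic as syn
from mutassess.ensemble_io import ResidueID
from mutassess.psn import PSNGraph


@pytest.fixture(scope="session")
def toy_ensemble():
    """12 pseudo-residues, 20 frames, three scheduled contacts (100/50/25%)."""
    return syn.make_toy_ensemble(
        12, {(3, 10): 100.0, (2, 7): 50.0, (4, 8): 25.0}, n_frames=20, seed=11
    )


@pytest.fixture(scope="session")
def charged_pair_998():
    return syn.make_charged_pair_ensemble(99.8, 500, seed=5)


def residue(position, name="ALA", chain="A"):
    return ResidueID(chain, position, name)


def graph_from_edges(edges, weights=None):
    """PSNGraph over integer-positioned Ala residues, persistence default 50."""
    g = PSNGraph(interaction_type="contact", distance_cutoff=5.0, persistence_cutoff=20.0)
    for k, (i, j) in enumerate(edges):
        w = 50.0 if weights is None else weights[k]
        g.add_edge(residue(i), residue(j), persistence=w)
    return g


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
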