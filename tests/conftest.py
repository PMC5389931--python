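"""Shared fixtures: seeded random trees and small hand-built inputs."""

from __future__ import annotations

import dendropy
import pytest

from nudixclan.simulate import SimConfig, sim_tree
from nudixclan.trees import read_newick


def random_tree(seed: int, n_leaves: int, scale: float = 0.1) -> dendropy.Tree:
    """Seeded random binary tree with exponential branch lengths."""
    return sim_tree(SimConfig(seed=seed, n_leaves=n_leaves,
                              branch_length_scale=scale))


@pytest.fixture
def newick():
    def _load(text: str) -> dendropy.Tree:
        return read_newick(text, from_path=False)
    return _load
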