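import numpy as np
import pytest

from amaztraits.phylo_core import parse_newick, vcv_matrix
from amaztraits.synthetic_data import SimulationConfig, simulate_tree


@pytest.fixture
def three_taxon_tree():
    """The hand-checkable worked example: ((A:1,B:1):1,C:2)."""
    return parse_newick("((A:1.0,B:1.0):1.0,C:2.0);")


@pytest.fixture
def star_tree():
    return parse_newick("(A:1.0,B:1.0,C:1.0,D:1.0);")


@pytest.fixture(scope="session")
def tree_factory():
    """Birth-death tree maker used across modules: tree_factory(n, seed)."""

    def make(n_tips, seed, death_rate=0.2, depth=None):
        cfg = SimulationConfig(
            n_tips=n_tips, seed=seed, death_rate=death_rate, tree_depth=depth
        )
        return simulate_tree(cfg)

    return make


@pytest.fixture(scope="session")
def bm_sampler():
    """Draw a Brownian trait on a tree: bm_sampler(tree, lam, seed)."""

    def draw(tree, lam=1.0, seed=0, sigma2=1.0, mu=0.0):
        from amaztraits.phylo_core import lambda_transform

        C = lambda_transform(vcv_matrix(tree), lam).matrix
        n = C.shape[0]
        L = np.linalg.cholesky(C + 1e-12 * np.trace(C) / n * np.eye(n))
        rng = np.random.default_rng(seed)
        return mu + np.sqrt(sigma2) * (L @ rng.standard_normal(n))

    return draw


@pytest.fixture(scope="session")
def study_dataset():
    """One study-scale synthetic dataset shared by the slower tests."""
    from amaztraits.synthetic_data import make_study_like_dataset

    return make_study_like_dataset(seed=0)
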