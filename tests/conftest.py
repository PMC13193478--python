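import warnings

import numpy as np
import pytest

from mimodiv.simulate import SimConfig, simulate_sse_dataset
from mimodiv.trees import read_newick


def pytest_configure(config):
    warnings.filterwarnings("ignore", message="tree is not ultrametric")


@pytest.fixture
def three_tip():
    """((A:1,B:1):1,C:2); ultrametric, root age 2."""
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def two_tip():
    return read_newick("(A:1.5,B:1.5);")


@pytest.fixture(scope="session")
def yule_tree_50():
    """Neutral 50-tip pure-birth tree (habit evolving independently)."""
    cfg = SimConfig(
        seed=7, n_tips=50, early_mode="dependent", late_mode="dependent",
        lam_early=(0.14, 0.14), lam_late=(0.14, 0.14), mu_early=0.0, mu_late=0.0,
        q01_early=0.05, q10_early=0.03, q01_late=0.05, q10_late=0.03, qh=0.0,
    )
    tree, traits, _ = simulate_sse_dataset(cfg, root_state=0)
    return tree, traits


def neutral_tree(seed, n_tips, lam=0.15, mu=0.0, q01=0.05, q10=0.03):
    """Birth-death tree with habit evolving neutrally (no rate dependence)."""
    cfg = SimConfig(
        seed=seed, n_tips=n_tips, early_mode="dependent", late_mode="dependent",
        lam_early=(lam, lam), lam_late=(lam, lam), mu_early=mu, mu_late=mu,
        q01_early=q01, q10_early=q10, q01_late=q01, q10_late=q10, qh=0.0,
    )
    return simulate_sse_dataset(cfg, root_state=0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
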