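import numpy as np
import pytest

from fbdage.trees import EXTANT_SAMPLED, FOSSIL, Node, Tree


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def three_tip_tree():
    """((A:4,B:4):6,C:10) with origin 12."""
    root = Node(10.0)
    a = root.add_child(Node(4.0))
    root.add_child(Node(0.0, "C", EXTANT_SAMPLED))
    a.add_child(Node(0.0, "A", EXTANT_SAMPLED))
    a.add_child(Node(0.0, "B", EXTANT_SAMPLED))
    return Tree(root, 12.0)


@pytest.fixture
def sa_tree():
    """Two extant tips with a sampled-ancestor fossil on the stem of A."""
    root = Node(10.0)
    att = root.add_child(Node(6.0))
    root.add_child(Node(0.0, "B", EXTANT_SAMPLED))
    att.add_child(Node(6.0, "F1", FOSSIL, sampled_ancestor=True))
    att.add_child(Node(0.0, "A", EXTANT_SAMPLED))
    return Tree(root, 12.0)


def random_sampled_tree(rng, n_extant=5, origin=40.0, lam=0.08, mu=0.03, rho=0.7):
    """A random fossil-free sampled tree via simulation + pruning."""
    from fbdage.treesim import BirthDeathConfig, prune_to_reconstructed, simulate_accepted_tree

    cfg = BirthDeathConfig(
        origin_age=origin, lam=lam, mu=mu, rho=rho,
        min_extant_sampled=n_extant, max_extant_sampled=n_extant,
    )
    tree, _ = simulate_accepted_tree(cfg, rng)
    return prune_to_reconstructed(tree, [])
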