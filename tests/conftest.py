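"""Shared fixtures and independent oracles for the test suite."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy.linalg import expm

from sodalake import synthetic_data as sd
from sodalake.community_profiling import abundance_table
from sodalake.trees import Phylogeny

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


# ---------------------------------------------------------------- oracles

def enumeration_loglik(tree: Phylogeny, tip_matrix: np.ndarray,
                       Q: np.ndarray, root_freq: np.ndarray) -> float:
    """Brute-force likelihood: sum over every joint state assignment.

    Independent of the pruning implementation: transition matrices come
    from scipy's expm and the sum runs over all K^n_nodes assignments.
    """
    K = Q.shape[0]
    P = [expm(Q * tree.edge_length[node]) for node in range(tree.n_nodes)]
    total = 0.0
    for assign in itertools.product(range(K), repeat=tree.n_nodes):
        w = root_freq[assign[tree.root]]
        for node in range(tree.n_nodes):
            if node == tree.root:
                continue
            w *= P[node][assign[tree.parent[node]], assign[node]]
            if w == 0.0:
                break
        else:
            for tip in range(tree.n_tips):
                w *= tip_matrix[tip, assign[tip]]
            total += w
    return math.log(total)


def random_four_tip_tree(rng: np.random.Generator) -> Phylogeny:
    """A random 4-tip rooted binary tree (balanced or caterpillar shape)."""
    bl = rng.uniform(0.05, 1.0, size=7)
    if rng.uniform() < 0.5:  # balanced: ((A,B),(C,D))
        parent = np.array([4, 4, 5, 5, 6, 6, -1])
        children = [[], [], [], [], [0, 1], [2, 3], [4, 5]]
    else:  # caterpillar: (((A,B),C),D)
        parent = np.array([4, 4, 5, 6, 5, 6, -1])
        children = [[], [], [], [], [0, 1], [4, 2], [5, 3]]
    bl[6] = 0.0
    return Phylogeny(tip_labels=["A", "B", "C", "D"], parent=parent,
                     children=children, edge_length=bl, root=6)


def star_tree(n_tips: int, branch_length: float) -> Phylogeny:
    parent = np.concatenate([np.full(n_tips, n_tips), [-1]])
    children = [[] for _ in range(n_tips)] + [list(range(n_tips))]
    bl = np.concatenate([np.full(n_tips, float(branch_length)), [0.0]])
    return Phylogeny(tip_labels=[f"t{i}" for i in range(n_tips)],
                     parent=parent, children=children, edge_length=bl,
                     root=n_tips)


def two_tip_tree(bl_a: float, bl_b: float) -> Phylogeny:
    return Phylogeny(tip_labels=["A", "B"], parent=np.array([2, 2, -1]),
                     children=[[], [], [0, 1]],
                     edge_length=np.array([bl_a, bl_b, 0.0]), root=2)


# ---------------------------------------------------------------- fixtures

@pytest.fixture(scope="session")
def small_sim_config():
    return sd.SimConfig(n_species=120, n_samples_per_region=4,
                        decay_scale_km=3000.0, seed=7)


@pytest.fixture(scope="session")
def small_community(small_sim_config):
    return sd.generate_abundance_inputs(small_sim_config)


@pytest.fixture(scope="session")
def small_table(small_community):
    return abundance_table(small_community.mapping_summaries,
                           small_community.sample_metadata)
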