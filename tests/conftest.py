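import numpy as np
import pytest

from paleosky import BDSKYParams, CoalescentParams, make_time_grid
from paleosky.core import Node, TimeTree

# change times of the eight geological bins used throughout
EIGHT_BIN_BOUNDARIES = [66.0, 89.8, 121.4, 145.0, 161.5, 174.7, 201.4, 237.0]


@pytest.fixture
def grid1():
    """Single-bin grid anchored at the K-Pg boundary."""
    return make_time_grid([66.0])


@pytest.fixture
def grid8():
    return make_time_grid(EIGHT_BIN_BOUNDARIES)


@pytest.fixture
def grid_zero():
    """Single-bin grid with the reference at the true present (0 Ma is
    disallowed, so use a tiny positive reference)."""
    return make_time_grid([1e-9])


def balanced_tree(ages=(0.0, 0.0, 0.0, 0.0), internal=(5.0, 7.0, 10.0), origin=None):
    """((A,B),(C,D)) with given tip ages and internal ages
    (AB ancestor, CD ancestor, root)."""
    a, b, c, d = (Node(age=t, label=lab) for t, lab in zip(ages, "ABCD"))
    ab = Node(age=internal[0], children=[a, b])
    cd = Node(age=internal[1], children=[c, d])
    root = Node(age=internal[2], children=[ab, cd])
    return TimeTree(root, origin_age=origin)


@pytest.fixture
def four_tip_tree():
    return balanced_tree()


@pytest.fixture
def fossil_tree():
    """5 fossil tips at positive ages, origin set: a valid BDSKY input."""
    tips = [Node(age=t, label=f"T{i}") for i, t in enumerate((2.0, 3.5, 1.0, 6.0, 9.0))]
    n1 = Node(age=8.0, children=[tips[0], tips[1]])
    n2 = Node(age=12.0, children=[n1, tips[2]])
    n3 = Node(age=15.0, children=[tips[3], tips[4]])
    root = Node(age=20.0, children=[n2, n3])
    return TimeTree(root, origin_age=25.0)


def random_fossil_tree(rng, n_tips=5, depth=20.0):
    """Random binary tree with fossil tips at positive ages; coalescent-
    style construction, independent of the simulators under test."""
    nodes = [Node(age=float(rng.uniform(0.5, depth * 0.4)), label=f"T{i}") for i in range(n_tips)]
    age = float(max(nd.age for nd in nodes))
    while len(nodes) > 1:
        age += float(rng.uniform(0.5, depth / n_tips))
        i, j = rng.choice(len(nodes), size=2, replace=False)
        merged = Node(age=age, children=[nodes[i], nodes[j]])
        nodes = [nd for k, nd in enumerate(nodes) if k not in (int(i), int(j))] + [merged]
    return TimeTree(nodes[0], origin_age=age + float(rng.uniform(1.0, 10.0)))
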