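import numpy as np
import pytest

from morphoclock.trees import TimeTree


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture()
def three_taxon_tree():
    """((A:1,B:1):1,C:2); root age 2, all tips extant."""
    return TimeTree([-1, 0, 0, 1, 1], [2.0, 1.0, 0.0, 0.0, 0.0], ["", "", "C", "A", "B"])


@pytest.fixture()
def five_taxon_tree():
    """Dated 5-taxon binary tree, root at 10 Ma, all tips extant."""
    parent = [-1, 0, 0, 1, 1, 2, 2, 5, 5]
    ages = [10.0, 6.0, 7.0, 0.0, 0.0, 4.0, 0.0, 0.0, 0.0]
    labels = ["", "", "", "A", "B", "", "C", "D", "E"]
    return TimeTree(parent, ages, labels)


def random_dated_tree(n_tips, rng, max_root_age=3.0, fossil_prob=0.0):
    """Random binary dated tree by recursive splitting (test utility)."""
    parent = [-1]
    ages = [float(rng.uniform(1.0, max_root_age))]
    labels = [""]
    frontier = [0]
    while len(frontier) < n_tips:
        v = frontier.pop(int(rng.integers(len(frontier))))
        for _ in range(2):
            idx = len(parent)
            parent.append(v)
            ages.append(float(rng.uniform(0.0, ages[v])))
            labels.append("")
            frontier.append(idx)
    for i, v in enumerate(frontier):
        labels[v] = f"T{i}"
        if rng.random() >= fossil_prob:
            ages[v] = 0.0
    return TimeTree(parent, ages, labels)
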