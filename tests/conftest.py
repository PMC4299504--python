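import math

import numpy as np
import pytest

from budmorph.core import (
    NodeRecord,
    SimulationConfig,
    Tree,
    bifurcate_tips,
    run,
)


def grow_rounds(n_rounds: int, divergence: float = 93.0, length: float = 1.0) -> Tree:
    """A tree after n synchronous bifurcation rounds, unit-ish segment lengths."""
    tree = Tree([NodeRecord(1, None, length, 0.0, 0.0, "root")], root_heading=90.0)
    for k in range(n_rounds):
        tree = bifurcate_tips(tree, divergence, length, time=float(k + 1))
    return tree


def worked_y() -> Tree:
    """The reference retraction geometry: stalk from (0,0) to (0,1), daughters
    reaching (-1,2) and (1,2), i.e. a 90-degree divergence 'Y'."""
    nodes = [
        NodeRecord(1, None, 0.0, 0.0, 0.0, "root"),  # root node at the origin
        NodeRecord(2, 1, 1.0, 0.0, 0.0, "internal"),
        NodeRecord(3, 2, math.sqrt(2.0), -45.0, 0.0, "tip"),
        NodeRecord(4, 2, math.sqrt(2.0), 45.0, 0.0, "tip"),
    ]
    return Tree(nodes, root_heading=90.0)


def random_tree(seed: int, max_depth: int = 4) -> Tree:
    """Random strictly bifurcating tree with random lengths and angles."""
    rng = np.random.default_rng(seed)
    parents: dict[int, int | None] = {1: None}
    lengths = {1: float(rng.uniform(0.5, 2.0))}
    angles = {1: 0.0}
    children: dict[int, list[int]] = {1: []}
    frontier = [(1, 0)]
    next_id = 2
    while frontier:
        nid, depth = frontier.pop()
        if depth >= max_depth or rng.random() < 0.3:
            continue
        for sign in (-1.0, 1.0):
            parents[next_id] = nid
            lengths[next_id] = float(rng.uniform(0.2, 2.0))
            angles[next_id] = sign * float(rng.uniform(10.0, 80.0))
            children[nid].append(next_id)
            children[next_id] = []
            frontier.append((next_id, depth + 1))
            next_id += 1
    records = [
        NodeRecord(
            nid,
            parents[nid],
            lengths[nid],
            angles[nid],
            0.0,
            "root" if parents[nid] is None else ("tip" if not children[nid] else "internal"),
        )
        for nid in parents
    ]
    return Tree(records, root_heading=float(rng.uniform(0.0, 360.0)))


@pytest.fixture(scope="session")
def run_growth_only():
    return run(SimulationConfig(retraction_enabled=False))


@pytest.fixture(scope="session")
def run_length_based():
    return run(SimulationConfig(retraction_mode="length_based"))


@pytest.fixture(scope="session")
def run_tip_anchored():
    return run(SimulationConfig(retraction_mode="tip_anchored"))
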