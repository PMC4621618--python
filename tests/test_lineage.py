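"""Lineage trees from event logs: Newick export and clonal metrics."""

from __future__ import annotations

import io

import dendropy
import numpy as np
import pandas as pd
import pytest

from germsim.lineage import LineageTree, min_generations_to_fill


def _events(rows):
    return pd.DataFrame(rows, columns=["t", "kind", "cell", "parent",
                                       "x", "y", "z", "axial", "radius",
                                       "mechanism"])


def _birth(t, cell, parent=None):
    return dict(t=t, kind="birth", cell=cell, parent=parent, x=0.0, y=0.0,
                z=0.0, axial=0.0, radius=1.0, mechanism="")


def _end(t, cell, kind):
    return dict(t=t, kind=kind, cell=cell, parent=None, x=0.0, y=0.0,
                z=0.0, axial=0.0, radius=1.0, mechanism="")


def test_generations_to_fill_distal_tip():
    """Eight synchronous binary divisions suffice for >= 200 cells
    (2**8 = 256, 2**7 = 128)."""
    assert min_generations_to_fill(200) == 8
    assert min_generations_to_fill(128) == 7
    assert min_generations_to_fill(1) == 0


def test_single_founder_newick():
    ev = _events([_birth(0.0, 0), _end(7200.0, 0, "apoptosis")])
    tree = LineageTree.from_events(ev)
    assert tree.roots == [0]
    assert tree.to_newick() == "c0:2;"      # lifetime in hours


def test_one_division_round_trips_through_dendropy():
    """A division makes a two-leaf cherry; an independent Newick parser
    recovers both labels and lifetimes."""
    ev = _events([
        _birth(0.0, 0),
        _end(3600.0, 0, "division"),
        _birth(3600.0, 1, 0), _birth(3600.0, 2, 0),
        _end(10800.0, 1, "fertilization"),
        _end(14400.0, 2, "apoptosis"),
    ])
    tree = LineageTree.from_events(ev)
    text = tree.to_newick()
    parsed = dendropy.Tree.get(data=text, schema="newick")
    taxa = {leaf.taxon.label for leaf in parsed.leaf_node_iter()}
    assert taxa == {"c1", "c2"}
    lengths = {leaf.taxon.label: leaf.edge.length
               for leaf in parsed.leaf_node_iter()}
    assert lengths["c1"] == pytest.approx(2.0)
    assert lengths["c2"] == pytest.approx(3.0)
    root = parsed.seed_node
    assert root.edge.length == pytest.approx(1.0)


def test_leaf_count_identity_on_random_logs(rng):
    """Leaves = births - internal nodes, for random division forests."""
    rows = [_birth(0.0, 0)]
    next_id = 1
    alive = [0]
    t = 0.0
    for _ in range(60):
        t += 100.0
        i = int(rng.integers(0, len(alive)))
        cell = alive.pop(i)
        if rng.random() < 0.6:
            rows.append(_end(t, cell, "division"))
            rows += [_birth(t, next_id, cell), _birth(t, next_id + 1, cell)]
            alive += [next_id, next_id + 1]
            next_id += 2
        else:
            rows.append(_end(t, cell, "apoptosis"))
        if not alive:
            break
    tree = LineageTree.from_events(_events(rows))
    births = sum(1 for r in rows if r["kind"] == "birth")
    internal = sum(1 for n in tree.nodes.values() if n.children)
    assert len(tree.leaves()) == births - internal


def test_leaf_causes_partition():
    """Non-censored leaves are apoptosis or fertilization; internal nodes
    are divisions."""
    ev = _events([
        _birth(0.0, 0), _end(10.0, 0, "division"),
        _birth(10.0, 1, 0), _birth(10.0, 2, 0),
        _end(20.0, 1, "apoptosis"),
    ])
    tree = LineageTree.from_events(ev, run_end=30.0)
    for cid in tree.leaves():
        assert tree.nodes[cid].cause in ("apoptosis", "fertilization",
                                         "censored")
    for cid, node in tree.nodes.items():
        if node.children:
            assert node.cause == "division"


@pytest.fixture
def three_generation_tree():
    ev = _events([
        _birth(0.0, 0),
        _end(10.0, 0, "division"),
        _birth(10.0, 1, 0), _birth(10.0, 2, 0),
        _end(30.0, 1, "division"),
        _birth(30.0, 3, 1), _birth(30.0, 4, 1),
        _end(50.0, 3, "division"),
        _birth(50.0, 5, 3), _birth(50.0, 6, 3),
    ])
    return LineageTree.from_events(ev, run_end=100.0)


def test_generation_numbers_follow_divisions(three_generation_tree):
    t = three_generation_tree
    assert t.nodes[0].generation == 0
    assert t.nodes[2].generation == 1
    assert t.nodes[4].generation == 2
    assert t.nodes[6].generation == 3


def test_max_generation_separation(three_generation_tree):
    """At t=60 the alive set is {2 (gen1), 4 (gen2), 5, 6 (gen3)}."""
    t = three_generation_tree
    assert t.max_generation_separation(60.0, ids=[2, 4, 5, 6]) == 2
    # hand-picked generations 3, 5, 9 -> separation 6
    ev = _events([_birth(0.0, 0)])
    tree = LineageTree.from_events(ev, run_end=10.0)
    tree.nodes[0].generation = 3
    for cid, gen in ((10, 5), (11, 9)):
        tree.nodes[cid] = type(tree.nodes[0])(
            cell=cid, parent=None, birth=0.0, end=10.0, cause="censored",
            generation=gen)
    assert tree.max_generation_separation(5.0, ids=[0, 10, 11]) == 6


def test_max_generation_separation_errors(three_generation_tree):
    with pytest.raises(ValueError):
        three_generation_tree.max_generation_separation(60.0, ids=[])


def test_founder_assignment(three_generation_tree):
    t = three_generation_tree
    # at t0=20 the alive cells are 1 and 2; later cells map back to them
    mapping = t.founder_assignment(20.0, 60.0)
    assert mapping[2] == 2
    assert mapping[4] == 1 and mapping[5] == 1 and mapping[6] == 1
    # t = t0 is the identity on the alive set
    ident = t.founder_assignment(20.0, 20.0)
    assert ident == {1: 1, 2: 2}


def test_founder_assignment_constant_along_paths(three_generation_tree):
    t = three_generation_tree
    mapping = t.founder_assignment(20.0, 60.0)
    for cell in (5, 6):
        node = t.nodes[cell]
        while node.parent is not None and t.nodes[node.parent].birth >= 20.0:
            assert mapping.get(cell) == t.ancestor_at(node.parent, 20.0)
            node = t.nodes[node.parent]


def test_distal_tip_dominance_on_scripted_log(three_generation_tree):
    """Dominance is declared on the first frame where the region contains a
    single t0-founder's descendants."""
    t = three_generation_tree
    frames = []
    # frame at t=40: cells 2 (founder 2) and 4 (founder 1) inside
    frames.append(pd.DataFrame(dict(t=40.0, cell=[2, 4],
                                    x=[1.0, 2.0], y=0.0, z=0.0,
                                    radius=1.0, fate="mitosis")))
    # frame at t=60: only descendants of founder 1 remain inside
    frames.append(pd.DataFrame(dict(t=60.0, cell=[5, 6],
                                    x=[1.0, 2.0], y=0.0, z=0.0,
                                    radius=1.0, fate="mitosis")))
    traj = pd.concat(frames, ignore_index=True)
    inside = lambda pos: pos[:, 0] < 10.0
    assert t.distal_tip_dominance_time(traj, inside, 20.0) == 60.0
    # single founder at t0 -> dominated immediately
    ev = _events([_birth(0.0, 0)])
    solo = LineageTree.from_events(ev, run_end=100.0)
    traj1 = pd.DataFrame(dict(t=[20.0], cell=[0], x=[1.0], y=0.0, z=0.0,
                              radius=1.0, fate="mitosis"))
    assert solo.distal_tip_dominance_time(traj1, inside, 20.0) == 20.0


def test_corrupt_log_detected():
    ev = _events([_birth(5.0, 0), _end(1.0, 0, "apoptosis")])
    with pytest.raises(ValueError):
        LineageTree.from_events(ev)
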