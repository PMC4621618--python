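"""Lineage bookkeeping: trees from event logs, Newick export, clonal metrics.

A lineage tree is reconstructed exactly from the run's birth/death/
fertilization log (no inference).  Single-founder runs yield a single-rooted
tree; steady-state-seeded runs yield a forest with one root per seeded cell.

Newick dialect (fixed, for bit-reproducible export): labels on both leaves
and internal nodes, branch lengths in **hours** with 6 significant digits,
no quoted labels; cells alive at run end appear as censored leaves whose end
time is the run end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional

import numpy as np
import pandas as pd

__all__ = ["LineageNode", "LineageTree", "min_generations_to_fill"]


def min_generations_to_fill(target: int) -> int:
    """Smallest generation count of synchronous binary divisions from one
    founder that yields at least ``target`` cells (2**g >= target)."""
    if target < 1:
        raise ValueError("target must be >= 1")
    return int(math.ceil(math.log2(target)))


@dataclass
class LineageNode:
    cell: int
    parent: Optional[int]
    birth: float                      # s
    end: Optional[float] = None       # s; None while alive / un-finalised
    cause: str = "censored"           # division | apoptosis | fertilization | censored
    generation: int = 0
    children: List[int] = field(default_factory=list)

    @property
    def lifetime_h(self) -> float:
        end = self.end if self.end is not None else self.birth
        return (end - self.birth) / 3600.0


class LineageTree:
    """A forest of cell lineages keyed by cell id."""

    def __init__(self):
        self.nodes: Dict[int, LineageNode] = {}

    # -- construction ---------------------------------------------------
    @classmethod
    def from_events(cls, events: pd.DataFrame,
                    run_end: Optional[float] = None) -> "LineageTree":
        """Build the forest from an event log (birth/division/apoptosis/
        fertilization records).  Cells without a terminal record are censored
        at ``run_end`` (default: the last event time)."""
        tree = cls()
        if len(events):
            run_end = float(events.t.max()) if run_end is None else run_end
        else:
            run_end = run_end or 0.0
        for row in events.itertuples(index=False):
            if row.kind == "birth":
                parent = None if pd.isna(row.parent) else int(row.parent)
                node = LineageNode(cell=int(row.cell), parent=parent,
                                   birth=float(row.t))
                tree.nodes[node.cell] = node
                if parent is not None:
                    pnode = tree.nodes[parent]
                    pnode.children.append(node.cell)
                    node.generation = pnode.generation + 1
            elif row.kind in ("division", "apoptosis", "fertilization"):
                node = tree.nodes[int(row.cell)]
                node.end = float(row.t)
                node.cause = row.kind
        for node in tree.nodes.values():
            if node.end is None:
                node.end = run_end
                node.cause = "censored"
            if node.end < node.birth - 1e-9:
                raise ValueError(f"cell {node.cell}: end before birth")
        tree._validate()
        return tree

    def _validate(self):
        for node in self.nodes.values():
            seen = set()
            cur = node
            while cur.parent is not None:
                if cur.cell in seen:
                    raise ValueError("cyclic parent links")
                seen.add(cur.cell)
                cur = self.nodes[cur.parent]

    # -- basic structure --------------------------------------------------
    @property
    def roots(self) -> List[int]:
        return sorted(c for c, n in self.nodes.items() if n.parent is None)

    def leaves(self) -> List[int]:
        return sorted(c for c, n in self.nodes.items() if not n.children)

    def alive_at(self, t: float) -> List[int]:
        return sorted(c for c, n in self.nodes.items()
                      if n.birth <= t < (n.end if n.cause != "censored"
                                         else float("inf")))

    def ancestor_at(self, cell: int, t0: float) -> int:
        """The unique ancestor of ``cell`` that was alive at time ``t0``."""
        cur = self.nodes[cell]
        while True:
            alive_end = cur.end if cur.cause != "censored" else float("inf")
            if cur.birth <= t0 < alive_end:
                return cur.cell
            if cur.parent is None:
                raise ValueError(
                    f"cell {cell} has no ancestor alive at t0={t0}")
            cur = self.nodes[cur.parent]

    # -- Newick export ----------------------------------------------------
    def to_newick(self, root: Optional[int] = None) -> str:
        """Serialise one rooted tree (or the whole forest, one tree per
        line) in the fixed dialect described in the module docstring."""
        if root is not None:
            return self._newick_one(root)
        return "\n".join(self._newick_one(r) for r in self.roots)

    def _newick_one(self, root: int) -> str:
        def render(cell: int) -> str:
            node = self.nodes[cell]
            label = f"c{cell}:{node.lifetime_h:.6g}"
            if not node.children:
                return label
            inner = ",".join(render(ch) for ch in sorted(node.children))
            return f"({inner}){label}"

        return render(root) + ";"

    # -- metrics -----------------------------------------------------------
    def max_generation_separation(self, t: float,
                                  ids: Optional[Iterable[int]] = None) -> int:
        """Max generation-number difference among the dividing population
        alive at ``t``.

        ``ids`` restricts the population (e.g. to cells decoded as mitotic);
        by default cells alive at ``t`` whose eventual end cause is division
        are used -- the "dividing cells" of a lineage plot.
        """
        if ids is None:
            pool = [c for c in self.alive_at(t)
                    if self.nodes[c].cause == "division"]
        else:
            alive = set(self.alive_at(t))
            pool = [c for c in ids if c in alive]
        if not pool:
            raise ValueError(f"no dividing cells alive at t={t}")
        gens = [self.nodes[c].generation for c in pool]
        return max(gens) - min(gens)

    def founder_assignment(self, t0: float, t: float) -> Dict[int, int]:
        """Map every cell alive at ``t`` to its unique ancestor alive at
        ``t0`` (the "colouring" of clonal-dominance analysis)."""
        if t < t0:
            raise ValueError("t must be >= t0")
        return {c: self.ancestor_at(c, t0) for c in self.alive_at(t)}

    def distal_tip_dominance_time(self, trajectory: pd.DataFrame,
                                  region_test, t0: float):
        """First frame time >= t0 at which all cells inside the distal-tip
        region descend from a single ancestor alive at t0.

        ``region_test`` maps an (n, 3) position array to a boolean mask
        (e.g. membership of the DELTA zone).  Returns the simulated time, or
        ``None`` if dominance is never reached in the trajectory.
        """
        for t, frame in trajectory[trajectory.t >= t0].groupby("t", sort=True):
            pos = frame[["x", "y", "z"]].to_numpy()
            inside = np.asarray(region_test(pos), dtype=bool)
            cells = frame.cell.to_numpy()[inside]
            if len(cells) == 0:
                continue
            founders = {self.ancestor_at(int(c), t0) for c in cells}
            if len(founders) == 1:
                return float(t)
        return None
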