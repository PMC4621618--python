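"""Qualitative network engine.

A qualitative network (QN) is a finite, deterministic, synchronous dynamical
system.  Each variable ``v`` holds an integer level in ``[0, N_v]`` and is
assigned a *target function* ``T_v``; on every tick each variable moves one
step toward its (clamped) target, all variables updating concurrently from
the same predecessor state:

    d' = d - 1   if T_v(s) < d and d > 0
    d' = d + 1   if T_v(s) > d and d < N_v
    d' = d       otherwise

Because the update is deterministic on a finite state space, every execution
ends in a cycle; if every state reaches the same length-1 cycle the network
is *stabilizing* and that state is its stable state.

Two target forms are supported:

* the default *average difference*: round(mean(activators) - mean(inhibitors)),
  rounded half away from zero and clamped to the variable's range (an empty
  activator or inhibitor set contributes 0);
* an explicit integer expression tree (see :mod:`germsim.qn.expr`).

The same evaluator runs on scalars and on numpy arrays, so one code path
serves per-cell simulation, whole-population batch stepping in the hybrid
simulator, and exhaustive state-space enumeration for attractor search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .expr import Const, Expr, Var

__all__ = [
    "Variable", "AvgTarget", "ExprTarget", "QNSpec", "AttractorReport",
    "Trajectory", "StateSpaceTooLarge", "evaluate_target", "qn_step",
    "qn_step_batch", "run_to_attractor", "find_all_attractors",
    "apply_environment",
]

State = tuple  # tuple[int, ...]


class StateSpaceTooLarge(RuntimeError):
    """Exhaustive enumeration refused: state space exceeds the guard limit."""


@dataclass(frozen=True)
class Variable:
    """A QN variable with levels 0..nmax (nmax=1 for Boolean variables)."""

    name: str
    nmax: int = 1

    def __post_init__(self):
        if not self.name:
            raise ValueError("variable name must be non-empty")
        if self.nmax < 1:
            raise ValueError(f"{self.name}: granularity must be >= 1")


@dataclass(frozen=True)
class AvgTarget:
    """Default target: rounded average difference of activators and inhibitors."""

    activators: tuple = ()
    inhibitors: tuple = ()

    def names(self) -> frozenset:
        return frozenset(self.activators) | frozenset(self.inhibitors)


@dataclass(frozen=True)
class ExprTarget:
    """Explicit target given as an integer expression tree."""

    expr: Expr

    def names(self) -> frozenset:
        return self.expr.names()


Target = Union[AvgTarget, ExprTarget]


def _round_half_away(x):
    """Round half away from zero (BMA convention), elementwise."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass(frozen=True)
class QNSpec:
    """A qualitative network: variables, target functions, designated inputs.

    ``inputs`` are externally driven variables; any input without an explicit
    target defaults to holding its current value (identity target), so free
    inputs act as constants chosen by the initial state.
    """

    variables: tuple
    targets: Mapping[str, Target]
    inputs: frozenset = frozenset()
    name: str = ""

    def __post_init__(self):
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("variable names must be unique")
        known = set(names)
        targets = dict(self.targets)
        for v in self.variables:
            if v.name not in targets:
                if v.name in self.inputs:
                    targets[v.name] = ExprTarget(Var(v.name))
                else:
                    raise ValueError(f"variable {v.name} has no target")
        for vname, tgt in targets.items():
            if vname not in known:
                raise ValueError(f"target for unknown variable {vname}")
            missing = tgt.names() - known
            if missing:
                raise ValueError(
                    f"target of {vname} references unknown variables {sorted(missing)}")
        extra = self.inputs - known
        if extra:
            raise ValueError(f"inputs not in variable list: {sorted(extra)}")
        object.__setattr__(self, "targets", targets)
        object.__setattr__(self, "variables", tuple(self.variables))
        object.__setattr__(self, "inputs", frozenset(self.inputs))

    # -- introspection -------------------------------------------------
    @property
    def m(self) -> int:
        return len(self.variables)

    def index(self, name: str) -> int:
        for i, v in enumerate(self.variables):
            if v.name == name:
                return i
        raise KeyError(name)

    def nmax(self, name: str) -> int:
        return self.variables[self.index(name)].nmax

    @property
    def n_states(self) -> int:
        n = 1
        for v in self.variables:
            n *= v.nmax + 1
        return n

    def validate_state(self, state: Sequence[int]) -> State:
        if len(state) != self.m:
            raise ValueError(
                f"state length {len(state)} != variable count {self.m}")
        out = []
        for v, d in zip(self.variables, state):
            d = int(d)
            if not 0 <= d <= v.nmax:
                raise ValueError(f"{v.name}={d} outside [0, {v.nmax}]")
            out.append(d)
        return tuple(out)

    # -- state <-> integer codec (mixed radix, variable 0 most significant)
    def encode(self, states: np.ndarray) -> np.ndarray:
        states = np.asarray(states)
        code = np.zeros(states.shape[:-1], dtype=np.int64)
        for i, v in enumerate(self.variables):
            code = code * (v.nmax + 1) + states[..., i]
        return code

    def decode(self, codes: np.ndarray) -> np.ndarray:
        codes = np.asarray(codes, dtype=np.int64)
        out = np.zeros(codes.shape + (self.m,), dtype=np.int16)
        for i in range(self.m - 1, -1, -1):
            base = self.variables[i].nmax + 1
            out[..., i] = codes % base
            codes = codes // base
        return out

    def all_states(self, limit: int = 2 ** 20) -> np.ndarray:
        if self.n_states > limit:
            raise StateSpaceTooLarge(
                f"{self.n_states} states exceeds enumeration limit {limit}")
        return self.decode(np.arange(self.n_states))


def _env_of(spec: QNSpec, states: np.ndarray) -> dict:
    """Map variable name -> column (or scalar) for target evaluation."""
    return {v.name: states[..., i] for i, v in enumerate(spec.variables)}


def _target_values(spec: QNSpec, var: str, env: Mapping) -> np.ndarray:
    tgt = spec.targets[var]
    nmax = spec.nmax(var)
    if isinstance(tgt, AvgTarget):
        act = (np.mean([np.asarray(env[a], dtype=float) for a in tgt.activators], axis=0)
               if tgt.activators else 0.0)
        inh = (np.mean([np.asarray(env[a], dtype=float) for a in tgt.inhibitors], axis=0)
               if tgt.inhibitors else 0.0)
        t = _round_half_away(act - inh)
    else:
        t = np.asarray(tgt.expr.eval(env))
    return np.clip(t, 0, nmax)


def evaluate_target(spec: QNSpec, state: Sequence[int], var: str) -> int:
    """Evaluate ``T_var(state)``, clamped to the variable's range."""
    if var not in spec.targets:
        raise KeyError(f"unknown variable {var!r}")
    state = spec.validate_state(state)
    env = {v.name: d for v, d in zip(spec.variables, state)}
    return int(_target_values(spec, var, env))


def qn_step_batch(spec: QNSpec, states: np.ndarray) -> np.ndarray:
    """Synchronous update of a batch of states, shape (..., m)."""
    states = np.asarray(states)
    env = _env_of(spec, states)
    out = np.empty_like(states)
    for i, v in enumerate(spec.variables):
        t = _target_values(spec, v.name, env)
        d = states[..., i]
        out[..., i] = d + np.sign(t - d).astype(states.dtype)
    return out


def qn_step(spec: QNSpec, state: Sequence[int]) -> State:
    """One synchronous step from a single state (all variables concurrent)."""
    state = spec.validate_state(state)
    nxt = qn_step_batch(spec, np.asarray(state, dtype=np.int16))
    return tuple(int(x) for x in nxt)


@dataclass
class Trajectory:
    """A deterministic execution: visited states and the cycle it enters.

    ``states[cycle_start:]`` is one full period of the terminal cycle.
    """

    states: list
    cycle_start: int

    @property
    def cycle(self) -> list:
        return self.states[self.cycle_start:]

    @property
    def fixpoint(self) -> Optional[State]:
        c = self.cycle
        return c[0] if len(c) == 1 else None


def run_to_attractor(spec: QNSpec, start: Sequence[int],
                     step_cap: Optional[int] = None) -> Trajectory:
    """Iterate from ``start`` until a state repeats (visited-set detection).

    Always terminates within |state space| steps; ``step_cap`` is a safety
    bound whose violation signals an implementation bug.
    """
    state = spec.validate_state(start)
    seen = {state: 0}
    seq = [state]
    cap = step_cap if step_cap is not None else spec.n_states + 1
    for _ in range(cap):
        state = qn_step(spec, state)
        if state in seen:
            return Trajectory(states=seq, cycle_start=seen[state])
        seen[state] = len(seq)
        seq.append(state)
    raise RuntimeError("step cap exceeded without revisiting a state")


@dataclass
class AttractorReport:
    """Exhaustive attractor decomposition of a QN's state space.

    ``attractors`` lists each terminal cycle once (as a state sequence in
    update order); ``basin_sizes[i]`` counts states draining to attractor i.
    ``stabilizing`` is true iff there is exactly one attractor of length 1.
    """

    attractors: list
    basin_sizes: list
    n_states: int

    @property
    def stabilizing(self) -> bool:
        return len(self.attractors) == 1 and len(self.attractors[0]) == 1

    @property
    def stable_state(self) -> Optional[State]:
        return self.attractors[0][0] if self.stabilizing else None

    @property
    def fixpoints(self) -> list:
        return [a[0] for a in self.attractors if len(a) == 1]

    @property
    def cycles(self) -> list:
        return [a for a in self.attractors if len(a) > 1]


def find_all_attractors(spec: QNSpec, limit: int = 2 ** 20) -> AttractorReport:
    """Exhaustively map every state to its attractor.

    Vectorised: builds the full successor table, then iterates pointer
    doubling so that every state lands on its terminal cycle, and traces
    each distinct cycle once.  Refuses (raises :class:`StateSpaceTooLarge`)
    above ``limit`` states; callers must sample instead.
    """
    n = spec.n_states
    if n > limit:
        raise StateSpaceTooLarge(
            f"{n} states exceeds enumeration limit {limit}")
    states = spec.all_states(limit)
    succ = spec.encode(qn_step_batch(spec, states))
    # After ceil(log2(n)) squarings every pointer has advanced >= n steps,
    # hence lies on its cycle.
    g = succ.copy()
    for _ in range(max(1, math.ceil(math.log2(max(n, 2))))):
        g = g[g]
    on_cycle = np.unique(g)
    cycle_id = {}
    attractors = []
    for node in on_cycle.tolist():
        if node in cycle_id:
            continue
        cyc = [node]
        cur = int(succ[node])
        while cur != node:
            cyc.append(cur)
            cur = int(succ[cur])
        idx = len(attractors)
        for c in cyc:
            cycle_id[c] = idx
        attractors.append([tuple(int(x) for x in states[c]) for c in cyc])
    ids = np.array([cycle_id[int(x)] for x in g], dtype=np.int64)
    basin_sizes = np.bincount(ids, minlength=len(attractors)).tolist()
    return AttractorReport(attractors=attractors, basin_sizes=basin_sizes,
                           n_states=n)


def apply_environment(spec: QNSpec, clamps: Mapping[str, int]) -> QNSpec:
    """Clamp designated input variables to constant levels.

    Returns a new spec in which each clamped input's target is the constant
    clamp value; all other targets are untouched.  Clamping a non-input
    variable is an error (environments model *external* ligands only).
    """
    clamps = dict(getattr(clamps, "clamps", clamps))
    targets = dict(spec.targets)
    for name, value in clamps.items():
        if name not in spec.inputs:
            raise ValueError(f"{name!r} is not an input variable")
        value = int(value)
        if not 0 <= value <= spec.nmax(name):
            raise ValueError(f"clamp {name}={value} outside range")
        targets[name] = ExprTarget(Const(value))
    return replace(spec, targets=targets)
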