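"""Cross-environment fix-point proofs and compartment-chain analysis.

Cells at a boundary between two gonad compartments diffuse back and forth, so
their network alternates between two environments (two sets of input clamps).
:func:`prove_crossing` certifies that every state accessible this way from
the stable state of the first environment still reaches a single fix point in
the second -- i.e. that stability of the niche environment *propagates* and
fate progression stays invariant despite an unstable downstream environment.

The procedure is a worklist closure over deterministic trajectories:

1. identify the stable state ``A`` of the stable environment;
2. simulate from ``A`` in the other environment to its fix point ``B``,
   collecting every intermediate state;
3. for each collected state, simulate in the stable environment back to
   ``A`` (collecting states), and simulate every newly seen state in the
   other environment, checking it also reaches ``B``;
4. repeat until no new states appear (verdict ``single_fixpoint``) or some
   trajectory ends in a different fix point or a cycle (``counterexample``).

:func:`compartment_chain` iterates the same idea along the gonad: the
terminal states of compartment *k* seed compartment *k+1*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Mapping, Optional, Sequence

from .qn.core import (QNSpec, StateSpaceTooLarge, apply_environment,
                      find_all_attractors, run_to_attractor)

__all__ = ["CrossingProof", "CompartmentReport", "prove_crossing",
           "compartment_chain", "NotStabilizingError"]


class NotStabilizingError(RuntimeError):
    """The designated stable environment is not stabilizing (precondition)."""


class VisitedBoundExceeded(RuntimeError):
    """Worklist grew past the configured ceiling; reported, never truncated."""


@dataclass
class CrossingProof:
    """Result of a cross-environment fix-point proof.

    ``verdict`` is ``"single_fixpoint"`` or ``"counterexample"``.  On success
    ``fixpoint`` is B, the unique fix point reached in the unstable
    environment from every accessible state.  On failure ``trace`` is the
    offending trajectory and ``alternative`` its terminal cycle.
    """

    verdict: str
    stable_state: tuple
    fixpoint: Optional[tuple] = None
    visited: set = field(default_factory=set)
    trace: Optional[list] = None
    alternative: Optional[list] = None

    @property
    def single_fixpoint(self) -> bool:
        return self.verdict == "single_fixpoint"


def _stable_state(spec: QNSpec, env, sample_certificate: int,
                  enumeration_limit: int):
    applied = apply_environment(spec, env)
    try:
        report = find_all_attractors(applied, limit=enumeration_limit)
        if not report.stabilizing:
            raise NotStabilizingError(
                f"environment is not stabilizing: {len(report.attractors)} "
                "attractors")
        return applied, report.stable_state
    except StateSpaceTooLarge:
        # sampled certificate: all sampled executions must share a fix point
        import numpy as np
        rng = np.random.default_rng(0)
        fixpoint = None
        for _ in range(sample_certificate):
            s = tuple(int(rng.integers(0, v.nmax + 1))
                      for v in applied.variables)
            traj = run_to_attractor(applied, s)
            if traj.fixpoint is None or (
                    fixpoint is not None and traj.fixpoint != fixpoint):
                raise NotStabilizingError(
                    "sampled executions do not share a single fix point")
            fixpoint = traj.fixpoint
        return applied, fixpoint


def prove_crossing(spec: QNSpec, env_stable, env_other,
                   max_visited: int = 200_000,
                   sample_certificate: int = 200,
                   enumeration_limit: int = 2 ** 20) -> CrossingProof:
    """Prove that all states accessible across the boundary between
    ``env_stable`` and ``env_other`` reach one fix point in ``env_other``.

    Raises :class:`NotStabilizingError` if the precondition (stable
    environment stabilizing) fails, and :class:`VisitedBoundExceeded` if the
    closure exceeds ``max_visited`` states.
    """
    spec_s, A = _stable_state(spec, env_stable, sample_certificate,
                              enumeration_limit)
    spec_o = apply_environment(spec, env_other)

    first = run_to_attractor(spec_o, A)
    if first.fixpoint is None:
        return CrossingProof(verdict="counterexample", stable_state=A,
                             visited=set(first.states), trace=first.states,
                             alternative=first.cycle)
    B = first.fixpoint

    visited = set(first.states)
    checked_other = set(first.states)      # states whose env_other fate is known
    worklist = list(first.states)
    while worklist:
        if len(visited) > max_visited:
            raise VisitedBoundExceeded(
                f"visited set exceeded {max_visited} states")
        state = worklist.pop()
        # relaxation back in the stable environment (must end at A)
        back = run_to_attractor(spec_s, state)
        for s in back.states:
            if s in visited:
                continue
            visited.add(s)
            if s not in checked_other:
                fwd = run_to_attractor(spec_o, s)
                if fwd.fixpoint != B:
                    return CrossingProof(
                        verdict="counterexample", stable_state=A, fixpoint=B,
                        visited=visited, trace=fwd.states,
                        alternative=fwd.cycle)
                for t in fwd.states:
                    checked_other.add(t)
                    if t not in visited:
                        visited.add(t)
                        worklist.append(t)
                worklist.append(s)
    return CrossingProof(verdict="single_fixpoint", stable_state=A,
                         fixpoint=B, visited=visited)


@dataclass
class CompartmentReport:
    """Terminal behaviour of one compartment, seeded from the previous one."""

    name: str
    environment: Mapping[str, int]
    terminal_states: list          # fix points reached from the seeds
    cycles: list                   # terminal cycles, if any
    fates: list                    # decoded labels (when a decoder is given)


def compartment_chain(spec: QNSpec, envs: Sequence,
                      decoder: Optional[Callable] = None,
                      enumeration_limit: int = 2 ** 20,
                      sample_certificate: int = 200) -> List[CompartmentReport]:
    """Propagate reachable states along an ordered chain of environments.

    The first environment must be stabilizing; each later compartment is
    seeded with the terminal states of its predecessor, and its own terminal
    attractors (from those seeds only) are recorded.  ``decoder`` maps a
    terminal state to a label (e.g. a fate).
    """
    if not envs:
        raise ValueError("empty environment chain")
    reports: List[CompartmentReport] = []
    _, A = _stable_state(spec, envs[0], sample_certificate, enumeration_limit)
    seeds = [A]
    reports.append(_report(spec, envs[0], [A], [], decoder))
    for env in envs[1:]:
        applied = apply_environment(spec, env)
        fixpoints: dict = {}
        cycles: dict = {}
        for s in seeds:
            traj = run_to_attractor(applied, s)
            if traj.fixpoint is not None:
                fixpoints[traj.fixpoint] = None
            else:
                key = tuple(sorted(traj.cycle))
                cycles[key] = traj.cycle
        terminal = list(fixpoints)
        reports.append(_report(spec, env, terminal, list(cycles.values()),
                               decoder))
        seeds = terminal
        if not seeds:
            break
    return reports


def _report(spec, env, terminal, cycles, decoder) -> CompartmentReport:
    fates = [decoder(spec, s) for s in terminal] if decoder else []
    return CompartmentReport(
        name=getattr(env, "name", "") or "",
        environment=dict(env), terminal_states=terminal, cycles=cycles,
        fates=fates)
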