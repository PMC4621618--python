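"""Independent brute-force oracle for the QN engine (test helper).

Re-implements target evaluation (exact rational arithmetic), the
synchronous +/-1 update and exhaustive attractor search with plain Python
dictionaries; shares no code with the engine it checks.
"""

from __future__ import annotations

import math
from fractions import Fraction

from germsim.qn import AvgTarget, ExprTarget, QNSpec, Variable, parse_expr



def oracle_target(spec, state, var):
    """Average-difference target via exact rational arithmetic."""
    tgt = spec.targets[var]
    env = {v.name: d for v, d in zip(spec.variables, state)}
    if isinstance(tgt, ExprTarget):
        t = tgt.expr.eval(env)
    else:
        act = (Fraction(sum(env[a] for a in tgt.activators),
                        len(tgt.activators)) if tgt.activators else Fraction(0))
        inh = (Fraction(sum(env[a] for a in tgt.inhibitors),
                        len(tgt.inhibitors)) if tgt.inhibitors else Fraction(0))
        diff = act - inh
        # round half away from zero
        t = math.floor(abs(diff) + Fraction(1, 2))
        t = t if diff >= 0 else -t
    return max(0, min(spec.nmax(var), int(t)))


def oracle_step(spec, state):
    out = []
    for i, v in enumerate(spec.variables):
        t = oracle_target(spec, state, v.name)
        d = state[i]
        if t < d and d > 0:
            out.append(d - 1)
        elif t > d and d < v.nmax:
            out.append(d + 1)
        else:
            out.append(d)
    return tuple(out)


def oracle_state_graph(spec):
    """Successor map over the entire state space, by brute enumeration."""
    import itertools
    ranges = [range(v.nmax + 1) for v in spec.variables]
    return {s: oracle_step(spec, s) for s in itertools.product(*ranges)}


def oracle_attractors(graph):
    """All terminal cycles of a deterministic finite map."""
    cycles = set()
    for start in graph:
        seen = {}
        s = start
        while s not in seen:
            seen[s] = len(seen)
            s = graph[s]
        # canonical rotation of the cycle containing s
        cyc = []
        c = s
        while True:
            cyc.append(c)
            c = graph[c]
            if c == s:
                break
        k = cyc.index(min(cyc))
        cycles.add(tuple(cyc[k:] + cyc[:k]))
    return cycles


def random_spec(rng, m=None, expr_fraction=0.3):
    """A random QN with state space <= 2**12."""
    m = int(rng.integers(2, 6)) if m is None else m
    names = [f"v{i}" for i in range(m)]
    variables = []
    targets = {}
    for i, name in enumerate(names):
        nmax = int(rng.integers(1, 4))
        variables.append(Variable(name, nmax))
    for name in names:
        others = [n for n in names]
        if rng.random() < expr_fraction:
            a, b = rng.choice(others, size=2)
            form = rng.integers(0, 3)
            text = {0: f"min({a}, {b})", 1: f"max({a}, 1 - {b})",
                    2: f"{a} + {b} - 1"}[int(form)]
            targets[name] = ExprTarget(parse_expr(text))
        else:
            k_a = int(rng.integers(0, 3))
            k_i = int(rng.integers(0, 2))
            act = tuple(rng.choice(others, size=k_a)) if k_a else ()
            inh = tuple(rng.choice(others, size=k_i)) if k_i else ()
            targets[name] = AvgTarget(activators=act, inhibitors=inh)
    spec = QNSpec(tuple(variables), targets)
    assert spec.n_states <= 2 ** 12
    return spec




def canon_cycle(cycle):
    k = cycle.index(min(cycle))
    return tuple(cycle[k:] + cycle[:k])
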