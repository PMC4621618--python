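"""Germline signaling network, fate decoding, and compartment environments.

The network is a minimal Boolean reconstruction of germ-cell signaling in the
*C. elegans* gonad:

* ``DELTA -> NOTCH`` drives the mitotic fate and suppresses pachytene entry
  (the distal tip niche);
* ``RASinput / VAB1 -> RAS -> MAPK`` drives pachytene exit into the diplotene
  fate and, through the ``CEP1 -> EGL1 -> CED3`` chain, the pro-apoptotic
  state (the chain length is immaterial to the dynamics and configurable);
* RAS downregulation (``RASdown``, bend entry) enables the diakinesis fate,
  which latches until NOTCH resets it;
* ``MSP -> VAB1 -> RAS`` reactivates MAPK in diakinetic oocytes and latches
  the maturation fate (sperm signal at the proximal end);
* a small meiotic cell-cycle block (``CCLICENSE`` gating the ``CYCB``/``APC``
  negative feedback) oscillates only from initial states carrying the
  license; NOTCH clears the license, so the distal-tip environment remains
  globally stabilizing while the ligand-free environment retains oscillatory
  executions from arbitrary initial states.

Exactly five Boolean fate variables exist (mitosis, pachytene, diplotene,
diakinesis, maturation), hence 32 joint fate assignments; the pro-apoptotic
state is reported separately through the chain output variable.

In the ``timed_ras`` variant, RAS latches on after a transient ``RASinput``
pulse and is turned off only by ``RASdown`` (timed pachytene-exit mechanism
instead of a spatial RAS-activating ligand).
"""

from __future__ import annotations

from enum import Enum
from typing import Iterable, List, Mapping, Sequence, Tuple

import numpy as np

from .qn.core import (AvgTarget, ExprTarget, QNSpec, Variable,
                      apply_environment)
from .qn.expr import parse_expr

__all__ = [
    "FateLabel", "Environment", "FATE_VARIABLES", "INPUT_VARIABLES",
    "build_germline_qn", "decode_fate", "decode_fate_batch",
    "is_pro_apoptotic", "environment", "compartment_environments",
    "apply_environment",
]

FATE_VARIABLES: Tuple[str, ...] = (
    "MITOSIS", "PACHYTENE", "DIPLOTENE", "DIAKINESIS", "MATURATION")
INPUT_VARIABLES: Tuple[str, ...] = ("DELTA", "RASinput", "MSP", "RASdown")

APOPTOSIS_OUTPUT = "CED3"


class FateLabel(str, Enum):
    """Decoded germ-cell fate; total over QN states (undefined if no bit set)."""

    MITOSIS = "mitosis"
    PACHYTENE = "pachytene"
    DIPLOTENE = "diplotene"
    DIAKINESIS = "diakinesis"
    MATURATION = "maturation"
    PRO_APOPTOTIC = "pro-apoptotic"
    UNDEFINED = "undefined"


#: decode priority when several fate bits are set: later stages win
_PRIORITY = ("MATURATION", "DIAKINESIS", "DIPLOTENE", "PACHYTENE", "MITOSIS")

_PRIORITY_LABEL = {
    "MATURATION": FateLabel.MATURATION,
    "DIAKINESIS": FateLabel.DIAKINESIS,
    "DIPLOTENE": FateLabel.DIPLOTENE,
    "PACHYTENE": FateLabel.PACHYTENE,
    "MITOSIS": FateLabel.MITOSIS,
}


class Environment(dict):
    """A gonad compartment: constant clamps on the network's input variables."""

    def __init__(self, clamps: Mapping[str, int], name: str = ""):
        super().__init__(clamps)
        self.name = name

    @property
    def clamps(self) -> dict:
        return dict(self)


def environment(delta: int = 0, ras: int = 0, msp: int = 0,
                rasdown: int = 0, name: str = "") -> Environment:
    """Build an environment clamping all four ligand inputs."""
    return Environment({"DELTA": delta, "RASinput": ras, "MSP": msp,
                        "RASdown": rasdown}, name=name)


def compartment_environments() -> List[Environment]:
    """The gonad's compartment chain, distal tip to proximal end."""
    return [
        environment(delta=1, name="distal_tip"),
        environment(name="meiotic_entry"),
        environment(ras=1, name="ras_zone"),
        environment(rasdown=1, name="bend"),
        environment(msp=1, name="proximal"),
    ]


def build_germline_qn(variant: str = "zone_ras",
                      apoptosis_chain: int = 2) -> QNSpec:
    """Construct the germline QN.

    Parameters
    ----------
    variant:
        ``"zone_ras"`` -- RAS follows the spatial RAS-activating ligand
        (``RASinput``), decaying when the ligand is absent.
        ``"timed_ras"`` -- RAS latches on after a transient ``RASinput``
        pulse and is cleared only by ``RASdown``.
    apoptosis_chain:
        Number of Boolean intermediates between MAPK and the ``CED3``
        apoptosis output (default 2: CEP1, EGL1).
    """
    if variant not in ("zone_ras", "timed_ras"):
        raise ValueError(f"unknown variant {variant!r}")
    if apoptosis_chain < 0:
        raise ValueError("apoptosis_chain must be >= 0")

    names = list(INPUT_VARIABLES) + ["NOTCH", "VAB1", "RAS", "MAPK"]
    targets: dict = {
        "NOTCH": AvgTarget(activators=("DELTA",)),
        "VAB1": AvgTarget(activators=("MSP",)),
        "MAPK": AvgTarget(activators=("RAS",)),
    }
    if variant == "zone_ras":
        targets["RAS"] = AvgTarget(activators=("RASinput", "VAB1"),
                                   inhibitors=("RASdown",))
    else:
        targets["RAS"] = ExprTarget(parse_expr(
            "min(1 - RASdown, max(RAS, RASinput, VAB1))"))

    # MAPK -> ... -> CED3 pro-apoptotic chain
    chain = ["MAPK"]
    if apoptosis_chain >= 1:
        chain.append("CEP1")
    for i in range(1, apoptosis_chain):
        chain.append("EGL1" if i == 1 else f"APO{i + 1}")
    for up, down in zip(chain, chain[1:]):
        names.append(down)
        targets[down] = AvgTarget(activators=(up,))
    names.append(APOPTOSIS_OUTPUT)
    targets[APOPTOSIS_OUTPUT] = AvgTarget(activators=(chain[-1],))

    # meiotic cell-cycle block: negative feedback gated by a license that
    # NOTCH clears; off on every trajectory out of the distal-tip stable state
    names += ["CCLICENSE", "CYCB", "APC"]
    targets["CCLICENSE"] = ExprTarget(parse_expr("min(CCLICENSE, 1 - NOTCH)"))
    targets["CYCB"] = ExprTarget(parse_expr("min(CCLICENSE, 1 - APC)"))
    targets["APC"] = ExprTarget(parse_expr("min(CCLICENSE, CYCB)"))

    # the five fate variables
    names += list(FATE_VARIABLES)
    targets["MITOSIS"] = AvgTarget(activators=("NOTCH",))
    targets["PACHYTENE"] = ExprTarget(parse_expr("1 - NOTCH"))
    # diplotene commitment latches (gene-expression changes downstream of
    # MAPK persist when the ligand is left behind); NOTCH resets it
    targets["DIPLOTENE"] = ExprTarget(parse_expr(
        "min(1 - NOTCH, max(DIPLOTENE, MAPK))"))
    targets["DIAKINESIS"] = ExprTarget(parse_expr(
        "min(1 - NOTCH, max(DIAKINESIS, min(DIPLOTENE, 1 - MAPK)))"))
    # maturation requires the sperm-specific branch (MSP -> VAB1) driving
    # MAPK in a diakinetic oocyte; gating on VAB1 rather than bare MAPK
    # excludes premature maturation when boundary back-diffusion transiently
    # re-activates MAPK in the growth-factor region
    targets["MATURATION"] = ExprTarget(parse_expr(
        "min(1 - NOTCH, max(MATURATION, min(DIAKINESIS, MAPK, VAB1)))"))

    return QNSpec(
        variables=tuple(Variable(n, 1) for n in names),
        targets=targets,
        inputs=frozenset(INPUT_VARIABLES),
        name=f"germline-{variant.replace('_', '-')}",
    )


def _fate_indices(spec: QNSpec) -> dict:
    try:
        return {n: spec.index(n) for n in _PRIORITY}
    except KeyError as exc:
        raise ValueError(
            f"state does not match a germline spec (missing {exc})") from None


def decode_fate(spec: QNSpec, state: Sequence[int]) -> FateLabel:
    """Priority-decode the five fate bits (later meiotic stages win)."""
    idx = _fate_indices(spec)
    for name in _PRIORITY:
        if state[idx[name]]:
            return _PRIORITY_LABEL[name]
    return FateLabel.UNDEFINED


def decode_fate_batch(spec: QNSpec, states: np.ndarray) -> np.ndarray:
    """Vectorised fate decoding; returns an object array of FateLabel."""
    idx = _fate_indices(spec)
    states = np.asarray(states)
    codes = np.full(states.shape[:-1], -1, dtype=np.int8)
    # ascending priority: later meiotic stages overwrite earlier ones
    for code, name in enumerate(reversed(_PRIORITY)):
        codes[states[..., idx[name]] > 0] = code
    labels = [FateLabel.UNDEFINED] + [_PRIORITY_LABEL[n]
                                      for n in reversed(_PRIORITY)]
    out = np.empty(codes.shape, dtype=object)
    for flat_i, c in np.ndenumerate(codes):
        out[flat_i] = labels[c + 1]
    return out


def is_pro_apoptotic(spec: QNSpec, state: Sequence[int]) -> bool:
    """True when the apoptosis-chain output (CED3) is active."""
    return bool(state[spec.index(APOPTOSIS_OUTPUT)])
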