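"""Read/write qualitative networks as versioned YAML documents (``.qn``).

Schema (version 1)::

    qn: 1
    name: my-network            # optional
    variables:
      - name: DELTA             # required, unique
        max: 1                  # granularity N_v >= 1 (default 1, Boolean)
        input: true             # optional; externally driven variable
        activators: [X, Y]      # default-target regulators (optional)
        inhibitors: [Z]
        target: "max(A, 1 - B)" # explicit expression, overrides act/inh

A variable with neither regulators nor an explicit target is an error unless
it is an input (inputs default to holding their value).  Files written by
:func:`write_qn` re-read to a structurally identical spec.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Union

import yaml

from .core import AvgTarget, ExprTarget, QNSpec, Variable
from .expr import parse_expr

SCHEMA_VERSION = 1

__all__ = ["read_qn", "write_qn", "SCHEMA_VERSION"]


def _spec_from_doc(doc: dict) -> QNSpec:
    if not isinstance(doc, dict) or doc.get("qn") != SCHEMA_VERSION:
        raise ValueError(f"not a qn schema version {SCHEMA_VERSION} document")
    variables = []
    targets = {}
    inputs = set()
    for entry in doc.get("variables", []):
        name = entry["name"]
        variables.append(Variable(name=name, nmax=int(entry.get("max", 1))))
        if entry.get("input", False):
            inputs.add(name)
        if "target" in entry:
            targets[name] = ExprTarget(parse_expr(str(entry["target"])))
        elif "activators" in entry or "inhibitors" in entry:
            targets[name] = AvgTarget(
                activators=tuple(entry.get("activators", ())),
                inhibitors=tuple(entry.get("inhibitors", ())),
            )
        elif name not in inputs:
            raise ValueError(f"variable {name} has no target and is not an input")
    return QNSpec(variables=tuple(variables), targets=targets,
                  inputs=frozenset(inputs), name=doc.get("name", ""))


def read_qn(source: Union[str, Path, io.TextIOBase]) -> QNSpec:
    """Load a QN definition from a path or open text stream."""
    if isinstance(source, (str, Path)):
        with open(source, "r") as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = yaml.safe_load(source)
    return _spec_from_doc(doc)


def _doc_from_spec(spec: QNSpec) -> dict:
    variables = []
    for v in spec.variables:
        entry: dict = {"name": v.name, "max": v.nmax}
        if v.name in spec.inputs:
            entry["input"] = True
        tgt = spec.targets[v.name]
        if isinstance(tgt, AvgTarget):
            if tgt.activators:
                entry["activators"] = list(tgt.activators)
            if tgt.inhibitors:
                entry["inhibitors"] = list(tgt.inhibitors)
        else:
            expr_text = str(tgt.expr)
            # inputs carrying the implicit identity target need no entry
            if not (v.name in spec.inputs and expr_text == v.name):
                entry["target"] = expr_text
        variables.append(entry)
    doc = {"qn": SCHEMA_VERSION, "variables": variables}
    if spec.name:
        doc["name"] = spec.name
    return doc


def write_qn(spec: QNSpec, target: Union[str, Path, io.TextIOBase]) -> None:
    """Serialise ``spec`` to the versioned YAML schema."""
    doc = _doc_from_spec(spec)
    text = yaml.safe_dump(doc, sort_keys=False, default_flow_style=None)
    if isinstance(target, (str, Path)):
        Path(target).write_text(text)
    else:
        target.write(text)
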