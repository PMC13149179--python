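"""Reading and writing models and cohorts.

Models are stored as versioned JSON (nodes with ordered states and class,
edge list, CPTs as row-major probability arrays) with an optional XMLBIF
export for interoperability. Cohorts are plain CSV: UTF-8, header row of
node names, empty cell = missing. Both round-trip losslessly.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd

from .network import (
    Cpt,
    DagStructure,
    DiscreteBayesianNetwork,
    MISSING,
    NetworkError,
    NodeSpec,
)

__all__ = [
    "read_cohort_csv",
    "write_cohort_csv",
    "read_model_json",
    "write_model_json",
    "export_xmlbif",
    "import_xmlbif",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = 1


def read_cohort_csv(
    path, known_columns=None, strict: bool = False
) -> pd.DataFrame:
    """Read a cohort CSV; empty cells become the missing token.

    With ``strict=True``, columns outside ``known_columns`` raise; otherwise
    they are kept with a warning attribute on the frame.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = df.fillna(MISSING)
    if known_columns is not None:
        unknown = [c for c in df.columns if c not in set(known_columns)]
        if unknown and strict:
            raise ValueError(f"unknown columns {unknown} in {path}")
        df.attrs["unknown_columns"] = unknown
    return df


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    out = cohort.replace(MISSING, "")
    out.to_csv(path, index=False)


def validate_cohort_states(cohort: pd.DataFrame, structure: DagStructure) -> None:
    """Raise (naming row and column) on any unseen state in known columns."""
    for col in cohort.columns:
        try:
            spec = structure.spec(col)
        except KeyError:
            continue
        valid = set(spec.states) | {MISSING}
        bad = ~cohort[col].isin(valid)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"unseen state {cohort[col].iloc[row]!r} in column {col!r}, "
                f"row {row}"
            )


def write_model_json(net: DiscreteBayesianNetwork, path) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "nodes": [
            {
                "name": n.name,
                "states": list(n.states),
                "class": n.node_class,
                "description": n.description,
            }
            for n in net.structure.nodes
        ],
        "edges": [list(e) for e in net.structure.edges],
        "cpts": {
            name: {
                "parents": list(cpt.parents),
                "table": [float(v) for v in cpt.flat()],
            }
            for name, cpt in net.cpts.items()
        },
    }
    Path(path).write_text(json.dumps(doc))


def read_model_json(path) -> DiscreteBayesianNetwork:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise NetworkError(
            f"unsupported schema_version {doc.get('schema_version')!r}"
        )
    nodes = tuple(
        NodeSpec(
            n["name"], tuple(n["states"]), n.get("class", "categorical"),
            n.get("description", ""),
        )
        for n in doc["nodes"]
    )
    structure = DagStructure(nodes, tuple((p, c) for p, c in doc["edges"]))
    states = {n.name: n.states for n in nodes}
    cpts = []
    for name, entry in doc["cpts"].items():
        parents = tuple(entry["parents"])
        cpts.append(
            Cpt(
                name,
                states[name],
                parents,
                {p: states[p] for p in parents},
                np.asarray(entry["table"], float),
            )
        )
    return DiscreteBayesianNetwork(structure, cpts)


def export_xmlbif(net: DiscreteBayesianNetwork, path) -> None:
    """Write the network in XMLBIF 0.3 (row-major CPT tables)."""
    root = ET.Element("BIF", VERSION="0.3")
    network = ET.SubElement(root, "NETWORK")
    ET.SubElement(network, "NAME").text = "periobn"
    for spec in net.structure.nodes:
        var = ET.SubElement(network, "VARIABLE", TYPE="nature")
        ET.SubElement(var, "NAME").text = spec.name
        for s in spec.states:
            ET.SubElement(var, "OUTCOME").text = s
    for name in net.node_names:
        cpt = net.cpts[name]
        definition = ET.SubElement(network, "DEFINITION")
        ET.SubElement(definition, "FOR").text = name
        for p in cpt.parents:
            ET.SubElement(definition, "GIVEN").text = p
        ET.SubElement(definition, "TABLE").text = " ".join(
            repr(float(v)) for v in cpt.flat()
        )
    ET.ElementTree(root).write(path, encoding="unicode")


def import_xmlbif(path) -> DiscreteBayesianNetwork:
    """Read an XMLBIF 0.3 file written by :func:`export_xmlbif`.

    State classes are not part of XMLBIF; nodes come back as categorical
    (binary when they have exactly two states).
    """
    tree = ET.parse(path)
    network = tree.getroot().find("NETWORK")
    nodes = []
    for var in network.findall("VARIABLE"):
        name = var.find("NAME").text
        outcomes = tuple(o.text for o in var.findall("OUTCOME"))
        nodes.append(
            NodeSpec(name, outcomes, "binary" if len(outcomes) == 2 else "categorical")
        )
    states = {n.name: n.states for n in nodes}
    edges = []
    cpts = []
    for definition in network.findall("DEFINITION"):
        name = definition.find("FOR").text
        parents = tuple(g.text for g in definition.findall("GIVEN"))
        for p in parents:
            edges.append((p, name))
        table = np.asarray(
            [float(v) for v in definition.find("TABLE").text.split()]
        )
        cpts.append(
            Cpt(name, states[name], parents, {p: states[p] for p in parents}, table)
        )
    structure = DagStructure(tuple(nodes), tuple(edges))
    return DiscreteBayesianNetwork(structure, cpts)
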