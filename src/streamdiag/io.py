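"""File formats: network JSON, XMLBIF interchange, catalog, run config.

The native network format is a small JSON dialect::

    {
      "nodes": [{"name": ..., "role": "stressor"|"metric",
                 "states": [{"label": ..., "lower": ..., "upper": ...}],
                 "degraded_state": ...}],
      "cpts":  [{"child": ..., "parents": [...],
                 "rows": [{"given": {parent: state, ...}, "p": [...]}]}],
      "meta":  {...}
    }

Interval bounds serialize ±infinity as the strings ``"inf"``/``"-inf"``
and categorical states omit the bounds, so ``load(save(net)) == net``
bit-exactly.  XMLBIF export is provided for interchange with standard BBN
software; roles, interval bounds and degraded-state markers ride along in
``PROPERTY`` elements so the secondary format also round-trips.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path
from xml.etree import ElementTree as ET

import numpy as np
import yaml

from .cpt import ExpertOverride, NetworkSkeleton
from .network import (
    CPT,
    DiagnosticNetwork,
    Node,
    NodeState,
    validate_network,
)

__all__ = [
    "NetworkFormatError",
    "load_network",
    "save_network",
    "networks_equal",
    "export_xmlbif",
    "import_xmlbif",
    "save_skeleton",
    "load_skeleton",
    "load_catalog",
    "load_evidence",
    "load_overrides",
    "RunConfig",
]


class NetworkFormatError(ValueError):
    """A network file violates the schema or its probability invariants."""


def _bound_to_json(value: float | None):
    if value is None:
        return None
    if value == math.inf:
        return "inf"
    if value == -math.inf:
        return "-inf"
    return float(value)


def _bound_from_json(value):
    if value is None:
        return None
    if value == "inf":
        return math.inf
    if value == "-inf":
        return -math.inf
    if isinstance(value, (int, float)):
        return float(value)
    raise NetworkFormatError(f"invalid interval bound {value!r}")


def network_to_dict(net: DiagnosticNetwork) -> dict:
    nodes = []
    for n in net.nodes:
        states = []
        for s in n.states:
            entry = {"label": s.label}
            if s.is_interval:
                entry["lower"] = _bound_to_json(s.lower)
                entry["upper"] = _bound_to_json(s.upper)
            states.append(entry)
        nodes.append(
            {
                "name": n.name,
                "role": n.role,
                "states": states,
                "degraded_state": n.degraded_state,
            }
        )
    cpts = []
    for name in net.node_names:
        cpt = net.cpts[name]
        rows = [
            {
                "given": dict(zip(cpt.parents, combo)),
                "p": [float(x) for x in cpt.table[combo]],
            }
            for combo in sorted(cpt.table)
        ]
        cpts.append({"child": cpt.child, "parents": list(cpt.parents), "rows": rows})
    meta = _meta_to_json(net.meta)
    return {"nodes": nodes, "cpts": cpts, "meta": meta}


def _meta_to_json(meta: dict) -> dict:
    out = dict(meta)
    if "zero_support_rows" in out:
        out["zero_support_rows"] = [
            [child, list(combo)] for child, combo in out["zero_support_rows"]
        ]
    return out


def _meta_from_json(meta: dict) -> dict:
    out = dict(meta)
    if "zero_support_rows" in out:
        out["zero_support_rows"] = [
            (child, tuple(combo)) for child, combo in out["zero_support_rows"]
        ]
    return out


def network_from_dict(payload: dict) -> DiagnosticNetwork:
    for key in ("nodes", "cpts"):
        if key not in payload:
            raise NetworkFormatError(f"network file lacks the {key!r} section")
    nodes = []
    for i, entry in enumerate(payload["nodes"]):
        try:
            states = tuple(
                NodeState(
                    s["label"],
                    _bound_from_json(s.get("lower")),
                    _bound_from_json(s.get("upper")),
                )
                for s in entry["states"]
            )
            nodes.append(
                Node(entry["name"], entry["role"], states, entry.get("degraded_state"))
            )
        except (KeyError, TypeError) as exc:
            raise NetworkFormatError(f"nodes[{i}]: malformed entry ({exc})") from exc
    cpts = {}
    for i, entry in enumerate(payload["cpts"]):
        try:
            child = entry["child"]
            parents = tuple(entry["parents"])
            table = {}
            for j, row in enumerate(entry["rows"]):
                given = row["given"]
                if set(given) != set(parents):
                    raise NetworkFormatError(
                        f"cpts[{i}] ({child!r}), rows[{j}]: given-keys "
                        f"{sorted(given)} do not match parents {sorted(parents)}"
                    )
                combo = tuple(given[p] for p in parents)
                table[combo] = np.asarray(row["p"], dtype=float)
            cpts[child] = CPT(child, parents, table)
        except (KeyError, TypeError) as exc:
            raise NetworkFormatError(f"cpts[{i}]: malformed entry ({exc})") from exc
    net = DiagnosticNetwork(nodes, cpts, _meta_from_json(payload.get("meta", {})))
    problems = validate_network(net)
    if problems:
        raise NetworkFormatError("invalid network: " + "; ".join(problems))
    return net


def save_network(net: DiagnosticNetwork, path: str | Path) -> None:
    payload = network_to_dict(net)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def load_network(path: str | Path) -> DiagnosticNetwork:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise NetworkFormatError(f"{path}: line {exc.lineno}: {exc.msg}") from exc
    return network_from_dict(payload)


def networks_equal(a: DiagnosticNetwork, b: DiagnosticNetwork, tol: float = 0.0) -> bool:
    """Semantic equality: same nodes, states, structure, and CPT entries."""
    if [n.name for n in a.nodes] != [n.name for n in b.nodes]:
        return False
    for na, nb in zip(a.nodes, b.nodes):
        if (na.name, na.role, na.states, na.degraded_state) != (
            nb.name,
            nb.role,
            nb.states,
            nb.degraded_state,
        ):
            return False
    for name in a.node_names:
        ca, cb = a.cpts[name], b.cpts.get(name)
        if cb is None or ca.parents != cb.parents or set(ca.table) != set(cb.table):
            return False
        for combo, vec in ca.table.items():
            if not np.allclose(vec, cb.table[combo], rtol=0, atol=tol):
                return False
    return True


# ---------------------------------------------------------------------------
# XMLBIF interchange


def export_xmlbif(net: DiagnosticNetwork, path: str | Path, name: str = "streamdiag") -> None:
    """Write the network in XMLBIF 0.3 for standard BBN software.

    Probability tables list the child outcome fastest, parent combinations
    in row-major order of the GIVEN list.  Role, degraded state and
    interval bounds are preserved in PROPERTY elements.
    """
    bif = ET.Element("BIF", VERSION="0.3")
    network = ET.SubElement(bif, "NETWORK")
    ET.SubElement(network, "NAME").text = name
    for node in net.nodes:
        var = ET.SubElement(network, "VARIABLE", TYPE="nature")
        ET.SubElement(var, "NAME").text = node.name
        for s in node.states:
            ET.SubElement(var, "OUTCOME").text = s.label
        ET.SubElement(var, "PROPERTY").text = f"role = {node.role}"
        if node.degraded_state is not None:
            ET.SubElement(var, "PROPERTY").text = f"degraded_state = {node.degraded_state}"
        for s in node.states:
            if s.is_interval:
                ET.SubElement(var, "PROPERTY").text = (
                    f"interval {s.label} = "
                    f"{_bound_to_json(s.lower)} {_bound_to_json(s.upper)}"
                )
    for child in net.node_names:
        cpt = net.cpts[child]
        definition = ET.SubElement(network, "DEFINITION")
        ET.SubElement(definition, "FOR").text = child
        for p in cpt.parents:
            ET.SubElement(definition, "GIVEN").text = p
        combos = itertools.product(*(net.node(p).state_labels for p in cpt.parents))
        flat = [f"{x:.17g}" for combo in combos for x in cpt.table[combo]]
        ET.SubElement(definition, "TABLE").text = " ".join(flat)
    tree = ET.ElementTree(bif)
    ET.indent(tree)
    tree.write(path, encoding="unicode", xml_declaration=True)


def import_xmlbif(path: str | Path) -> DiagnosticNetwork:
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise NetworkFormatError(f"{path}: {exc}") from exc
    network = root.find("NETWORK")
    if network is None:
        raise NetworkFormatError(f"{path}: no NETWORK element")

    nodes: list[Node] = []
    for var in network.findall("VARIABLE"):
        name = var.findtext("NAME")
        labels = [o.text for o in var.findall("OUTCOME")]
        role, degraded = "metric", None
        intervals: dict[str, tuple] = {}
        for prop in var.findall("PROPERTY"):
            text = (prop.text or "").strip()
            if text.startswith("role = "):
                role = text.removeprefix("role = ")
            elif text.startswith("degraded_state = "):
                degraded = text.removeprefix("degraded_state = ")
            elif text.startswith("interval "):
                body = text.removeprefix("interval ")
                label, bounds = body.rsplit(" = ", 1)
                lo_s, hi_s = bounds.split()
                intervals[label] = (
                    _bound_from_json(_maybe_number(lo_s)),
                    _bound_from_json(_maybe_number(hi_s)),
                )
        states = tuple(
            NodeState(lab, *intervals[lab]) if lab in intervals else NodeState(lab)
            for lab in labels
        )
        nodes.append(Node(name, role, states, degraded))
    by_name = {n.name: n for n in nodes}

    cpts: dict[str, CPT] = {}
    for definition in network.findall("DEFINITION"):
        child = definition.findtext("FOR")
        parents = tuple(g.text for g in definition.findall("GIVEN"))
        values = [float(x) for x in (definition.findtext("TABLE") or "").split()]
        if child not in by_name:
            raise NetworkFormatError(f"{path}: DEFINITION for unknown variable {child!r}")
        k = by_name[child].n_states
        combos = list(itertools.product(*(by_name[p].state_labels for p in parents)))
        if len(values) != k * len(combos):
            raise NetworkFormatError(
                f"{path}: TABLE of {child!r} has {len(values)} entries, "
                f"expected {k * len(combos)}"
            )
        table = {
            combo: np.asarray(values[i * k : (i + 1) * k])
            for i, combo in enumerate(combos)
        }
        cpts[child] = CPT(child, parents, table)

    net = DiagnosticNetwork(nodes, cpts)
    problems = validate_network(net)
    if problems:
        raise NetworkFormatError(f"{path}: invalid network: " + "; ".join(problems))
    return net


def _maybe_number(s: str):
    try:
        return float(s)
    except ValueError:
        return s


# ---------------------------------------------------------------------------
# Skeleton files (structure before parameter learning)


def save_skeleton(skeleton: NetworkSkeleton, path: str | Path) -> None:
    nodes = []
    for n in skeleton.nodes:
        states = []
        for s in n.states:
            entry = {"label": s.label}
            if s.is_interval:
                entry["lower"] = _bound_to_json(s.lower)
                entry["upper"] = _bound_to_json(s.upper)
            states.append(entry)
        nodes.append(
            {
                "name": n.name,
                "role": n.role,
                "states": states,
                "degraded_state": n.degraded_state,
            }
        )
    payload = {"nodes": nodes, "edges": [list(e) for e in skeleton.edges]}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def load_skeleton(path: str | Path) -> NetworkSkeleton:
    payload = json.loads(Path(path).read_text())
    nodes = []
    for i, entry in enumerate(payload.get("nodes", [])):
        try:
            states = tuple(
                NodeState(
                    s["label"],
                    _bound_from_json(s.get("lower")),
                    _bound_from_json(s.get("upper")),
                )
                for s in entry["states"]
            )
            nodes.append(
                Node(entry["name"], entry["role"], states, entry.get("degraded_state"))
            )
        except (KeyError, TypeError) as exc:
            raise NetworkFormatError(f"{path}: nodes[{i}]: {exc}") from exc
    skeleton = NetworkSkeleton(nodes, [tuple(e) for e in payload.get("edges", [])])
    problems = skeleton.validate()
    if problems:
        raise NetworkFormatError(f"{path}: " + "; ".join(problems))
    return skeleton


# ---------------------------------------------------------------------------
# Catalog and small input files


def load_catalog() -> dict:
    """The packaged roster of 18 biological metrics and 13 degradation causes.

    Transcribed from the published overview tables, including each metric's
    potential indication, each stressor's native-scale summary per
    stream-type group, and qualitative edge notes from the published
    results.  Group placements that are typographically ambiguous in the
    source are marked ``unconfirmed``.
    """
    with resources.files("streamdiag").joinpath("catalog.json").open() as fh:
        return json.load(fh)


def load_evidence(path: str | Path) -> dict[str, str]:
    payload = json.loads(Path(path).read_text())
    if not isinstance(payload, dict) or not all(
        isinstance(k, str) and isinstance(v, str) for k, v in payload.items()
    ):
        raise NetworkFormatError(f"{path}: evidence must map node names to state labels")
    return payload


def load_overrides(path: str | Path) -> list[ExpertOverride]:
    payload = json.loads(Path(path).read_text())
    out = []
    for i, entry in enumerate(payload):
        try:
            out.append(
                ExpertOverride(
                    entry["child"],
                    dict(entry["given"]),
                    [float(x) for x in entry["p"]],
                    entry.get("note", ""),
                )
            )
        except (KeyError, TypeError) as exc:
            raise NetworkFormatError(f"{path}: overrides[{i}]: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Tunables of a full pipeline run, with their standard defaults.

    Defaults follow the published procedure where one is stated: three
    cross-validation folds, a 0.8 collinearity threshold, at most three
    node states, and the 10-percentage-point no-change rule.
    """

    seed: int = 0
    k_folds: int = 3
    collinearity_threshold: float = 0.8
    max_states: int = 3
    alpha: float = 0.05
    alpha_prior: float = 1.0
    no_change_pp: float = 10.0
    n_trees: int = 300
    n_perm: int = 9999
    min_sharpness_frac: float = 0.25
    voi_variant: str = "state_averaged"
    cv_evidence_mode: str = "all"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))
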