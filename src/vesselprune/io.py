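"""Reading and writing vascular networks.

Supported dialects:

* ``csv`` — a pair of files: ``<stem>.nodes.csv`` with columns
  ``node_id, x_um, y_um, role`` and ``<stem>.vessels.csv`` with columns
  ``vessel_id, node_a, node_b, diameter_um, length_um``.
* ``json`` — one file holding both tables under ``nodes`` / ``vessels``.
* ``graphml`` — networkx GraphML with the same attribute names.
* ``vtk`` — legacy ASCII polydata export (write-only) with per-cell
  ``diameter_um``, ``length_um`` and, optionally, ``flow_m3s`` and
  ``perfused`` scalar arrays for visualisation.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Mapping, Optional

import networkx as nx

from .network import NetworkValidationError, VascularNetwork

__all__ = ["read_network", "write_network", "write_vtk"]

NODE_COLUMNS = ["node_id", "x_um", "y_um", "role"]
VESSEL_COLUMNS = ["vessel_id", "node_a", "node_b", "diameter_um", "length_um"]


def _csv_paths(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("") if path.suffix == ".csv" else path
    s = str(stem)
    if s.endswith(".nodes") or s.endswith(".vessels"):
        s = s.rsplit(".", 1)[0]
    return Path(s + ".nodes.csv"), Path(s + ".vessels.csv")


def read_network(path: str | Path, format: Optional[str] = None) -> VascularNetwork:
    """Read a network, inferring the dialect from the suffix if not given."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "csv":
        return _read_csv(path)
    if fmt == "json":
        return _read_json(path)
    if fmt == "graphml":
        return _read_graphml(path)
    raise ValueError(f"unsupported input format {fmt!r}")


def write_network(network: VascularNetwork, path: str | Path,
                  format: Optional[str] = None,
                  flow: Optional[Mapping[int, float]] = None,
                  perfused: Optional[Mapping[int, bool]] = None) -> None:
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "csv":
        _write_csv(network, path)
    elif fmt == "json":
        _write_json(network, path)
    elif fmt == "graphml":
        _write_graphml(network, path)
    elif fmt == "vtk":
        write_vtk(network, path, flow=flow, perfused=perfused)
    else:
        raise ValueError(f"unsupported output format {fmt!r}")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("csv", "json", "graphml", "vtk"):
        return suffix
    raise ValueError(f"cannot infer network format from {path.name!r}")


# -- CSV ----------------------------------------------------------------


def _read_csv(path: Path) -> VascularNetwork:
    nodes_path, vessels_path = _csv_paths(path)
    net = VascularNetwork()
    with open(nodes_path, newline="") as fh:
        reader = csv.DictReader(fh)
        _require_columns(reader.fieldnames, NODE_COLUMNS, nodes_path)
        for i, row in enumerate(reader, start=2):
            net.add_node(int(row["node_id"]), float(row["x_um"]),
                         float(row["y_um"]), row["role"] or "interior")
    with open(vessels_path, newline="") as fh:
        reader = csv.DictReader(fh)
        _require_columns(reader.fieldnames, VESSEL_COLUMNS, vessels_path)
        for i, row in enumerate(reader, start=2):
            try:
                net.add_vessel(int(row["vessel_id"]), int(row["node_a"]),
                               int(row["node_b"]), float(row["diameter_um"]),
                               float(row["length_um"]))
            except NetworkValidationError as exc:
                raise NetworkValidationError(
                    f"{vessels_path.name} row {i}: {exc}") from exc
    net.validate()
    return net


def _require_columns(fieldnames, required, path) -> None:
    missing = set(required) - set(fieldnames or [])
    if missing:
        raise NetworkValidationError(
            f"{Path(path).name}: missing required columns {sorted(missing)}")


def _write_csv(network: VascularNetwork, path: Path) -> None:
    nodes_path, vessels_path = _csv_paths(path)
    with open(nodes_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(NODE_COLUMNS)
        for node in sorted(network.nodes.values(), key=lambda n: n.id):
            writer.writerow([node.id, repr(node.x), repr(node.y), node.role])
    with open(vessels_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(VESSEL_COLUMNS)
        for v in sorted(network.vessels.values(), key=lambda v: v.id):
            writer.writerow([v.id, v.node_a, v.node_b,
                             repr(v.diameter), repr(v.length)])


# -- JSON ---------------------------------------------------------------


def _read_json(path: Path) -> VascularNetwork:
    with open(path) as fh:
        payload = json.load(fh)
    net = VascularNetwork()
    for row in payload["nodes"]:
        net.add_node(int(row["node_id"]), float(row["x_um"]),
                     float(row["y_um"]), row.get("role", "interior"))
    for row in payload["vessels"]:
        net.add_vessel(int(row["vessel_id"]), int(row["node_a"]),
                       int(row["node_b"]), float(row["diameter_um"]),
                       float(row["length_um"]))
    net.validate()
    return net


def _write_json(network: VascularNetwork, path: Path) -> None:
    payload = {
        "nodes": [
            {"node_id": n.id, "x_um": n.x, "y_um": n.y, "role": n.role}
            for n in sorted(network.nodes.values(), key=lambda n: n.id)
        ],
        "vessels": [
            {"vessel_id": v.id, "node_a": v.node_a, "node_b": v.node_b,
             "diameter_um": v.diameter, "length_um": v.length}
            for v in sorted(network.vessels.values(), key=lambda v: v.id)
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


# -- GraphML ------------------------------------------------------------


def _read_graphml(path: Path) -> VascularNetwork:
    g = nx.read_graphml(path)
    net = VascularNetwork()
    for nid, data in g.nodes(data=True):
        net.add_node(int(nid), float(data["x_um"]), float(data["y_um"]),
                     data.get("role", "interior"))
    for a, b, data in g.edges(data=True):
        net.add_vessel(int(data["vessel_id"]), int(a), int(b),
                       float(data["diameter_um"]), float(data["length_um"]))
    net.validate()
    return net


def _write_graphml(network: VascularNetwork, path: Path) -> None:
    g = nx.Graph()
    for n in network.nodes.values():
        g.add_node(n.id, x_um=n.x, y_um=n.y, role=n.role)
    for v in network.vessels.values():
        g.add_edge(v.node_a, v.node_b, vessel_id=v.id,
                   diameter_um=v.diameter, length_um=v.length)
    nx.write_graphml(g, path)


# -- VTK legacy polydata ------------------------------------------------


def write_vtk(network: VascularNetwork, path: str | Path,
              flow: Optional[Mapping[int, float]] = None,
              perfused: Optional[Mapping[int, bool]] = None) -> None:
    """Write the network as legacy ASCII VTK polydata.

    Each vessel becomes one two-point line cell; diameter and length
    (and optionally signed flow and a perfused flag) are attached as
    per-cell scalar arrays.
    """
    node_ids = sorted(network.nodes)
    index = {nid: i for i, nid in enumerate(node_ids)}
    vessels = sorted(network.vessels.values(), key=lambda v: v.id)
    lines = [
        "# vtk DataFile Version 3.0",
        "vascular network",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(node_ids)} double",
    ]
    for nid in node_ids:
        n = network.nodes[nid]
        lines.append(f"{n.x} {n.y} 0.0")
    lines.append(f"LINES {len(vessels)} {3 * len(vessels)}")
    for v in vessels:
        lines.append(f"2 {index[v.node_a]} {index[v.node_b]}")
    lines.append(f"CELL_DATA {len(vessels)}")

    def scalar_block(name: str, values, kind: str = "double"):
        lines.append(f"SCALARS {name} {kind} 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(str(v) for v in values)

    scalar_block("vessel_id", [v.id for v in vessels], "int")
    scalar_block("diameter_um", [v.diameter for v in vessels])
    scalar_block("length_um", [v.length for v in vessels])
    if flow is not None:
        scalar_block("flow_m3s", [flow.get(v.id, 0.0) for v in vessels])
    if perfused is not None:
        scalar_block("perfused", [int(bool(perfused.get(v.id, False)))
                                  for v in vessels], "int")
    Path(path).write_text("\n".join(lines) + "\n")
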