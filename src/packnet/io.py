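"""Readers and writers: PDB, extended XYZ, edge lists, GraphML, TSV
reports, and the plain-text run manifest.

All outputs are deterministic: edges and nodes are written in sorted
order and floats are formatted at six significant digits.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from Bio.PDB import PDBParser

from .graph_stats import ContactGraph, node_table
from .spatial_network import CoordinateSet

__all__ = [
    "read_pdb",
    "read_xyz",
    "write_xyz",
    "read_edgelist",
    "write_edgelist",
    "read_graphml",
    "write_graphml",
    "write_node_table",
    "write_manifest",
    "read_manifest",
]

FLOAT_FMT = "%.6g"     # reports
COORD_FMT = "%.12g"    # coordinate data: round-trips to 1e-9


def read_pdb(path) -> "Bio.PDB.Structure.Structure":  # noqa: F821
    """Parse a PDB file (first model is what downstream consumers use).

    Malformed headers are tolerated; missing coordinates are fatal.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(Path(path).stem, str(path))
    if not any(True for _ in structure.get_atoms()):
        raise ValueError(f"{path}: no atomic coordinates")
    return structure


def _parse_box_comment(comment: str):
    # extended-XYZ style box in the comment line: box="Lx Ly Lz"
    if "box=" not in comment:
        return None
    frag = comment.split("box=", 1)[1].strip()
    if frag.startswith('"'):
        frag = frag[1:].split('"', 1)[0]
    vals = [float(v) for v in frag.split()[:3]]
    if len(vals) != 3:
        raise ValueError(f"malformed box specification: {comment!r}")
    return tuple(vals)


def read_xyz(path) -> CoordinateSet:
    """Extended XYZ: count line, comment line (optional box="Lx Ly Lz"),
    then one `label x y z [chain seq]` row per point."""
    lines = Path(path).read_text().splitlines()
    if len(lines) < 2:
        raise ValueError(f"{path}: not an XYZ file")
    n = int(lines[0].split()[0])
    comment = lines[1]
    rows = [ln.split() for ln in lines[2:2 + n] if ln.strip()]
    if len(rows) != n:
        raise ValueError(f"{path}: count line says {n}, found {len(rows)} rows")
    labels, pos, chains, seqs = [], [], [], []
    for row in rows:
        labels.append(row[0])
        pos.append([float(v) for v in row[1:4]])
        if len(row) >= 6:
            chains.append(row[4])
            seqs.append(int(row[5]))
    has_chains = len(chains) == n
    return CoordinateSet(
        positions=np.asarray(pos),
        labels=tuple(labels),
        chain_ids=tuple(chains) if has_chains else None,
        sequence_index=tuple(seqs) if has_chains else None,
        box=_parse_box_comment(comment),
    )


def write_xyz(coords: CoordinateSet, path, comment: str = "") -> None:
    parts = [comment] if comment else []
    if coords.box is not None:
        parts.append('box="%s %s %s"' % tuple(COORD_FMT % b for b in coords.box))
    lines = [str(coords.n_points), " ".join(parts)]
    labels = coords.labels or tuple(f"X{i}" for i in range(coords.n_points))
    for i in range(coords.n_points):
        row = [labels[i]] + [COORD_FMT % v for v in coords.positions[i]]
        if coords.chain_ids is not None and coords.sequence_index is not None:
            row += [coords.chain_ids[i], str(coords.sequence_index[i])]
        lines.append(" ".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def write_edgelist(graph: ContactGraph, path) -> None:
    """Two integer columns, sorted; a header comment preserves the node
    count so isolated nodes survive the round trip."""
    lines = [f"# n_nodes {graph.n_nodes}"]
    for i, j in sorted(graph.edges):
        lines.append(f"{i} {j}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_edgelist(path) -> ContactGraph:
    n_nodes = None
    edges = []
    for ln in Path(path).read_text().splitlines():
        ln = ln.strip()
        if not ln:
            continue
        if ln.startswith("#"):
            toks = ln[1:].split()
            if len(toks) == 2 and toks[0] == "n_nodes":
                n_nodes = int(toks[1])
            continue
        i, j = ln.split()[:2]
        edges.append((int(i), int(j)))
    if n_nodes is None:
        n_nodes = max((max(e) for e in edges), default=-1) + 1
    return ContactGraph.from_edges(n_nodes, edges)


def write_graphml(graph: ContactGraph, path) -> None:
    nx.write_graphml(graph.to_networkx(), str(path))


def read_graphml(path) -> ContactGraph:
    return ContactGraph.from_networkx(nx.read_graphml(str(path),
                                                      node_type=int))


def write_node_table(graph: ContactGraph, path) -> None:
    """Per-node descriptor TSV: node_label, k, knn, C, L."""
    df = node_table(graph)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_manifest(params: dict, path) -> None:
    """Plain-text key = value provenance record, with a content hash so
    reports can reference the exact configuration."""
    items = sorted((str(k), str(v)) for k, v in params.items())
    body = "\n".join(f"{k} = {v}" for k, v in items)
    digest = hashlib.sha256(body.encode()).hexdigest()[:12]
    Path(path).write_text(body + f"\nconfig_hash = {digest}\n")


def read_manifest(path) -> dict:
    out = {}
    for ln in Path(path).read_text().splitlines():
        if "=" in ln:
            k, v = ln.split("=", 1)
            out[k.strip()] = v.strip()
    return out
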