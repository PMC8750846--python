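"""Readers and writers for edge lists, node mappings and community tables.

Edge-list dialect: one edge per line, fields separated by any run of
whitespace, ``#``-prefixed lines and blank lines ignored.  Physical edge
lists have two columns (node, node); conceptual edge lists have three
(node, node, weight).  Mapping files have two columns (physical node,
conceptual node) with an optional third similarity column.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Iterable, TYPE_CHECKING

import networkx as nx

from .model import ParseError, ValidationError, validate_conceptual, validate_physical

if TYPE_CHECKING:  # pragma: no cover
    from .communities import Community

__all__ = [
    "read_edge_list",
    "write_edge_list",
    "read_mapping",
    "write_mapping",
    "write_communities",
    "read_communities",
    "write_ground_truth",
    "read_ground_truth",
    "write_alignment_graph",
]


def _data_lines(
    path: str | Path, isolated: list[str] | None = None
) -> Iterable[tuple[int, list[str]]]:
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                # "#node <id>" records an isolated node; edge lists cannot
                # carry it otherwise (other tools see an ordinary comment)
                if isolated is not None and line.startswith("#node "):
                    isolated.extend(line.split()[1:])
                continue
            yield lineno, line.split()


def read_edge_list(path: str | Path, weighted: bool = False) -> nx.Graph:
    """Read an undirected edge list; ``weighted`` selects the 3-column dialect.

    Duplicate edges collapse; a duplicate weighted edge with a conflicting
    weight is an error rather than a silent overwrite.
    """
    graph = nx.Graph()
    isolated: list[str] = []
    n_fields = 3 if weighted else 2
    for lineno, fields in _data_lines(path, isolated=isolated):
        if len(fields) != n_fields:
            raise ParseError(
                f"{path}:{lineno}: expected {n_fields} fields, got {len(fields)}"
            )
        u, v = fields[0], fields[1]
        if u == v:
            raise ValidationError(f"{path}:{lineno}: self-loop on node {u!r}")
        if weighted:
            try:
                w = float(fields[2])
            except ValueError as exc:
                raise ValidationError(
                    f"{path}:{lineno}: non-numeric weight {fields[2]!r}"
                ) from exc
            if not w > 0.0:
                raise ValidationError(f"{path}:{lineno}: non-positive weight {w}")
            if graph.has_edge(u, v) and graph[u][v]["weight"] != w:
                raise ValidationError(
                    f"{path}:{lineno}: duplicate edge ({u}, {v}) with conflicting "
                    f"weights {graph[u][v]['weight']} and {w}"
                )
            graph.add_edge(u, v, weight=w)
        else:
            graph.add_edge(u, v)
    graph.add_nodes_from(isolated)
    return validate_conceptual(graph) if weighted else validate_physical(graph)


def write_edge_list(graph: nx.Graph, path: str | Path, weighted: bool = False) -> None:
    """Write an edge list in the dialect :func:`read_edge_list` accepts;
    edges sorted for byte-identical round trips."""
    with open(path, "w", encoding="utf-8") as handle:
        for node in sorted(nx.isolates(graph)):
            handle.write(f"#node {node}\n")
        for u, v, data in sorted(graph.edges(data=True), key=lambda e: (min(e[:2]), max(e[:2]))):
            a, b = sorted((u, v))
            if weighted:
                handle.write(f"{a}\t{b}\t{data['weight']!r}\n")
            else:
                handle.write(f"{a}\t{b}\n")


def read_mapping(path: str | Path) -> tuple[tuple[tuple[str, str], ...], dict[tuple[str, str], float]]:
    """Read a node-correspondence file.

    Returns (pairs, similarity).  Duplicate pairs are deduplicated with a
    warning; an empty mapping is an error because every alignment node stems
    from a correspondence pair.
    """
    pairs: dict[tuple[str, str], None] = {}
    similarity: dict[tuple[str, str], float] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) not in (2, 3):
            raise ParseError(f"{path}:{lineno}: expected 2 or 3 fields, got {len(fields)}")
        pair = (fields[0], fields[1])
        if pair in pairs:
            warnings.warn(f"{path}:{lineno}: duplicate mapping pair {pair}", stacklevel=2)
            continue
        pairs[pair] = None
        if len(fields) == 3:
            try:
                similarity[pair] = float(fields[2])
            except ValueError as exc:
                raise ValidationError(
                    f"{path}:{lineno}: non-numeric similarity {fields[2]!r}"
                ) from exc
    if not pairs:
        raise ValidationError(f"{path}: mapping file is empty; mapping must be non-empty")
    return tuple(pairs), similarity


def write_mapping(pairs: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for v, w in pairs:
            handle.write(f"{v}\t{w}\n")


_TSV_HEADER = "community_id\tphysical_node\tconceptual_node\tmodularity\n"


def write_communities(communities: "list[Community]", path: str | Path, format: str = "tsv") -> None:
    """Write detected communities as TSV (one row per alignment-node
    membership) or JSON (one object per community).  Both round-trip."""
    if format == "tsv":
        with open(path, "w", encoding="utf-8") as handle:
            handle.write(_TSV_HEADER)
            for cid, com in enumerate(communities):
                for v, w in sorted(com.alignment_nodes):
                    handle.write(f"{cid}\t{v}\t{w}\t{com.modularity_contribution!r}\n")
    elif format == "json":
        payload = [
            {
                "id": cid,
                "alignment_nodes": sorted([list(p) for p in com.alignment_nodes]),
                "physical_nodes": sorted(com.physical_nodes),
                "conceptual_nodes": sorted(com.conceptual_nodes),
                "modularity": com.modularity_contribution,
                "density": com.density,
                "connected_in_physical": com.connected_in_physical,
            }
            for cid, com in enumerate(communities)
        ]
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(payload, handle, indent=1)
            handle.write("\n")
    else:
        raise ValueError(f"unknown community output format {format!r}")


def read_communities(path: str | Path, format: str = "tsv") -> "list[Community]":
    """Read communities written by :func:`write_communities`."""
    from .communities import Community

    if format == "tsv":
        groups: dict[str, set[tuple[str, str]]] = {}
        scores: dict[str, float] = {}
        with open(path, encoding="utf-8") as handle:
            header = handle.readline()
            if header != _TSV_HEADER:
                raise ParseError(f"{path}: unexpected header {header!r}")
            for lineno, raw in enumerate(handle, start=2):
                if not raw.strip():
                    continue
                fields = raw.rstrip("\n").split("\t")
                if len(fields) != 4:
                    raise ParseError(f"{path}:{lineno}: expected 4 fields")
                cid, v, w, q = fields
                groups.setdefault(cid, set()).add((v, w))
                scores[cid] = float(q)
        return [
            Community.from_alignment_nodes(groups[cid], modularity_contribution=scores[cid])
            for cid in sorted(groups, key=int)
        ]
    if format == "json":
        with open(path, encoding="utf-8") as handle:
            payload = json.load(handle)
        return [
            Community.from_alignment_nodes(
                {tuple(p) for p in entry["alignment_nodes"]},
                modularity_contribution=entry.get("modularity", 0.0),
                density=entry.get("density"),
                connected_in_physical=bool(entry.get("connected_in_physical", False)),
            )
            for entry in payload
        ]
    raise ValueError(f"unknown community input format {format!r}")


def write_ground_truth(communities: Iterable[frozenset[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        json.dump([sorted(c) for c in communities], handle)
        handle.write("\n")


def read_ground_truth(path: str | Path) -> list[frozenset[str]]:
    with open(path, encoding="utf-8") as handle:
        return [frozenset(c) for c in json.load(handle)]


def write_alignment_graph(graph: nx.Graph, path: str | Path) -> None:
    """Export an alignment graph as a weighted edge list with an edge-type
    column (``MATCH`` or ``GAP``); alignment nodes serialise as ``v|w``."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("node_a\tnode_b\tweight\tkind\n")
        rows = sorted(graph.edges(data=True), key=lambda e: tuple(sorted(e[:2])))
        for a, b, data in rows:
            a, b = sorted((a, b))
            handle.write(f"{a[0]}|{a[1]}\t{b[0]}|{b[1]}\t{data['weight']!r}\t{data['kind']}\n")
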