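"""Data model for dual networks.

A dual network pairs two undirected simple graphs over corresponding node
sets: a *physical* network whose edges are unweighted direct interactions
(e.g. binary protein binding, declared friendships) and a *conceptual*
network whose edges carry positive weights expressing association strength
(e.g. functional association scores, normalised geographic proximity).
A node correspondence relates members of the two layers; in the common case
where the layers share identifiers the correspondence is the identity.

Graphs are held as :class:`networkx.Graph` objects.  Node identifiers are
opaque strings throughout — no integer coercion — so biological accessions
and user ids work alike.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "DualNetworkError",
    "ParseError",
    "ValidationError",
    "DualNetwork",
    "validate_physical",
    "validate_conceptual",
    "identity_mapping",
    "assemble_dual_network",
]


class DualNetworkError(Exception):
    """Base class for errors raised by this package."""


class ParseError(DualNetworkError):
    """A malformed input file (the message names the offending line)."""


class ValidationError(DualNetworkError):
    """An input violates a structural invariant of the model."""


def validate_physical(graph: nx.Graph) -> nx.Graph:
    """Check physical-network invariants: undirected, simple, no self-loops."""
    if graph.is_directed() or graph.is_multigraph():
        raise ValidationError("physical network must be a simple undirected graph")
    loops = list(nx.selfloop_edges(graph))
    if loops:
        raise ValidationError(f"physical network contains self-loops: {loops[:5]}")
    return graph


def validate_conceptual(graph: nx.Graph) -> nx.Graph:
    """Check conceptual-network invariants: simple, self-loop free, every
    edge weight finite and strictly positive."""
    if graph.is_directed() or graph.is_multigraph():
        raise ValidationError("conceptual network must be a simple undirected graph")
    loops = list(nx.selfloop_edges(graph))
    if loops:
        raise ValidationError(f"conceptual network contains self-loops: {loops[:5]}")
    for u, v, data in graph.edges(data=True):
        w = data.get("weight")
        if w is None:
            raise ValidationError(f"conceptual edge ({u}, {v}) has no weight")
        w = float(w)
        if not (w > 0.0) or w != w or w == float("inf"):
            raise ValidationError(
                f"conceptual edge ({u}, {v}) has non-positive or non-finite weight {w}"
            )
    return graph


def identity_mapping(physical: nx.Graph, conceptual: nx.Graph) -> tuple[tuple[str, str], ...]:
    """Identity correspondence over the shared node identifiers of the two
    layers (sorted for determinism)."""
    shared = sorted(set(physical.nodes) & set(conceptual.nodes))
    return tuple((n, n) for n in shared)


@dataclass(frozen=True)
class DualNetwork:
    """A physical/conceptual graph pair plus node correspondences.

    ``mapping`` is a tuple of (physical node, conceptual node) pairs; it is
    the correspondence set the alignment graph is built over.  ``similarity``
    optionally carries a per-pair similarity score parsed from the mapping
    file; it is stored but not used by any downstream computation.
    """

    physical: nx.Graph
    conceptual: nx.Graph
    mapping: tuple[tuple[str, str], ...]
    similarity: dict[tuple[str, str], float] = field(default_factory=dict)

    def validate(self) -> "DualNetwork":
        validate_physical(self.physical)
        validate_conceptual(self.conceptual)
        if not self.mapping:
            raise ValidationError("node mapping must be non-empty")
        if len(set(self.mapping)) != len(self.mapping):
            raise ValidationError("node mapping contains duplicate pairs")
        bad_phys = sorted({v for v, _ in self.mapping if v not in self.physical})
        bad_conc = sorted({w for _, w in self.mapping if w not in self.conceptual})
        if bad_phys or bad_conc:
            raise ValidationError(
                "mapping references unknown nodes: "
                f"physical {bad_phys[:10]}, conceptual {bad_conc[:10]}"
            )
        return self


def assemble_dual_network(
    physical: nx.Graph,
    conceptual: nx.Graph,
    mapping: tuple[tuple[str, str], ...] | None = None,
    similarity: dict[tuple[str, str], float] | None = None,
) -> DualNetwork:
    """Assemble and validate a :class:`DualNetwork`.

    When ``mapping`` is omitted the identity correspondence over the
    intersection of the two node sets is derived; the intersection must be
    non-empty.  Re-assembling a valid dual network is a no-op (idempotent).
    """
    validate_physical(physical)
    validate_conceptual(conceptual)
    if mapping is None:
        mapping = identity_mapping(physical, conceptual)
        if not mapping:
            raise ValidationError(
                "no mapping given and the two node sets share no identifier"
            )
    else:
        mapping = tuple(dict.fromkeys(tuple(p) for p in mapping))
    dn = DualNetwork(
        physical=physical,
        conceptual=conceptual,
        mapping=mapping,
        similarity=dict(similarity or {}),
    )
    return dn.validate()
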