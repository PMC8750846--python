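"""Synthetic dual networks with planted communities.

The generator emulates a planted-partition benchmark over two layers that
share one latent community structure: starting from an edgeless graph,
community node sets are sampled (sizes uniform in [size_min, size_max]),
then each layer is realised independently — node pairs that co-occur in at
least one community connect with probability p_in, all other pairs with
probability p_out.  Conceptual edges additionally draw a weight:
within-community edges from U(0.5, 1.0) (strong association) and
between-community edges from U(0, 0.5) (weak association), mirroring
normalised similarity scores where 1 means closely related.

The default specification plants 200 communities of sizes 4–100 on 500
nodes with layers calibrated to ≈3000 physical and ≈4000 conceptual edges.
At that load the expected total membership (~10,400) far exceeds the node
count, so communities necessarily overlap; ``overlap_mode="overlapping"``
samples each community's nodes independently, while ``"disjoint"`` carves
non-overlapping blocks (useful for exactly recoverable test cases).

When edge probabilities are not given they are calibrated so the expected
edge count matches the target, with the within/between ratio fixed at
``mixing_ratio`` (p_in = mixing_ratio · p_out).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .model import DualNetwork, DualNetworkError, assemble_dual_network

__all__ = [
    "SyntheticSpec",
    "solve_edge_probabilities",
    "calibrate_edge_probabilities",
    "sample_ground_truth",
    "generate_dual_network",
]


@dataclass(frozen=True)
class SyntheticSpec:
    n_nodes: int = 500
    n_communities: int = 200
    size_min: int = 4
    size_max: int = 100
    overlap_mode: str = "overlapping"  # or "disjoint"
    # per-layer Bernoulli probabilities; None means "calibrate to target"
    p_in_physical: float | None = None
    p_out_physical: float | None = None
    p_in_conceptual: float | None = None
    p_out_conceptual: float | None = None
    physical_edge_target: int = 3000
    conceptual_edge_target: int = 4000
    mixing_ratio: float = 10.0  # p_in / p_out when calibrating
    weight_within: tuple[float, float] = (0.5, 1.0)
    weight_between: tuple[float, float] = (0.0, 0.5)
    seed: int = 42

    def validate(self) -> "SyntheticSpec":
        if self.n_nodes < 2 or self.n_communities < 1:
            raise DualNetworkError("need at least 2 nodes and 1 community")
        if not (2 <= self.size_min <= self.size_max <= self.n_nodes):
            raise DualNetworkError(
                f"community sizes must satisfy 2 <= {self.size_min} <= "
                f"{self.size_max} <= {self.n_nodes}"
            )
        if self.overlap_mode not in ("overlapping", "disjoint"):
            raise DualNetworkError(f"unknown overlap_mode {self.overlap_mode!r}")
        for name in ("p_in_physical", "p_out_physical", "p_in_conceptual", "p_out_conceptual"):
            p = getattr(self, name)
            if p is not None and not (0.0 <= p <= 1.0):
                raise DualNetworkError(f"{name}={p} outside [0, 1]")
        for p_in, p_out in (
            (self.p_in_physical, self.p_out_physical),
            (self.p_in_conceptual, self.p_out_conceptual),
        ):
            if p_in is not None and p_out is not None and not (p_out <= p_in):
                raise DualNetworkError("p_out must not exceed p_in")
        if self.mixing_ratio < 1.0:
            raise DualNetworkError("mixing_ratio must be >= 1")
        return self


def _node_label(i: int) -> str:
    return f"n{i:04d}"


def sample_ground_truth(spec: SyntheticSpec, rng: np.random.Generator) -> list[frozenset[str]]:
    """Sample the planted community node sets for ``spec``."""
    sizes = rng.integers(spec.size_min, spec.size_max + 1, size=spec.n_communities)
    communities: list[frozenset[str]] = []
    if spec.overlap_mode == "disjoint":
        if int(sizes.sum()) > spec.n_nodes:
            raise DualNetworkError(
                f"disjoint communities need {int(sizes.sum())} nodes but only "
                f"{spec.n_nodes} are available"
            )
        order = rng.permutation(spec.n_nodes)
        cursor = 0
        for s in sizes:
            block = order[cursor : cursor + int(s)]
            communities.append(frozenset(_node_label(i) for i in block))
            cursor += int(s)
    else:
        for s in sizes:
            members = rng.choice(spec.n_nodes, size=int(s), replace=False)
            communities.append(frozenset(_node_label(i) for i in members))
    return communities


def _within_pairs(communities: list[frozenset[str]], n_nodes: int) -> np.ndarray:
    """Boolean mask over the upper-triangle pair enumeration marking node
    pairs that co-occur in at least one planted community."""
    index = {_node_label(i): i for i in range(n_nodes)}
    mask = np.zeros((n_nodes, n_nodes), dtype=bool)
    for com in communities:
        members = np.fromiter((index[m] for m in com), dtype=np.int64)
        mask[np.ix_(members, members)] = True
    iu, ju = np.triu_indices(n_nodes, k=1)
    return mask[iu, ju]


def solve_edge_probabilities(
    n_within: int, n_between: int, target: int, mixing_ratio: float
) -> tuple[float, float]:
    """Closed-form (p_in, p_out) so the expected edge count hits ``target``
    with p_in = mixing_ratio · p_out; p_in is capped at 1."""
    if target < 0:
        raise DualNetworkError("edge target must be non-negative")
    if target > n_within + n_between:
        raise DualNetworkError(
            f"edge target {target} exceeds the {n_within + n_between} available pairs"
        )
    if target == 0:
        return 0.0, 0.0
    denom = mixing_ratio * n_within + n_between
    if denom == 0:
        raise DualNetworkError("no node pairs to place edges on")
    p_out = target / denom
    p_in = mixing_ratio * p_out
    if p_in > 1.0:
        p_in = 1.0
        if n_between == 0:
            raise DualNetworkError(f"edge target {target} exceeds within-pair count")
        p_out = (target - n_within) / n_between
        p_out = max(p_out, 0.0)
    return p_in, p_out


def calibrate_edge_probabilities(spec: SyntheticSpec) -> SyntheticSpec:
    """Fill in any unset layer probabilities from the spec's edge targets,
    using the community structure implied by the spec's seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    truth = sample_ground_truth(spec, rng)
    within = _within_pairs(truth, spec.n_nodes)
    n_within = int(within.sum())
    n_between = int(within.size - n_within)
    updates: dict[str, float] = {}
    if spec.p_in_physical is None or spec.p_out_physical is None:
        p_in, p_out = solve_edge_probabilities(
            n_within, n_between, spec.physical_edge_target, spec.mixing_ratio
        )
        updates["p_in_physical"] = p_in
        updates["p_out_physical"] = p_out
    if spec.p_in_conceptual is None or spec.p_out_conceptual is None:
        p_in, p_out = solve_edge_probabilities(
            n_within, n_between, spec.conceptual_edge_target, spec.mixing_ratio
        )
        updates["p_in_conceptual"] = p_in
        updates["p_out_conceptual"] = p_out
    return replace(spec, **updates)


def _sample_layer(
    rng: np.random.Generator,
    n_nodes: int,
    within: np.ndarray,
    p_in: float,
    p_out: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bernoulli edge realisation; returns (i, j, is_within) index arrays."""
    iu, ju = np.triu_indices(n_nodes, k=1)
    probs = np.where(within, p_in, p_out)
    chosen = rng.random(probs.shape) < probs
    return iu[chosen], ju[chosen], within[chosen]


def generate_dual_network(spec: SyntheticSpec) -> tuple[DualNetwork, list[frozenset[str]]]:
    """Generate a dual network plus its planted ground truth.

    Fully reproducible: the same spec (seed included) yields bit-identical
    edge lists.  Both layers share the sampled community structure but are
    realised independently.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    truth = sample_ground_truth(spec, rng)
    within = _within_pairs(truth, spec.n_nodes)
    n_within = int(within.sum())
    n_between = int(within.size - n_within)

    def probs_for(p_in, p_out, target):
        if p_in is None or p_out is None:
            return solve_edge_probabilities(n_within, n_between, target, spec.mixing_ratio)
        return p_in, p_out

    p_in_p, p_out_p = probs_for(
        spec.p_in_physical, spec.p_out_physical, spec.physical_edge_target
    )
    p_in_c, p_out_c = probs_for(
        spec.p_in_conceptual, spec.p_out_conceptual, spec.conceptual_edge_target
    )

    labels = [_node_label(i) for i in range(spec.n_nodes)]
    physical = nx.Graph()
    physical.add_nodes_from(labels)
    pi, pj, _ = _sample_layer(rng, spec.n_nodes, within, p_in_p, p_out_p)
    physical.add_edges_from(zip((labels[i] for i in pi), (labels[j] for j in pj)))

    conceptual = nx.Graph()
    conceptual.add_nodes_from(labels)
    ci, cj, c_within = _sample_layer(rng, spec.n_nodes, within, p_in_c, p_out_c)
    lo_in, hi_in = spec.weight_within
    lo_out, hi_out = spec.weight_between
    weights = np.where(
        c_within,
        rng.uniform(lo_in, hi_in, size=c_within.size),
        rng.uniform(lo_out, hi_out, size=c_within.size),
    )
    weights = np.maximum(weights, 1e-9)  # conceptual weights must stay positive
    conceptual.add_weighted_edges_from(
        (labels[i], labels[j], float(w)) for i, j, w in zip(ci, cj, weights)
    )

    dn = assemble_dual_network(physical, conceptual)
    return dn, truth
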