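"""Independent brute-force oracles used only by the tests.

Everything here is deliberately naive — exhaustive enumeration, direct
pair counting, textbook entropy formulas — and shares no code with the
package implementation it cross-checks.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter


# ---------------------------------------------------------------- partitions

def set_partitions(items):
    """Yield every partition of ``items`` as a list of lists."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for sub in set_partitions(rest):
        for i in range(len(sub)):
            yield sub[:i] + [[first] + sub[i]] + sub[i + 1 :]
        yield [[first]] + sub


def modularity_naive(graph, blocks, resolution=1.0):
    """Weighted Newman–Girvan Q by direct double summation over node pairs."""
    nodes = list(graph.nodes)
    label = {}
    for idx, block in enumerate(blocks):
        for n in block:
            label[n] = idx
    m = sum(d.get("weight", 1.0) for _, _, d in graph.edges(data=True))
    if m == 0:
        return 0.0
    degree = {n: sum(d.get("weight", 1.0) for _, _, d in graph.edges(n, data=True))
              for n in nodes}
    q = 0.0
    for i in nodes:
        for j in nodes:
            if label[i] != label[j]:
                continue
            a_ij = graph[i][j].get("weight", 1.0) if graph.has_edge(i, j) else 0.0
            q += a_ij - resolution * degree[i] * degree[j] / (2 * m)
    return q / (2 * m)


def best_partition_exhaustive(graph, resolution=1.0):
    """Globally optimal-modularity partition by enumerating all partitions."""
    best_q, best_blocks = -math.inf, None
    for blocks in set_partitions(graph.nodes):
        q = modularity_naive(graph, blocks, resolution)
        if q > best_q:
            best_q, best_blocks = q, blocks
    return best_q, [frozenset(b) for b in best_blocks]


# ---------------------------------------------------------------- densest

def _subset_density(graph, subset):
    subset = set(subset)
    w = sum(
        d.get("weight", 1.0)
        for u, v, d in graph.edges(data=True)
        if u in subset and v in subset
    )
    return w / len(subset)


def densest_subset_exhaustive(graph):
    """(nodes, density) of the true densest subgraph over all subsets."""
    nodes = list(graph.nodes)
    best, best_set = -1.0, None
    for r in range(1, len(nodes) + 1):
        for subset in itertools.combinations(nodes, r):
            d = _subset_density(graph, subset)
            if d > best:
                best, best_set = d, frozenset(subset)
    return best_set, best


def densest_connected_exhaustive(graph, physical):
    """Densest subset whose induced subgraph in ``physical`` is connected."""
    import networkx as nx

    nodes = list(graph.nodes)
    best, best_set = -1.0, None
    for r in range(1, len(nodes) + 1):
        for subset in itertools.combinations(nodes, r):
            sub = physical.subgraph(subset)
            if sub.number_of_nodes() and not nx.is_connected(sub):
                continue
            d = _subset_density(graph, subset)
            if d > best:
                best, best_set = d, frozenset(subset)
    return best_set, best


def unweighted_peel_naive(graph):
    """Classic (unweighted) Charikar peel with the same lexicographic
    tie-break; O(n^2) list scans, no heap."""
    remaining = set(graph.nodes)
    best_set = frozenset(remaining)

    def density(s):
        return sum(1 for u, v in graph.edges() if u in s and v in s) / len(s)

    best = density(remaining)
    while len(remaining) > 1:
        victim = min(remaining, key=lambda n: (sum(1 for x in graph[n] if x in remaining), str(n)))
        remaining.discard(victim)
        d = density(remaining)
        if d > best:
            best, best_set = d, frozenset(remaining)
    return best_set, best


# ---------------------------------------------------------------- metrics

def sn_naive(known, extracted):
    total, covered = 0, 0.0
    for k in known:
        best = max((len(set(k) & set(e)) for e in extracted), default=0)
        covered += best
        total += len(k)
    return covered / total


def ppv_naive(known, extracted):
    num, denom = 0.0, 0.0
    for e in extracted:
        col = [len(set(k) & set(e)) for k in known]
        mass = sum(col)
        if mass == 0:
            continue
        num += mass * (max(col) / mass)
        denom += mass
    return num / denom if denom else 0.0


def acc_naive(known, extracted):
    return math.sqrt(sn_naive(known, extracted) * ppv_naive(known, extracted))


def prf_naive(known, extracted, threshold):
    def jac(a, b):
        a, b = set(a), set(b)
        return len(a & b) / len(a | b)

    valid = [e for e in extracted if any(jac(k, e) >= threshold for k in known)]
    found = [k for k in known if any(jac(k, e) >= threshold for e in extracted)]
    p = len(valid) / len(extracted)
    r = len(found) / len(known)
    f = 0.0 if p + r == 0 else 2 * p * r / (p + r)
    return p, r, f


def _entropy(labels):
    n = len(labels)
    return -sum(c / n * math.log(c / n) for c in Counter(labels).values() if c)


def nmi_naive(labels_a, labels_b):
    """Arithmetic-mean NMI from joint counts; 1.0 for two constant labelings."""
    assert len(labels_a) == len(labels_b)
    n = len(labels_a)
    ha, hb = _entropy(labels_a), _entropy(labels_b)
    if ha == 0 and hb == 0:
        return 1.0
    joint = Counter(zip(labels_a, labels_b))
    ca, cb = Counter(labels_a), Counter(labels_b)
    mi = 0.0
    for (a, b), c in joint.items():
        mi += (c / n) * math.log(n * c / (ca[a] * cb[b]))
    return mi / ((ha + hb) / 2)


def rand_naive(labels_a, labels_b):
    n = len(labels_a)
    agree = 0
    for i in range(n):
        for j in range(i + 1, n):
            same_a = labels_a[i] == labels_a[j]
            same_b = labels_b[i] == labels_b[j]
            agree += same_a == same_b
    return agree / (n * (n - 1) / 2)
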