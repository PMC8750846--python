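"""Evaluation statistics for community recovery.

Two families of scores compare extracted communities with planted
(known) ones:

* **Complex-detection statistics** built on the confusion matrix
  C[i][j] = |known_i ∩ extracted_j|: clustering-wise sensitivity Sn
  (best-match coverage of each known community, size-weighted),
  clustering-wise positive predictive value PPV (column-normalised
  best-match precision of each extracted community, weighted by column
  mass), and the geometric accuracy Acc = sqrt(Sn · PPV).  Precision,
  recall and F-score count *valid* matches — extracted communities whose
  best Jaccard overlap with a known community reaches a threshold
  (default 0.5).

* **Partition-agreement indices**: normalised mutual information
  (arithmetic-mean normalisation) and the Rand index.  These require hard
  partitions, so overlapping community lists are first resolved to one
  label per node; nodes in no community share a single background label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import normalized_mutual_info_score, rand_score

from .model import DualNetworkError

__all__ = [
    "ConfusionMatrix",
    "confusion_matrix",
    "community_sensitivity",
    "community_ppv",
    "geometric_accuracy",
    "precision_recall_fscore",
    "communities_to_labels",
    "normalized_mutual_information",
    "rand_index",
    "EvaluationReport",
    "evaluate_communities",
]

NodeSets = "list[frozenset[str] | set[str]]"


@dataclass(frozen=True)
class ConfusionMatrix:
    """Overlap counts between known (rows) and extracted (columns)
    communities, plus the community sizes the statistics weight by."""

    counts: np.ndarray
    known_sizes: np.ndarray
    extracted_sizes: np.ndarray


def confusion_matrix(known, extracted) -> ConfusionMatrix:
    """C[i][j] = |known_i ∩ extracted_j| by exact set intersection."""
    if not known or not extracted:
        raise DualNetworkError("known and extracted community lists must be non-empty")
    known = [frozenset(c) for c in known]
    extracted = [frozenset(c) for c in extracted]
    if any(not c for c in known) or any(not c for c in extracted):
        raise DualNetworkError("communities must be non-empty node sets")
    counts = np.array(
        [[len(k & e) for e in extracted] for k in known], dtype=np.int64
    )
    return ConfusionMatrix(
        counts=counts,
        known_sizes=np.array([len(k) for k in known], dtype=np.int64),
        extracted_sizes=np.array([len(e) for e in extracted], dtype=np.int64),
    )


def community_sensitivity(cm: ConfusionMatrix) -> float:
    """Clustering-wise Sn: size-weighted mean over known communities of the
    maximal fraction of their nodes found in a single extracted community."""
    best = cm.counts.max(axis=1) if cm.counts.size else np.zeros(len(cm.known_sizes))
    sn_i = best / cm.known_sizes
    return float(np.sum(cm.known_sizes * sn_i) / np.sum(cm.known_sizes))


def community_ppv(cm: ConfusionMatrix) -> float:
    """Clustering-wise PPV: per extracted community j, the largest
    column-normalised share C[i][j] / Σ_i C[i][j]; averaged over extracted
    communities weighted by the column mass Σ_i C[i][j]."""
    col_mass = cm.counts.sum(axis=0)
    if col_mass.sum() == 0:
        warnings.warn("no overlap between known and extracted communities; PPV = 0",
                      stacklevel=2)
        return 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        ppv_j = np.where(col_mass > 0, cm.counts.max(axis=0) / col_mass, 0.0)
    return float(np.sum(col_mass * ppv_j) / np.sum(col_mass))


def geometric_accuracy(sn: float, ppv: float) -> float:
    """Acc = sqrt(Sn · PPV)."""
    return float(np.sqrt(sn * ppv))


def _jaccard(a: frozenset, b: frozenset) -> float:
    return len(a & b) / len(a | b)


def precision_recall_fscore(
    known, extracted, validity_threshold: float = 0.5
) -> tuple[float, float, float]:
    """Match-counting precision/recall/F at a Jaccard validity threshold.

    An extracted community is *valid* when its best Jaccard overlap with a
    known community reaches the threshold; a known community is *found*
    when some extracted community matches it at the threshold.
    Precision = valid/extracted, Recall = found/known, F = 2PR/(P+R)
    (0 when P + R = 0).
    """
    if not (0.0 < validity_threshold <= 1.0):
        raise DualNetworkError(
            f"validity threshold must lie in (0, 1], got {validity_threshold}"
        )
    if not known or not extracted:
        raise DualNetworkError("known and extracted community lists must be non-empty")
    known = [frozenset(c) for c in known]
    extracted = [frozenset(c) for c in extracted]
    valid = set()
    found = set()
    for j, e in enumerate(extracted):
        for i, k in enumerate(known):
            if _jaccard(k, e) >= validity_threshold:
                valid.add(j)
                found.add(i)
    precision = len(valid) / len(extracted)
    recall = len(found) / len(known)
    f_score = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f_score


BACKGROUND = -1


def communities_to_labels(
    communities,
    universe,
    reference_labels: dict | None = None,
) -> dict:
    """Resolve a (possibly overlapping) community list to one label per node.

    Nodes belonging to no community share the single background label -1.
    A node with several memberships is assigned to the containing community
    with the highest Jaccard similarity to the node's cluster under
    ``reference_labels`` (when given); without a reference, ties and
    multi-membership resolve to the earliest community in the list.
    """
    universe = sorted(universe)
    membership: dict[str, list[int]] = {n: [] for n in universe}
    communities = [frozenset(c) for c in communities]
    for idx, com in enumerate(communities):
        for node in com:
            if node in membership:
                membership[node].append(idx)
    ref_clusters: dict[int, frozenset] = {}
    if reference_labels is not None:
        clusters: dict[object, set] = {}
        for node, lab in reference_labels.items():
            clusters.setdefault(lab, set()).add(node)
        ref_of_node = {n: frozenset(clusters[l]) for n, l in reference_labels.items()}
    labels: dict[str, int] = {}
    for node in universe:
        owners = membership[node]
        if not owners:
            labels[node] = BACKGROUND
        elif len(owners) == 1 or reference_labels is None:
            labels[node] = owners[0]
        else:
            ref = ref_of_node.get(node, frozenset())
            labels[node] = max(owners, key=lambda i: (_jaccard(communities[i], ref), -i))
    return labels


def _label_arrays(labels_a: dict, labels_b: dict) -> tuple[np.ndarray, np.ndarray]:
    if set(labels_a) != set(labels_b):
        raise DualNetworkError("partitions must label the same node universe")
    nodes = sorted(labels_a)
    a = np.array([labels_a[n] for n in nodes])
    b = np.array([labels_b[n] for n in nodes])
    return a, b


def normalized_mutual_information(labels_a: dict, labels_b: dict) -> float:
    """NMI with arithmetic-mean normalisation, in [0, 1]."""
    a, b = _label_arrays(labels_a, labels_b)
    return float(normalized_mutual_info_score(a, b, average_method="arithmetic"))


def rand_index(labels_a: dict, labels_b: dict) -> float:
    """Fraction of node pairs on which the two partitions agree."""
    a, b = _label_arrays(labels_a, labels_b)
    if a.size < 2:
        raise DualNetworkError("Rand index needs a universe of at least 2 nodes")
    return float(rand_score(a, b))


@dataclass(frozen=True)
class EvaluationReport:
    """All community-recovery statistics for one extraction run."""

    sn: float
    ppv: float
    acc: float
    precision: float
    recall: float
    f_score: float
    mi: float
    rand: float
    f_score_mi_rand: float
    best_matches: tuple[tuple[int, int, float], ...] = field(default=())

    def as_dict(self) -> dict[str, float]:
        return {
            "sn": self.sn,
            "ppv": self.ppv,
            "acc": self.acc,
            "precision": self.precision,
            "recall": self.recall,
            "f_score": self.f_score,
            "mi": self.mi,
            "rand": self.rand,
            "f_score_mi_rand": self.f_score_mi_rand,
        }


def evaluate_communities(
    known,
    extracted,
    universe,
    validity_threshold: float = 0.5,
) -> EvaluationReport:
    """Compute every recovery statistic for one known/extracted comparison.

    ``universe`` is the full node set the partitions are taken over.  The
    extracted list is resolved to labels first; the (possibly overlapping)
    known list is then resolved against those labels, assigning each
    multi-membership node to its best-matching known community.
    """
    known = [frozenset(c) for c in known]
    extracted = [frozenset(c) for c in extracted]
    if not extracted:
        # nothing detected: every score is 0 by convention
        return EvaluationReport(0, 0, 0, 0, 0, 0, 0, 0, 0)
    cm = confusion_matrix(known, extracted)
    sn = community_sensitivity(cm)
    ppv = community_ppv(cm)
    acc = geometric_accuracy(sn, ppv)
    precision, recall, f_score = precision_recall_fscore(known, extracted, validity_threshold)
    extracted_labels = communities_to_labels(extracted, universe)
    known_labels = communities_to_labels(known, universe, reference_labels=extracted_labels)
    mi = normalized_mutual_information(known_labels, extracted_labels)
    rand = rand_index(known_labels, extracted_labels)
    best = tuple(
        (i, int(np.argmax(cm.counts[i])), float(cm.counts[i].max() / cm.known_sizes[i]))
        for i in range(len(known))
    )
    return EvaluationReport(
        sn=sn,
        ppv=ppv,
        acc=acc,
        precision=precision,
        recall=recall,
        f_score=f_score,
        mi=mi,
        rand=rand,
        f_score_mi_rand=float(np.sqrt(mi * rand)),
        best_matches=best,
    )
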