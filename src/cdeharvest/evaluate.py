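"""Scoring of recovered element clusters against generator ground truth.

Clustering quality is measured on item *pairs*: of all pairs of items
the truth puts in one element, how many did the clustering co-assign
(recall), and of all co-assigned pairs, how many are truly together
(precision).  Counts come from the contingency table, so scoring is
linear in the number of items.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .normalize import ElementCluster
from .synth import GroundTruth


@dataclass(frozen=True)
class PairwiseScore:
    precision: float
    recall: float
    n_items: int
    true_pairs: int
    pred_pairs: int
    common_pairs: int

    @property
    def f1(self) -> float:
        if self.precision + self.recall == 0:
            return 0.0
        return 2 * self.precision * self.recall / (self.precision + self.recall)


def _pairs(n: int) -> int:
    return n * (n - 1) // 2


def pairwise_cluster_score(
    clusters: Sequence[ElementCluster],
    true_partition: Mapping[str, str],
) -> PairwiseScore:
    """Pairwise precision/recall of a clustering vs. the true partition.

    ``true_partition`` maps "trial|form|item" keys to true element ids;
    items absent from either side are ignored.
    """
    pred_of: dict[str, str] = {}
    for c in clusters:
        for tr, fid, iid in c.members:
            pred_of[GroundTruth.item_key(tr, fid, iid)] = c.cluster_id

    keys = [k for k in true_partition if k in pred_of]
    true_sizes: dict[str, int] = {}
    pred_sizes: dict[str, int] = {}
    cont: dict[tuple[str, str], int] = {}
    for k in keys:
        t, p = true_partition[k], pred_of[k]
        true_sizes[t] = true_sizes.get(t, 0) + 1
        pred_sizes[p] = pred_sizes.get(p, 0) + 1
        cont[(t, p)] = cont.get((t, p), 0) + 1

    true_pairs = sum(_pairs(n) for n in true_sizes.values())
    pred_pairs = sum(_pairs(n) for n in pred_sizes.values())
    common = sum(_pairs(n) for n in cont.values())
    return PairwiseScore(
        precision=common / pred_pairs if pred_pairs else 1.0,
        recall=common / true_pairs if true_pairs else 1.0,
        n_items=len(keys),
        true_pairs=true_pairs,
        pred_pairs=pred_pairs,
        common_pairs=common,
    )


def exact_recovery(
    clusters: Sequence[ElementCluster], true_partition: Mapping[str, str]
) -> bool:
    """True when the clustering equals the true partition as a set of
    item groups."""
    pred_groups: dict[str, set[str]] = {}
    for c in clusters:
        pred_groups[c.cluster_id] = {
            GroundTruth.item_key(*m) for m in c.members
        }
    true_groups: dict[str, set[str]] = {}
    for k, e in true_partition.items():
        true_groups.setdefault(e, set()).add(k)
    return set(map(frozenset, pred_groups.values())) == set(
        map(frozenset, true_groups.values())
    )
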