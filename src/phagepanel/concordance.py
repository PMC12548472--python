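"""Adjusted Rand Index concordance between classification schemes.

Two partitions of the same phage set (e.g. receptor types vs physiological
clusters, or tail-fiber vs whole-genome groups) are compared through their
contingency table with the chance-corrected Rand index

    ARI = (Index - Expected) / (Max - Expected)

where Index = sum_ij C(n_ij, 2), Expected = sum_i C(a_i, 2) * sum_j C(b_j, 2)
/ C(n, 2) and Max = (sum_i C(a_i, 2) + sum_j C(b_j, 2)) / 2. ARI is 1 for
identical partitions and near 0 for random agreement; it is invariant to
relabeling, so the canonical relabeling applied before comparison affects
display only.
"""

from __future__ import annotations

import itertools
import warnings
from math import comb
from typing import Sequence

import pandas as pd

from .io import ConcordanceEntry, ConcordanceResult, Partition

__all__ = [
    "contingency",
    "adjusted_rand",
    "compare_all",
    "canonical_relabel",
]


def _check_same_items(p1: Partition, p2: Partition) -> None:
    s1, s2 = set(p1.item_ids), set(p2.item_ids)
    if s1 != s2:
        raise ValueError(
            f"partitions cover different items; symmetric difference: {sorted(s1 ^ s2)}"
        )


def canonical_relabel(p: Partition) -> Partition:
    """Relabel groups "1", "2", ... in order of first appearance.

    A display normalization only: ARI is invariant under any relabeling.
    """
    mapping: dict[str, str] = {}
    out = []
    for lab in p.labels:
        if lab not in mapping:
            mapping[lab] = str(len(mapping) + 1)
        out.append(mapping[lab])
    return Partition(list(p.item_ids), out)


def contingency(p1: Partition, p2: Partition) -> pd.DataFrame:
    """Cross-tabulation n_ij of group memberships, labels in first-appearance order."""
    _check_same_items(p1, p2)
    d2 = p2.as_dict()
    rows = list(dict.fromkeys(p1.labels))
    cols = list(dict.fromkeys(p2.labels))
    table = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    for item, lab1 in zip(p1.item_ids, p1.labels):
        table.at[lab1, d2[item]] += 1
    return table


def adjusted_rand(p1: Partition, p2: Partition) -> float:
    """Adjusted Rand Index between two partitions of the same items.

    Degenerate case (both partitions all singletons or both a single
    cluster, where the formula is 0/0): returns 1 if the partitions are
    identical as set partitions, else 0, with a warning.
    """
    _check_same_items(p1, p2)
    n = len(p1.item_ids)
    if n < 2:
        raise ValueError("ARI requires at least two items")
    table = contingency(p1, p2)
    nij = table.to_numpy()
    a = nij.sum(axis=1)
    b = nij.sum(axis=0)
    index = sum(comb(int(x), 2) for x in nij.ravel())
    sum_a = sum(comb(int(x), 2) for x in a)
    sum_b = sum(comb(int(x), 2) for x in b)
    expected = sum_a * sum_b / comb(n, 2)
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        identical = {frozenset(g) for g in p1.groups().values()} == {
            frozenset(g) for g in p2.groups().values()
        }
        warnings.warn(
            "degenerate ARI (both partitions trivial); returning 1 for identical "
            "partitions, 0 otherwise",
            stacklevel=2,
        )
        return 1.0 if identical else 0.0
    return (index - expected) / (max_index - expected)


def compare_all(named_partitions: Sequence[tuple[str, Partition]]) -> ConcordanceResult:
    """ARI for every unordered pair of named partitions.

    Partitions are canonically relabeled first (a no-op for ARI); both the
    raw and the 2-decimal display value are retained.
    """
    if len(named_partitions) < 2:
        raise ValueError("need at least two partitions to compare")
    names = [name for name, _ in named_partitions]
    if len(set(names)) != len(names):
        raise ValueError("partition names must be unique")
    normalized = [(name, canonical_relabel(p)) for name, p in named_partitions]
    result = ConcordanceResult()
    for (na, pa), (nb, pb) in itertools.combinations(normalized, 2):
        ari = adjusted_rand(pa, pb)
        result.entries.append(ConcordanceEntry(na, nb, ari, round(ari, 2)))
    return result
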