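"""Fold-change profile clustering: UPGMA dendrogram plus a dynamic tree cut.

Significant miRNAs are clustered on their log2 fold-change profiles across
exposures (average linkage, Euclidean distance). Instead of a single
fixed-height cut, the dendrogram is cut adaptively: walking top-down from the
root, a merge is treated as cluster-separating when its height stands well
clear of the internal merge heights of the branches it joins (a relative-gap
criterion whose stringency is set by ``deep_split``); branches that are never
split become clusters if they reach ``min_cluster_size``, and smaller
leftovers stay unassigned (label 0). This reproduces the variable-height
behaviour of dynamic dendrogram cutting with a deterministic, dependency-free
rule.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage

UNASSIGNED = 0

# relative-gap threshold per deep_split level; higher deep_split splits deeper
_GAP_BY_DEEP_SPLIT = {0: 0.30, 1: 0.20, 2: 0.15, 3: 0.10, 4: 0.05}

# a sub-min-size branch may only be detached when it attaches at least this
# many times higher than its sibling's internal merge height (a true outlier),
# which stops noise stragglers from being split off their own cluster
_DISTAL_FACTOR = 3.0


def build_profile(
    records: pd.DataFrame, exposures: list[str] | None = None
) -> pd.DataFrame:
    """log2 fold-change matrix (significant miRNA x exposure) from records.

    A miRNA enters if it is significant under any exposure; cells for
    exposures where it was not significant still carry its measured log2 FC,
    and exposures where it was not measured are imputed as 0 (no change).
    """
    sig = records[records["significant"]]
    if sig.empty:
        raise ValueError("no significant records to profile")
    mirnas = sorted(sig["mirna"].unique())
    if exposures is None:
        exposures = sorted(records["exposure"].unique())
    sub = records[records["mirna"].isin(mirnas)]
    mat = (
        sub.pivot_table(index="mirna", columns="exposure", values="fold_change")
        .reindex(index=mirnas, columns=exposures)
    )
    profile = np.log2(mat)
    return profile.fillna(0.0)


def average_linkage_dendrogram(profile: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """UPGMA merge tree on Euclidean distances between profile rows.

    Rows are sorted lexicographically by miRNA name first, which makes the
    scipy linkage (and thus any tie-break) independent of input order.
    Returns (scipy linkage matrix, leaf names in the sorted order).
    """
    if profile.index.duplicated().any():
        dup = profile.index[profile.index.duplicated()][0]
        raise ValueError(f"duplicate miRNA row: {dup!r}")
    if len(profile) < 2:
        raise ValueError("need at least 2 miRNAs to build a dendrogram")
    profile = profile.sort_index()
    z = linkage(profile.to_numpy(), method="average", metric="euclidean")
    return z, list(profile.index)


@dataclass
class ClusterAssignment:
    """miRNA -> cluster label (1..k contiguous; 0 = unassigned) + dendrogram."""

    labels: pd.Series
    linkage: np.ndarray
    leaves: list[str]

    def members(self, label: int) -> list[str]:
        return sorted(self.labels.index[self.labels == label])

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) if len(self.labels) else 0

    def as_partition(self) -> set[frozenset[str]]:
        """Label-free view for partition comparisons (unassigned excluded)."""
        return {
            frozenset(self.members(c)) for c in range(1, self.n_clusters + 1)
        }


def _node_members(z: np.ndarray, n_leaves: int) -> list[list[int]]:
    members: list[list[int]] = [[i] for i in range(n_leaves)]
    for a, b, _h, _c in z:
        members.append(members[int(a)] + members[int(b)])
    return members


def dynamic_tree_cut(
    z: np.ndarray,
    leaves: list[str],
    min_cluster_size: int = 3,
    deep_split: int = 1,
) -> ClusterAssignment:
    """Adaptive top-down cut of a UPGMA dendrogram.

    A node is split into its two children when (a) the relative gap
    ``(h - max(h_child)) / h`` between its merge height and its children's
    internal heights reaches the threshold set by ``deep_split``, and (b)
    either both children hold at least ``min_cluster_size`` leaves or the
    smaller branch is a distal outlier (it attaches far above its sibling's
    internal structure). Recursion continues inside split branches; unsplit
    branches become clusters when they hold at least ``min_cluster_size``
    leaves, otherwise their members are left unassigned. Clusters are
    numbered 1..k in dendrogram order.
    """
    if min_cluster_size < 1:
        raise ValueError("min_cluster_size must be >= 1")
    if deep_split not in _GAP_BY_DEEP_SPLIT:
        raise ValueError(f"deep_split must be one of {sorted(_GAP_BY_DEEP_SPLIT)}")
    gap_threshold = _GAP_BY_DEEP_SPLIT[deep_split]
    n = len(leaves)
    if z.shape[0] != n - 1:
        raise ValueError("linkage matrix does not match the leaf list")
    members = _node_members(z, n)
    heights = np.concatenate([np.zeros(n), z[:, 2]])

    groups: list[list[int]] = []

    def visit(node: int) -> None:
        if node < n:
            groups.append(members[node])
            return
        row = z[node - n]
        a, b, h = int(row[0]), int(row[1]), float(row[2])
        internal = max(heights[a], heights[b])
        if not (h > 0 and (h - internal) / h >= gap_threshold):
            groups.append(members[node])
            return
        small, big = sorted((a, b), key=lambda c: len(members[c]))
        if len(members[small]) < min_cluster_size:
            sibling_internal = heights[big]
            distal = sibling_internal == 0 or h >= _DISTAL_FACTOR * sibling_internal
            if not distal:
                groups.append(members[node])
                return
        visit(a)
        visit(b)

    visit(2 * n - 2)

    labels = pd.Series(UNASSIGNED, index=pd.Index(leaves, name="mirna"), dtype=int)
    next_label = 1
    for grp in groups:
        if len(grp) >= min_cluster_size:
            labels.iloc[grp] = next_label
            next_label += 1
    return ClusterAssignment(labels=labels, linkage=z, leaves=list(leaves))


def dendrogram_newick(z: np.ndarray, leaves: list[str]) -> str:
    """Render the merge tree as a Newick string for inspection."""
    n = len(leaves)
    reps: list[str] = [name for name in leaves]
    heights = [0.0] * n
    for a, b, h, _c in z:
        a, b = int(a), int(b)
        la = (h - heights[a]) / 2.0
        lb = (h - heights[b]) / 2.0
        reps.append(f"({reps[a]}:{la:.6g},{reps[b]}:{lb:.6g})")
        heights.append(float(h))
    return reps[-1] + ";"


def rand_index(labels_a: pd.Series, labels_b: pd.Series) -> float:
    """Plain Rand index between two labelings over the same items."""
    a = labels_a.sort_index().to_numpy()
    b = labels_b.loc[labels_a.sort_index().index].to_numpy()
    n = len(a)
    same_a = a[:, None] == a[None, :]
    same_b = b[:, None] == b[None, :]
    iu = np.triu_indices(n, k=1)
    agree = (same_a[iu] == same_b[iu]).sum()
    return float(agree) / len(iu[0])
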