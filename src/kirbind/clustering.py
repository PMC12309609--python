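"""Hierarchical clustering of the binding matrix and binding-class labels.

Both axes of the normalized binding matrix are clustered with average
linkage (UPGMA) over Euclidean distances. Cutting the HLA-axis tree into
three clusters and ranking the clusters by mean binding yields the
high / low / non-binder taxonomy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy import stats

from .binding import NormalizedBindingMatrix

CLASS_ORDER = ("high", "low", "non")


@dataclass
class ClusterResult:
    axis: str
    names: list[str]
    linkage: np.ndarray
    leaf_order: list[str]

    def cut(self, k: int) -> dict[str, int]:
        """Cut the tree into exactly k clusters; returns name -> cluster id."""
        if k > len(self.names):
            raise ValueError(f"cannot cut {len(self.names)} leaves into {k} clusters")
        labels = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        if len(set(labels)) != k:
            raise ValueError(
                f"tree does not separate into {k} clusters "
                "(tied or zero merge heights)"
            )
        return dict(zip(self.names, (int(v) for v in labels)))

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)
        return _newick(tree, self.names) + ";"


def _newick(node, names) -> str:
    if node.is_leaf():
        return f"{names[node.id]}:{node.dist:.6g}"
    left = _newick(node.get_left(), names)
    right = _newick(node.get_right(), names)
    return f"({left},{right}):{node.dist:.6g}"


@dataclass
class BindingClassLabels:
    """Per-HLA three-class assignment plus derived binary tasks."""

    class_of: dict[str, str]

    @property
    def binder_labels(self) -> dict[str, int]:
        """+1 for binders (high or low), -1 for non-binders."""
        return {n: (1 if c in ("high", "low") else -1) for n, c in self.class_of.items()}

    @property
    def high_low_labels(self) -> dict[str, int]:
        """+1 for high, -1 for low; defined only on binder alleles."""
        return {
            n: (1 if c == "high" else -1)
            for n, c in self.class_of.items()
            if c in ("high", "low")
        }


def hierarchical_cluster(m: NormalizedBindingMatrix, axis: str) -> ClusterResult:
    """Average-link (UPGMA) clustering over Euclidean distances.

    Items on ``axis`` are represented by their binding vectors over the
    other axis (for HLA: the vector of normalized affinities to each KIR).
    """
    if axis == "kir":
        vectors, names = m.values, list(m.kir_names)
    elif axis == "hla":
        vectors, names = m.values.T, list(m.hla_names)
    else:
        raise ValueError("axis must be 'kir' or 'hla'")
    if len(names) < 2:
        raise ValueError("need at least two items to cluster")
    if not np.all(np.isfinite(vectors)):
        raise ValueError("binding vectors contain missing values")
    linkage = hierarchy.linkage(pdist(vectors, metric="euclidean"), method="average")
    leaves = hierarchy.leaves_list(linkage)
    return ClusterResult(
        axis=axis, names=names, linkage=linkage, leaf_order=[names[i] for i in leaves]
    )


def label_three_groups(
    cluster: ClusterResult, m: NormalizedBindingMatrix
) -> BindingClassLabels:
    """Cut the HLA tree into 3 clusters and rank them by mean binding.

    The cluster with the highest mean normalized binding becomes ``high``,
    then ``low``, then ``non``.
    """
    if cluster.axis != "hla":
        raise ValueError("three-group labels require an HLA-axis clustering")
    assignment = cluster.cut(3)
    frame = m.to_frame()
    means = {}
    for cid in set(assignment.values()):
        members = [n for n, c in assignment.items() if c == cid]
        means[cid] = float(frame[members].to_numpy().mean())
    ranked = sorted(means, key=means.get, reverse=True)
    name_of = dict(zip(ranked, CLASS_ORDER))
    return BindingClassLabels(
        class_of={n: name_of[c] for n, c in assignment.items()}
    )


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def group_difference_tests(
    values: dict[str, float] | pd.Series,
    groups: dict[str, str] | pd.Series,
    reference: str,
) -> dict:
    """Rank-sum tests vs a reference group, one-way ANOVA, and Tukey HSD.

    Returns a dict with ``rank_sum`` (DataFrame of two-sided Mann-Whitney
    p-values of each group against ``reference``, with significance stars),
    ``anova`` (F, p) and ``tukey`` (all-pairs adjusted p-values).
    """
    values = pd.Series(values, dtype=float)
    groups = pd.Series(groups).loc[values.index]
    by_group = {g: values[groups == g].to_numpy() for g in groups.unique()}
    if reference not in by_group:
        raise ValueError(f"reference group {reference!r} not present")
    small = [g for g, v in by_group.items() if len(v) < 2]
    if small:
        raise ValueError(f"groups with fewer than 2 members: {small}")

    rows = []
    ref_values = by_group[reference]
    for g, v in by_group.items():
        if g == reference:
            continue
        res = stats.mannwhitneyu(v, ref_values, alternative="two-sided")
        rows.append(
            {"group": g, "reference": reference, "p": float(res.pvalue),
             "stars": _stars(float(res.pvalue))}
        )
    rank_sum = pd.DataFrame(rows)

    order = sorted(by_group)
    samples = [by_group[g] for g in order]
    f_stat, anova_p = stats.f_oneway(*samples)

    tukey = stats.tukey_hsd(*samples)
    pairs = []
    for i in range(len(order)):
        for j in range(i + 1, len(order)):
            p = float(tukey.pvalue[i, j])
            pairs.append(
                {"group_a": order[i], "group_b": order[j], "p_adj": p,
                 "stars": _stars(p)}
            )
    return {
        "rank_sum": rank_sum,
        "anova": {"F": float(f_stat), "p": float(anova_p)},
        "tukey": pd.DataFrame(pairs),
    }


def motif_groups(
    panel, pos_a: int = 80, pos_b: int = 83, min_count: int = 2
) -> dict[str, str]:
    """Group alleles by their residue combination at two positions.

    Combinations observed fewer than ``min_count`` times are dropped
    (rare-combination filter; threshold is a parameter).
    """
    combos: dict[str, str] = {}
    for seq in panel:
        combos[seq.name] = f"{seq.residue_at(pos_a)}{pos_a}/{seq.residue_at(pos_b)}{pos_b}"
    counts = pd.Series(combos).value_counts()
    keep = set(counts[counts >= min_count].index)
    return {n: c for n, c in combos.items() if c in keep}
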