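"""Hierarchical clustering of accessions and per-group trait profiling.

Accessions are clustered on Euclidean distance with complete linkage
(inter-cluster distance = maximum pairwise member distance, the "furthest
neighbour" method), the monotone agglomerative method used for germplasm
grouping.  Distances are computed on z-scored traits by default so that
traits with large units do not dominate; raw-scale distances are one flag
away.  The tree is cut into k groups (default) or at a height; groups are
labelled with roman numerals in decreasing-size order.

Group profiles report each trait's per-group mean ± sample SD together
with a compact letter display from a one-way ANOVA with all-pairs post
hoc comparisons at α = 0.05 (Tukey HSD by default, Fisher's LSD as an
option): groups sharing a letter do not differ significantly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import pdist

from .pca import standardize
from .simulate import TraitMatrix

__all__ = [
    "LinkageTree",
    "GroupProfile",
    "distances",
    "complete_linkage",
    "cut",
    "profile",
    "compact_letter_display",
    "to_newick",
]


def _roman(k: int) -> str:
    numerals = [
        (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"),
        (90, "XC"), (50, "L"), (40, "XL"), (10, "X"), (9, "IX"),
        (5, "V"), (4, "IV"), (1, "I"),
    ]
    out = []
    for value, sym in numerals:
        while k >= value:
            out.append(sym)
            k -= value
    return "".join(out)


def distances(matrix: TraitMatrix | np.ndarray, *, standardized: bool = True) -> np.ndarray:
    """Condensed Euclidean distance matrix between accessions."""
    X = matrix.values if isinstance(matrix, TraitMatrix) else np.asarray(matrix, float)
    if standardized:
        X = standardize(X)
    return pdist(X, metric="euclidean")


@dataclass
class LinkageTree:
    """Agglomerative merge sequence in scipy linkage form."""

    merges: np.ndarray  # (n-1) × 4 scipy linkage matrix
    n_leaves: int

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    @property
    def leaf_order(self) -> list[int]:
        return [int(i) for i in sch.leaves_list(self.merges)]


def complete_linkage(dist: np.ndarray) -> LinkageTree:
    """Complete-linkage agglomeration of a condensed distance matrix."""
    dist = np.asarray(dist, dtype=float)
    Z = sch.linkage(dist, method="complete")
    n = Z.shape[0] + 1
    return LinkageTree(merges=Z, n_leaves=n)


def cut(
    tree: LinkageTree,
    k: int | None = None,
    height: float | None = None,
) -> np.ndarray:
    """Cut the tree into flat groups, labelled by decreasing size.

    Exactly one of ``k`` (number of groups) and ``height`` (cut level)
    must be given.  Returns an array of roman-numeral labels, "I" for the
    largest group.
    """
    if (k is None) == (height is None):
        raise ValueError("give exactly one of k or height")
    if k is not None:
        if not 1 <= k <= tree.n_leaves:
            raise ValueError(f"k={k} out of range 1..{tree.n_leaves}")
        raw = sch.fcluster(tree.merges, t=k, criterion="maxclust")
    else:
        if height < 0:
            raise ValueError("height must be non-negative")
        raw = sch.fcluster(tree.merges, t=height, criterion="distance")
    # relabel in decreasing-size order; ties by first appearance
    ids, counts = np.unique(raw, return_counts=True)
    first_seen = {int(c): int(np.argmax(raw == c)) for c in ids}
    order = sorted(ids, key=lambda c: (-counts[list(ids).index(c)], first_seen[int(c)]))
    mapping = {int(c): _roman(rank + 1) for rank, c in enumerate(order)}
    return np.array([mapping[int(c)] for c in raw], dtype=object)


def compact_letter_display(
    means: dict[str, float], significant: set[frozenset[str]]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``significant`` holds the group pairs that differ at the chosen α.
    Groups sharing at least one letter are exactly the non-significant
    pairs.  Letters are assigned 'a' to the highest-mean group first.
    """
    groups = sorted(means, key=lambda g: -means[g])
    columns: list[set[str]] = [set(groups)]
    for pair in significant:
        a, b = tuple(pair)
        for col in list(columns):
            if a in col and b in col:
                columns.remove(col)
                columns.append(col - {a})
                columns.append(col - {b})
        # absorb columns contained in another
        columns = [
            c for c in columns
            if c and not any(c < other for other in columns if other is not c)
        ]
        # deduplicate
        seen: list[set[str]] = []
        for c in columns:
            if c not in seen:
                seen.append(c)
        columns = seen
    # order columns by the best (highest-mean) member so 'a' lands on top groups
    columns.sort(key=lambda c: min(groups.index(g) for g in c))
    letters = {g: "" for g in groups}
    for j, col in enumerate(columns):
        ch = chr(ord("a") + j)
        for g in groups:
            if g in col:
                letters[g] += ch
    return letters


def _pairwise_significant(
    samples: dict[str, np.ndarray], alpha: float, method: str
) -> set[frozenset[str]]:
    """All-pairs post hoc comparison; returns the significantly different pairs."""
    labels = list(samples)
    sig: set[frozenset[str]] = set()
    if method == "tukey":
        res = sps.tukey_hsd(*[samples[g] for g in labels])
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                if res.pvalue[i, j] < alpha:
                    sig.add(frozenset((labels[i], labels[j])))
    elif method == "lsd":
        # Fisher's LSD: pairwise t on the pooled within-group variance
        ns = {g: len(samples[g]) for g in labels}
        n_total = sum(ns.values())
        df = n_total - len(labels)
        mse = (
            sum((ns[g] - 1) * np.var(samples[g], ddof=1) for g in labels) / df
        )
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                a, b = labels[i], labels[j]
                se = np.sqrt(mse * (1 / ns[a] + 1 / ns[b]))
                t = (np.mean(samples[a]) - np.mean(samples[b])) / se
                p = 2 * sps.t.sf(abs(t), df)
                if p < alpha:
                    sig.add(frozenset((a, b)))
    else:
        raise ValueError(f"unknown post hoc method {method!r}")
    return sig


@dataclass
class GroupProfile:
    """Per-group trait means ± SD with significance letters and group mean D."""

    labels: np.ndarray                  # accession -> group label
    group_order: list[str]              # decreasing size
    table: pd.DataFrame                 # index trait; columns (group, mean/sd/letter)
    anova_p: pd.Series                  # per-trait one-way ANOVA p
    group_mean_d: pd.Series | None      # per-group mean composite D

    def group_sizes(self) -> dict[str, int]:
        return {g: int((self.labels == g).sum()) for g in self.group_order}


def profile(
    matrix: TraitMatrix,
    labels: np.ndarray,
    d_values: np.ndarray | None = None,
    *,
    alpha: float = 0.05,
    posthoc: str = "tukey",
) -> GroupProfile:
    """Per-group trait profile with ANOVA significance letters.

    Groups of size 1 have undefined SD (NaN); any trait whose comparison
    involves such a group skips the letter display with a warning.
    """
    labels = np.asarray(labels, dtype=object)
    if labels.size != matrix.n_accessions:
        raise ValueError("labels must cover all accessions")
    uniq, counts = np.unique(labels, return_counts=True)
    order = [g for g, _c in sorted(zip(uniq, counts), key=lambda t: -t[1])]
    singleton = any(c < 2 for c in counts)
    if singleton:
        warnings.warn(
            "group of size 1: SD undefined and letter display skipped",
            stacklevel=2,
        )

    records: dict[tuple[str, str], list] = {}
    anova_p = {}
    for trait in matrix.trait_names:
        col = matrix.column(trait)
        samples = {g: col[labels == g] for g in order}
        letters: dict[str, str] = {g: "" for g in order}
        pval = np.nan
        if not singleton and len(order) > 1:
            groups_data = [samples[g] for g in order]
            if all(np.ptp(s) == 0 for s in groups_data) and len(
                {s[0] for s in groups_data}
            ) == 1:
                # completely constant trait: no separation anywhere
                pval = 1.0
                letters = {g: "a" for g in order}
            else:
                pval = float(sps.f_oneway(*groups_data).pvalue)
                sig = _pairwise_significant(samples, alpha, posthoc)
                means = {g: float(np.mean(samples[g])) for g in order}
                letters = compact_letter_display(means, sig)
        for g in order:
            s = samples[g]
            records[(trait, g)] = [
                float(np.mean(s)),
                float(np.std(s, ddof=1)) if s.size > 1 else np.nan,
                letters[g],
            ]
        anova_p[trait] = pval

    cols = pd.MultiIndex.from_product([order, ["mean", "sd", "letter"]])
    table = pd.DataFrame(index=pd.Index(matrix.trait_names, name="trait"), columns=cols)
    for (trait, g), (m, s, letter) in records.items():
        table.loc[trait, (g, "mean")] = m
        table.loc[trait, (g, "sd")] = s
        table.loc[trait, (g, "letter")] = letter

    gmd = None
    if d_values is not None:
        d_values = np.asarray(d_values, dtype=float)
        gmd = pd.Series(
            {g: float(d_values[labels == g].mean()) for g in order}, name="mean_D"
        )
    return GroupProfile(
        labels=labels,
        group_order=order,
        table=table,
        anova_p=pd.Series(anova_p, name="anova_p"),
        group_mean_d=gmd,
    )


def to_newick(tree: LinkageTree, leaf_names: list[str] | None = None) -> str:
    """Serialize the dendrogram as a Newick string with branch lengths."""
    n = tree.n_leaves
    if leaf_names is None:
        leaf_names = [f"L{i}" for i in range(n)]
    root, _ = sch.to_tree(tree.merges, rd=True)

    def rec(node) -> str:
        if node.is_leaf():
            return leaf_names[node.id]
        left = rec(node.left)
        right = rec(node.right)
        dl = node.dist - (node.left.dist if not node.left.is_leaf() else 0.0)
        dr = node.dist - (node.right.dist if not node.right.is_leaf() else 0.0)
        return f"({left}:{dl:.6g},{right}:{dr:.6g})"

    return rec(root) + ";"
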