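"""Posterior tree ensembles: clade support, MCC trees, PH85 topology distance.

Ensembles are ordered posterior samples of rooted, typically ultrametric
trees, as produced by Bayesian phylogenetic samplers after thinning. Order is
preserved so that burn-in removal keeps its usual meaning. Clade posterior
probability is assessed on rooted trees (monophyly of a label set); the PH85
topology distance works on unrooted bipartitions, following its published
definition: the size of the symmetric difference of the two trees'
non-trivial bipartition sets, i.e. twice the number of conflicting splits
when both trees are binary.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import dendropy

from .distances import DistanceMatrix, nj_tree
from .errors import EnsembleError, TreeComparisonError
from .stats import hpd

DEFAULT_BURNIN = 0.10
"""Default burn-in fraction removed from posterior samples."""

SUPPORT_THRESHOLD = 0.6
"""Minimum posterior probability treated as support for monophyly."""


@dataclass(frozen=True)
class CladeQuery:
    """A named subset of leaf labels whose monophyly is being scored."""

    name: str
    taxa: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.taxa) < 2:
            raise EnsembleError(f"clade {self.name!r} needs at least 2 taxa")


def leaf_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in tree.leaf_node_iter())


def clade_sets(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Rooted clades: the leaf-label set below each internal node.

    Trivial clades (single leaves and the full leaf set) are excluded.
    """
    all_leaves = leaf_labels(tree)
    clades: set[frozenset[str]] = set()
    below: dict[int, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = frozenset([node.taxon.label])
        else:
            s = frozenset().union(*(below[id(c)] for c in node.child_nodes()))
            below[id(node)] = s
            if 2 <= len(s) < len(all_leaves):
                clades.add(s)
    return clades


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial unrooted bipartitions, canonicalized.

    Each internal edge splits the leaves in two; the split is represented by
    the side that does not contain the lexicographically smallest leaf label,
    so equality between trees over the same leaf set is well defined. A
    polytomy simply contributes fewer splits; no implicit resolution.
    """
    all_leaves = leaf_labels(tree)
    anchor = min(all_leaves)
    splits: set[frozenset[str]] = set()
    below: dict[int, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = frozenset([node.taxon.label])
            continue
        s = frozenset().union(*(below[id(c)] for c in node.child_nodes()))
        below[id(node)] = s
        side = all_leaves - s if anchor in s else s
        if 2 <= len(side) <= len(all_leaves) - 2:
            splits.add(side)
    return splits


def ph85(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """PH85 (Robinson-Foulds symmetric-difference) topology distance."""
    l1, l2 = leaf_labels(t1), leaf_labels(t2)
    if l1 != l2:
        raise TreeComparisonError("trees have different leaf sets")
    return len(bipartitions(t1) ^ bipartitions(t2))


def node_ages(tree: dendropy.Tree) -> dict[frozenset[str], float]:
    """Age (height above the present) of each internal node, keyed by clade.

    Assumes an ultrametric tree; the age of a node is the maximum path length
    from the node down to any of its leaves.
    """
    ages: dict[frozenset[str], float] = {}
    below: dict[int, tuple[frozenset[str], float]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = (frozenset([node.taxon.label]), 0.0)
            continue
        labels = frozenset()
        age = 0.0
        for c in node.child_nodes():
            cl, ca = below[id(c)]
            labels |= cl
            age = max(age, ca + (c.edge.length or 0.0))
        below[id(node)] = (labels, age)
        ages[labels] = age
    return ages


class TreeEnsemble:
    """Ordered posterior sample of trees over a shared taxon set.

    Parameters
    ----------
    trees : sequence of dendropy.Tree
        Samples in chain order (post-thinning).
    posterior : sequence of float, optional
        Per-sample posterior log density, used for credible-set construction.
    log_likelihood : sequence of float, optional
        Per-sample data log likelihood.
    """

    def __init__(
        self,
        trees: Sequence[dendropy.Tree],
        posterior: Sequence[float] | None = None,
        log_likelihood: Sequence[float] | None = None,
    ) -> None:
        if not trees:
            raise EnsembleError("empty tree ensemble")
        ref = leaf_labels(trees[0])
        for i, t in enumerate(trees):
            if leaf_labels(t) != ref:
                raise EnsembleError(f"sample {i} has a different leaf set")
        for name, scalars in (("posterior", posterior),
                              ("log_likelihood", log_likelihood)):
            if scalars is not None and len(scalars) != len(trees):
                raise EnsembleError(f"{name} length does not match sample count")
        self.trees = list(trees)
        self.posterior = list(posterior) if posterior is not None else None
        self.log_likelihood = (
            list(log_likelihood) if log_likelihood is not None else None
        )
        self.taxon_set = ref

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)


def read_trees(path: str | Path, format: str = "nexus_trees") -> TreeEnsemble:
    """Read a posterior tree sample from a newick list or NEXUS trees block.

    NEXUS translate tables are resolved to full labels (the usual BEAST /
    MrBayes dialect).
    """
    schema = {"newick_list": "newick", "nexus_trees": "nexus"}.get(format)
    if schema is None:
        raise EnsembleError(f"unsupported tree format: {format!r}")
    tl = dendropy.TreeList.get(path=str(path), schema=schema)
    if not tl:
        raise EnsembleError(f"no trees found in {path}")
    return TreeEnsemble(list(tl))


def apply_burnin(e: TreeEnsemble, fraction: float = DEFAULT_BURNIN) -> TreeEnsemble:
    """Discard the first ``floor(fraction * n)`` samples."""
    if not 0 <= fraction < 1:
        raise EnsembleError("burn-in fraction must be in [0, 1)")
    cut = int(fraction * len(e))
    if cut >= len(e):
        raise EnsembleError("burn-in removed every sample")
    return TreeEnsemble(
        e.trees[cut:],
        posterior=e.posterior[cut:] if e.posterior is not None else None,
        log_likelihood=(
            e.log_likelihood[cut:] if e.log_likelihood is not None else None
        ),
    )


def clade_pp(e: TreeEnsemble, clade: CladeQuery | frozenset[str]) -> float:
    """Posterior probability that the clade is monophyletic (rooted)."""
    taxa = clade.taxa if isinstance(clade, CladeQuery) else frozenset(clade)
    hits = sum(1 for t in e.trees if taxa in clade_sets(t))
    return hits / len(e)


def mcc_tree(e: TreeEnsemble) -> dendropy.Tree:
    """Maximum-clade-credibility tree with median common-ancestor heights.

    The sampled tree maximizing the product of its clades' posterior
    frequencies is selected (ties broken by earliest sample index); its node
    heights are replaced by the median height of each clade across the
    samples that contain it, so branch lengths are in time units.
    """
    counts: dict[frozenset[str], int] = {}
    ages: dict[frozenset[str], list[float]] = {}
    per_tree: list[set[frozenset[str]]] = []
    for t in e.trees:
        tree_ages = node_ages(t)
        clades = clade_sets(t)
        per_tree.append(clades)
        for c in clades:
            counts[c] = counts.get(c, 0) + 1
            ages.setdefault(c, []).append(tree_ages[c])
        root = leaf_labels(t)
        ages.setdefault(root, []).append(tree_ages[root])

    import math

    n = len(e)
    best_i, best_score = 0, -math.inf
    for i, clades in enumerate(per_tree):
        score = sum(math.log(counts[c] / n) for c in clades)
        if score > best_score:
            best_i, best_score = i, score

    best = e.trees[best_i].clone(depth=1)
    _set_median_heights(best, {c: statistics.median(v) for c, v in ages.items()})
    return best


def _set_median_heights(
    tree: dendropy.Tree, median_age: dict[frozenset[str], float]
) -> None:
    """Re-assign branch lengths from per-clade median ages (leaves at 0)."""
    age_of: dict[int, float] = {}
    below: dict[int, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = frozenset([node.taxon.label])
            age_of[id(node)] = 0.0
            continue
        s = frozenset().union(*(below[id(c)] for c in node.child_nodes()))
        below[id(node)] = s
        age = median_age.get(s, 0.0)
        # Heights must stay monotone root-to-leaf even if medians cross.
        child_max = max(
            age_of[id(c)] for c in node.child_nodes()
        )
        age_of[id(node)] = max(age, child_max)
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = age_of[id(node.parent_node)] - age_of[id(node)]


def credible_set(e: TreeEnsemble, level: float = 0.95) -> TreeEnsemble:
    """Samples whose posterior scalar falls in its HPD interval at ``level``.

    Membership is keyed on the per-sample posterior density scalar, the
    quantity Bayesian samplers log per state; the subset is the usual
    "credible set of trees" a containment test runs against.
    """
    if e.posterior is None:
        raise EnsembleError("credible_set requires per-sample posterior scalars")
    if level >= 1.0:
        return e
    lo, hi = hpd(e.posterior, level)
    keep = [i for i, p in enumerate(e.posterior) if lo <= p <= hi]
    if not keep:
        raise EnsembleError("credible set is empty")
    return TreeEnsemble(
        [e.trees[i] for i in keep],
        posterior=[e.posterior[i] for i in keep],
        log_likelihood=(
            [e.log_likelihood[i] for i in keep]
            if e.log_likelihood is not None
            else None
        ),
    )


def contains_topology(cs: TreeEnsemble, t: dendropy.Tree) -> bool:
    """True iff some sample in ``cs`` has PH85 distance 0 to ``t``."""
    target = bipartitions(t)
    if leaf_labels(cs.trees[0]) != leaf_labels(t):
        raise TreeComparisonError("reference tree has a different leaf set")
    return any(bipartitions(s) == target for s in cs.trees)


def ph85_matrix(
    trees: Sequence[dendropy.Tree], names: Sequence[str]
) -> DistanceMatrix:
    """All-pairs PH85 distances between named trees."""
    import numpy as np

    n = len(trees)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = ph85(trees[i], trees[j])
    return DistanceMatrix(tuple(names), vals, units="PH85")


def tree_distance_dendrogram(
    trees: Sequence[dendropy.Tree], names: Sequence[str]
) -> dendropy.Tree:
    """NJ dendrogram of the PH85 distances between gene/partition trees.

    Leaf labels are the partition names; short branches indicate genes whose
    topologies agree.
    """
    return nj_tree(ph85_matrix(trees, names))
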