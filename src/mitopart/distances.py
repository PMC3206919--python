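"""Pairwise sequence distances, saturation tables and Neighbor-Joining.

Raw p-distances use pairwise deletion: a site is comparable for a pair only
when both sequences show an unambiguous base (A, C, G or T). The JC69
correction d = -(3/4) ln(1 - 4p/3) diverges at p = 3/4; pairs at or past that
point are flagged saturated (NaN) rather than raised, so saturation plots can
show them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import dendropy

from .alignment import Alignment
from .errors import DistanceError

_BASES = frozenset("ACGT")

SATURATED = math.nan
"""Sentinel for a JC69 distance past the p = 3/4 singularity."""


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix with ordered labels."""

    labels: tuple[str, ...]
    values: np.ndarray
    units: str = "substitutions/site"

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise DistanceError("matrix shape does not match labels")
        finite = np.isfinite(self.values)
        if not np.allclose(
            np.where(finite, self.values, 0.0),
            np.where(finite.T, self.values.T, 0.0),
        ):
            raise DistanceError("matrix is not symmetric")

    def value(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def to_phylip(self) -> str:
        """Render as a PHYLIP square matrix."""
        lines = [f" {len(self.labels)}"]
        for i, label in enumerate(self.labels):
            row = " ".join(f"{v:.6f}" for v in self.values[i])
            lines.append(f"{label}  {row}")
        return "\n".join(lines) + "\n"


def _comparable(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ok_a = np.isin(a, list(_BASES))
    ok_b = np.isin(b, list(_BASES))
    return ok_a & ok_b


def p_distance(a: str, b: str) -> float:
    """Uncorrected proportion of differing comparable sites.

    Sites where either sequence has a gap or ambiguity code are excluded
    (pairwise deletion). Raises :class:`DistanceError` when no comparable
    site remains.
    """
    if len(a) != len(b):
        raise DistanceError("sequences differ in length")
    arr_a = np.array(list(a.upper()), dtype="<U1")
    arr_b = np.array(list(b.upper()), dtype="<U1")
    mask = _comparable(arr_a, arr_b)
    n = int(mask.sum())
    if n == 0:
        raise DistanceError("no comparable sites between the pair")
    diffs = int((arr_a[mask] != arr_b[mask]).sum())
    return diffs / n


def jc69_distance(p: float) -> float:
    """Jukes-Cantor corrected distance, or NaN (saturated) for p >= 3/4."""
    if p < 0:
        raise DistanceError("proportion must be nonnegative")
    if p >= 0.75:
        return SATURATED
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


def _encode(mat: np.ndarray) -> np.ndarray:
    """Map characters to codes 0..3 for A,C,G,T and 255 for anything else."""
    codes = np.full(mat.shape, 255, dtype=np.uint8)
    for k, base in enumerate("ACGT"):
        codes[mat == base] = k
    return codes


def distance_matrix(aln: Alignment, model: str = "raw") -> DistanceMatrix:
    """All-pairs distance matrix under ``raw`` (p) or ``JC69``."""
    if model not in {"raw", "JC69"}:
        raise DistanceError(f"unknown distance model: {model!r}")
    if aln.n_taxa < 2:
        raise DistanceError("need at least 2 taxa")
    n = aln.n_taxa
    codes = _encode(aln.matrix)
    ok = codes != 255
    vals = np.zeros((n, n))
    for i in range(n):
        comp = ok[i] & ok[i + 1 :]
        n_comp = comp.sum(axis=1)
        if np.any(n_comp == 0):
            raise DistanceError("a pair has no comparable sites")
        diffs = (comp & (codes[i] != codes[i + 1 :])).sum(axis=1)
        p = diffs / n_comp
        if model == "JC69":
            with np.errstate(invalid="ignore", divide="ignore"):
                p = np.where(p < 0.75, -0.75 * np.log1p(-(4.0 / 3.0) * p),
                             SATURATED)
        vals[i, i + 1 :] = p
        vals[i + 1 :, i] = p
    units = "proportion" if model == "raw" else "substitutions/site"
    return DistanceMatrix(aln.taxon_labels, vals, units)


def saturation_table(aln: Alignment) -> pd.DataFrame:
    """Raw vs JC69-corrected distance per unordered pair.

    Returns a DataFrame with columns ``taxon_i, taxon_j, raw_p, jc69_d,
    saturated``; saturated pairs carry NaN in ``jc69_d``. Plotting corrected
    against raw distances diagnoses multiple-hit saturation: curvature away
    from the 1:1 line means later substitutions overwrite earlier ones.
    """
    if aln.n_taxa < 2:
        raise DistanceError("need at least 2 taxa")
    rows = []
    for i in range(aln.n_taxa):
        for j in range(i + 1, aln.n_taxa):
            p = p_distance(aln.row(i), aln.row(j))
            d = jc69_distance(p)
            rows.append(
                {
                    "taxon_i": aln.taxon_labels[i],
                    "taxon_j": aln.taxon_labels[j],
                    "raw_p": p,
                    "jc69_d": d,
                    "saturated": not math.isfinite(d),
                }
            )
    return pd.DataFrame(rows)


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei Neighbor-Joining on a finite distance matrix.

    Returns an unrooted dendropy tree (the basal node is a trifurcation for
    >= 3 labels). Negative branch-length estimates are clamped to zero. When
    two pairs tie on the Q criterion, the lexicographically smallest label
    pair is merged, which makes the output deterministic.
    """
    n = len(dm.labels)
    if n < 3:
        raise DistanceError("NJ needs at least 3 labels")
    if not np.all(np.isfinite(dm.values)):
        raise DistanceError("NJ input contains saturated/undefined distances")

    taxon_ns = dendropy.TaxonNamespace(list(dm.labels))
    tree = dendropy.Tree(taxon_namespace=taxon_ns)

    # Active nodes keyed by a representative label used for tie-breaking.
    nodes: dict[str, dendropy.Node] = {}
    for label in dm.labels:
        node = dendropy.Node(taxon=taxon_ns.get_taxon(label))
        nodes[label] = node
    d = {
        (a, b): float(dm.values[i, j])
        for i, a in enumerate(dm.labels)
        for j, b in enumerate(dm.labels)
        if i != j
    }

    def dist(a: str, b: str) -> float:
        return d[(a, b)]

    active = sorted(nodes)
    while len(active) > 2:
        m = len(active)
        r = {a: sum(dist(a, b) for b in active if b != a) for a in active}
        best: tuple[float, str, str] | None = None
        for i, a in enumerate(active):
            for b in active[i + 1 :]:
                q = (m - 2) * dist(a, b) - r[a] - r[b]
                key = (q, *sorted((a, b)))
                if best is None or key < best:
                    best = key
        _, a, b = best  # type: ignore[misc]
        dab = dist(a, b)
        la = 0.5 * dab + (r[a] - r[b]) / (2 * (m - 2))
        lb = dab - la
        la, lb = max(la, 0.0), max(lb, 0.0)
        parent = dendropy.Node()
        parent.add_child(nodes[a])
        nodes[a].edge.length = la
        parent.add_child(nodes[b])
        nodes[b].edge.length = lb
        rep = min(a, b)
        other = max(a, b)
        for c in active:
            if c in (a, b):
                continue
            dc = 0.5 * (dist(a, c) + dist(b, c) - dab)
            d[(rep, c)] = d[(c, rep)] = dc
        nodes[rep] = parent
        del nodes[other]
        active = sorted(set(active) - {a, b} | {rep})

    a, b = active
    root = dendropy.Node()
    root.add_child(nodes[a])
    root.add_child(nodes[b])
    half = max(dist(a, b), 0.0) / 2
    nodes[a].edge.length = half
    nodes[b].edge.length = half
    tree.seed_node = root
    tree.is_rooted = False
    tree.update_bipartitions(suppress_unifurcations=True)
    return tree
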