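"""Informative-gene selection over a genes-by-clades support matrix.

Given per-gene posterior probabilities (PP) for a set of reference clades —
the clades the whole mitogenome resolves — the algorithm picks a minimal-ish
gene subset expected to reproduce mitogenome-level support:

1. every gene that is the *only* supporter of some clade is included;
2. remaining uncovered clades are covered greedily by the gene adding the
   most of them, ties broken first by higher PP on the tied clades, then by
   lower coefficient of rate variation (more clock-like genes preferred),
   then lexicographically;
3. the concatenated subset is then re-analyzed and validated: every
   reference clade must come out supported above the threshold.

Support means PP strictly above the threshold (0.6 by default). Greedy set
cover is approximate by design; the report records coverage, not optimality.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import ValidationError

DEFAULT_THRESHOLD = 0.6


@dataclass(frozen=True)
class SupportMatrix:
    """Genes x clades PP table with optional per-gene rate CoV."""

    pp: pd.DataFrame  # index: genes, columns: clades
    cov: pd.Series | None = None  # per-gene coefficient of rate variation

    def __post_init__(self) -> None:
        if ((self.pp < 0) | (self.pp > 1)).any().any():
            raise ValueError("posterior probabilities must be in [0, 1]")
        if self.cov is not None and not self.cov.index.equals(self.pp.index):
            object.__setattr__(
                self, "cov", self.cov.reindex(self.pp.index)
            )

    @property
    def genes(self) -> list[str]:
        return list(self.pp.index)

    @property
    def clades(self) -> list[str]:
        return list(self.pp.columns)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SupportMatrix":
        """Load a CSV with genes in rows, clades in columns.

        A column named ``cov`` is split off as the per-gene coefficient of
        rate variation.
        """
        df = pd.read_csv(path, index_col=0)
        cov = None
        if "cov" in df.columns:
            cov = df["cov"]
            df = df.drop(columns=["cov"])
        return cls(pp=df, cov=cov)

    def to_csv(self, path: str | Path) -> None:
        df = self.pp.copy()
        if self.cov is not None:
            df["cov"] = self.cov
        df.to_csv(path)


@dataclass(frozen=True)
class SelectionStep:
    gene: str
    newly_covered: tuple[str, ...]
    stage: str  # "unique" or "greedy"
    tie_break: str  # "", "pp", "cov" or "name"


@dataclass(frozen=True)
class SelectionReport:
    threshold: float
    unique_supporters: Mapping[str, str]  # clade -> gene
    steps: tuple[SelectionStep, ...]
    selected: frozenset[str]
    covered: frozenset[str]
    uncovered: frozenset[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene": s.gene,
                    "stage": s.stage,
                    "newly_covered": ";".join(s.newly_covered),
                    "tie_break": s.tie_break,
                }
                for s in self.steps
            ]
        )


def supporters(m: SupportMatrix, threshold: float = DEFAULT_THRESHOLD
               ) -> dict[str, set[str]]:
    """Per clade, the genes whose PP is strictly above the threshold."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    return {
        clade: set(m.pp.index[m.pp[clade] > threshold])
        for clade in m.pp.columns
    }


def select_informative(
    m: SupportMatrix, threshold: float = DEFAULT_THRESHOLD
) -> SelectionReport:
    """Run the two-step informative-gene selection (see module docstring)."""
    supp = supporters(m, threshold)
    covered: set[str] = set()
    selected: list[str] = []
    steps: list[SelectionStep] = []

    # Step 1: unique supporters, in clade column order.
    unique: dict[str, str] = {}
    for clade in m.clades:
        genes = supp[clade]
        if len(genes) == 1:
            unique[clade] = next(iter(genes))
    for clade, gene in unique.items():
        if gene in selected:
            continue
        newly = tuple(
            c for c in m.clades if c not in covered and gene in supp[c]
        )
        selected.append(gene)
        covered.update(newly)
        steps.append(SelectionStep(gene, newly, "unique", ""))

    # Step 2: greedy cover of the remaining clades.
    while True:
        uncovered = [c for c in m.clades if c not in covered]
        if not uncovered:
            break
        candidates: list[tuple[str, list[str]]] = []
        for gene in m.genes:
            if gene in selected:
                continue
            gain = [c for c in uncovered if gene in supp[c]]
            if gain:
                candidates.append((gene, gain))
        if not candidates:
            break
        best_gain = max(len(gain) for _, gain in candidates)
        tied = [(g, gain) for g, gain in candidates if len(gain) == best_gain]
        tie_break = ""
        if len(tied) > 1:
            # Higher PP on the clades the gene would newly cover.
            best_pp = max(
                max(m.pp.loc[g, c] for c in gain) for g, gain in tied
            )
            tied = [
                (g, gain)
                for g, gain in tied
                if max(m.pp.loc[g, c] for c in gain) == best_pp
            ]
            tie_break = "pp"
        if len(tied) > 1 and m.cov is not None:
            best_cov = min(float(m.cov[g]) for g, _ in tied)
            tied = [(g, gain) for g, gain in tied
                    if float(m.cov[g]) == best_cov]
            tie_break = "cov"
        if len(tied) > 1:
            tied = [min(tied, key=lambda t: t[0])]
            tie_break = "name"
        gene, gain = tied[0]
        selected.append(gene)
        covered.update(gain)
        steps.append(SelectionStep(gene, tuple(gain), "greedy", tie_break))

    return SelectionReport(
        threshold=threshold,
        unique_supporters=unique,
        steps=tuple(steps),
        selected=frozenset(selected),
        covered=frozenset(covered),
        uncovered=frozenset(c for c in m.clades if c not in covered),
    )


def validate_subset(
    subset_pp: Mapping[str, float],
    clades: Sequence[str],
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[bool, list[str]]:
    """Check a concatenated subset's PPs cover every reference clade.

    Returns ``(passed, failing_clades)``. A clade missing from ``subset_pp``
    raises :class:`ValidationError`.
    """
    missing = [c for c in clades if c not in subset_pp]
    if missing:
        raise ValidationError(f"missing PP for clades: {missing}")
    failing = [c for c in clades if not subset_pp[c] > threshold]
    return (not failing), failing
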