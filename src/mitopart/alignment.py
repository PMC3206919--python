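"""Alignments, gene annotations and partition schemes for circular mitogenomes.

Coordinates are 1-based and inclusive, following the GenBank flat-file
convention for mtDNA. A gene whose ``end`` is smaller than its ``start`` wraps
through the circular origin. Minus-strand genes (ND6 in vertebrate mtDNA) are
reverse-complemented on extraction so that codon positions read 5'->3' on the
coding strand.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import AlignIO

from .errors import (
    AlignmentError,
    AnnotationError,
    ConcatenationError,
    PartitionError,
)

# IUPAC nucleotide complement, gaps preserved.
_COMPLEMENT = str.maketrans(
    "ACGTURYSWKMBDHVN-.?",
    "TGCAAYRSWMKVHDBN-.?",
)

_VALID_CHARS = set("ACGTURYSWKMBDHVN-.?")


@dataclass(frozen=True)
class Alignment:
    """A taxa-by-sites nucleotide character matrix.

    Parameters
    ----------
    taxon_labels : sequence of str
        Unique labels, one per row, in input order.
    matrix : numpy.ndarray
        Array of dtype ``<U1`` with shape ``(n_taxa, n_sites)``; characters are
        upper-case nucleotides, IUPAC ambiguity codes or gaps.
    """

    taxon_labels: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        if len(self.taxon_labels) != len(set(self.taxon_labels)):
            raise AlignmentError("duplicate taxon labels in alignment")
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.taxon_labels):
            raise AlignmentError("matrix shape does not match taxon labels")
        if self.matrix.shape[1] < 1:
            raise AlignmentError("alignment must have at least one site")

    @property
    def n_taxa(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def sequence(self, taxon: str) -> str:
        """Return one row as a string."""
        i = self.taxon_labels.index(taxon)
        return "".join(self.matrix[i])

    def row(self, i: int) -> str:
        return "".join(self.matrix[i])

    @classmethod
    def from_strings(
        cls, labels: Sequence[str], rows: Sequence[str]
    ) -> "Alignment":
        """Build an alignment from equal-length sequence strings."""
        if not rows:
            raise AlignmentError("no sequences supplied")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged rows: lengths {sorted(lengths)}")
        mat = np.array([list(r.upper()) for r in rows], dtype="<U1")
        return cls(tuple(labels), mat)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, label in enumerate(self.taxon_labels):
                fh.write(f">{label}\n{self.row(i)}\n")


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene on the circular genome, 1-based inclusive coordinates."""

    name: str
    start: int
    end: int
    strand: str = "+"
    coding: bool = True
    reading_frame_offset: int = 0

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise AnnotationError(f"{self.name}: coordinates must be >= 1")
        if self.strand not in {"+", "-"}:
            raise AnnotationError(f"{self.name}: strand must be '+' or '-'")
        if self.reading_frame_offset not in {0, 1, 2}:
            raise AnnotationError(f"{self.name}: frame offset must be 0, 1 or 2")

    def sites(self, n_sites: int) -> list[int]:
        """Ordered 1-based site indices covered by the gene.

        Wraps through the origin when ``end < start``. The order follows the
        plus strand; minus-strand genes are reversed at extraction time.
        """
        if self.start > n_sites or self.end > n_sites:
            raise AnnotationError(
                f"{self.name}: [{self.start},{self.end}] outside 1..{n_sites}"
            )
        if self.end >= self.start:
            return list(range(self.start, self.end + 1))
        return list(range(self.start, n_sites + 1)) + list(range(1, self.end + 1))


@dataclass(frozen=True)
class PartitionScheme:
    """Named, ordered blocks of 1-based site indices."""

    name: str
    blocks: tuple[tuple[str, tuple[int, ...]], ...]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise PartitionError("a partition scheme needs at least one block")
        for bname, sites in self.blocks:
            if not sites:
                raise PartitionError(f"block {bname!r} is empty")
            if len(sites) != len(set(sites)):
                raise PartitionError(f"block {bname!r} repeats site indices")

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def block_sizes(self) -> dict[str, int]:
        return {bname: len(sites) for bname, sites in self.blocks}

    def to_raxml(self) -> str:
        """Render as RAxML-style partition text (``DNA, name = 1-957`` lines).

        Runs with a constant stride of 3 are written with the ``\\3`` codon
        suffix.
        """
        lines = []
        for bname, sites in self.blocks:
            lines.append(f"DNA, {bname} = {_compress_runs(sites)}")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class HaplotypeSummary:
    """Result of collapsing identical sequences within one partition."""

    partition_name: str
    n_sequences: int
    n_unique_haplotypes: int
    collapse_map: Mapping[str, int]


def _compress_runs(sites: Sequence[int]) -> str:
    """Compress sorted indices into ``a-b`` / ``a-b\\3`` range expressions."""
    idx = sorted(sites)
    out: list[str] = []
    i = 0
    while i < len(idx):
        # Prefer stride-3 runs when they cover more indices than stride-1.
        best = (idx[i], idx[i], 1, 1)  # start, stop, stride, count
        for stride in (1, 3):
            j = i
            while j + 1 < len(idx) and idx[j + 1] - idx[j] == stride:
                j += 1
            count = j - i + 1
            if count > best[3]:
                best = (idx[i], idx[j], stride, count)
        start, stop, stride, count = best
        if count == 1:
            out.append(str(start))
        elif stride == 1:
            out.append(f"{start}-{stop}")
        else:
            out.append(f"{start}-{stop}\\3")
        i += count
    return ", ".join(out)


def read_alignment(path: str | Path, format: str = "FASTA") -> Alignment:
    """Read a multiple sequence alignment from FASTA or a NEXUS matrix.

    Rows are kept in file order and characters are upper-cased. Ragged rows
    and duplicate taxon labels raise :class:`AlignmentError`.
    """
    fmt = format.strip().lower()
    if fmt not in {"fasta", "nexus"}:
        raise AlignmentError(f"unsupported alignment format: {format!r}")
    try:
        msa = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise AlignmentError(f"could not parse {path}: {exc}") from exc
    labels = [rec.id for rec in msa]
    rows = [str(rec.seq).upper() for rec in msa]
    return Alignment.from_strings(labels, rows)


def read_annotations(path: str | Path) -> list[GeneAnnotation]:
    """Read a 6-column tab-separated gene table.

    Columns: name, start, end, strand, coding (0/1 or true/false), frame.
    Lines starting with ``#`` are comments.
    """
    genes: list[GeneAnnotation] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 6:
            raise AnnotationError(f"expected 6 tab-separated fields: {line!r}")
        name, start, end, strand, coding, frame = parts
        genes.append(
            GeneAnnotation(
                name=name,
                start=int(start),
                end=int(end),
                strand=strand,
                coding=coding.strip().lower() in {"1", "true", "yes", "y"},
                reading_frame_offset=int(frame),
            )
        )
    return genes


def write_annotations(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# name\tstart\tend\tstrand\tcoding\tframe\n")
        for g in genes:
            fh.write(
                f"{g.name}\t{g.start}\t{g.end}\t{g.strand}\t"
                f"{int(g.coding)}\t{g.reading_frame_offset}\n"
            )


def extract_gene(aln: Alignment, gene: GeneAnnotation) -> Alignment:
    """Cut one gene out of the alignment.

    Columns ``start..end`` are taken in order, wrapping through the circular
    origin when ``end < start``. Minus-strand genes are reverse-complemented.
    Sites shared with overlapping neighbours are retained as-is; each gene
    carries its full printed extent.
    """
    sites = gene.sites(aln.n_sites)
    cols = np.array(sites, dtype=int) - 1
    sub = aln.matrix[:, cols]
    if gene.strand == "-":
        rows = ["".join(r)[::-1].translate(_COMPLEMENT) for r in sub]
        return Alignment.from_strings(aln.taxon_labels, rows)
    return Alignment(aln.taxon_labels, sub.copy())


def concatenate(
    parts: Sequence[Alignment], names: Sequence[str]
) -> tuple[Alignment, PartitionScheme]:
    """Concatenate gene alignments column-wise.

    All parts must share an identical taxon set; rows are re-ordered to the
    first part's taxon order. The returned scheme records one contiguous block
    per part in concatenated coordinates.
    """
    if not parts:
        raise ConcatenationError("nothing to concatenate")
    if len(parts) != len(names):
        raise ConcatenationError("one name per part required")
    ref = parts[0].taxon_labels
    ref_set = set(ref)
    for name, p in zip(names, parts):
        if set(p.taxon_labels) != ref_set:
            raise ConcatenationError(
                f"taxon set of part {name!r} does not match the first part"
            )
    pieces = []
    for p in parts:
        order = [p.taxon_labels.index(t) for t in ref]
        pieces.append(p.matrix[order])
    mat = np.concatenate(pieces, axis=1)
    blocks = []
    offset = 0
    for name, p in zip(names, parts):
        blocks.append((name, tuple(range(offset + 1, offset + p.n_sites + 1))))
        offset += p.n_sites
    scheme = PartitionScheme(name="concatenation", blocks=tuple(blocks))
    return Alignment(ref, mat), scheme


def codon_partition(
    aln: Alignment,
    genes: Sequence[GeneAnnotation],
    mode: str,
) -> PartitionScheme:
    """Build a partition scheme over ``aln`` from gene annotations.

    ``mode`` is one of ``unpartitioned``, ``by_gene``, ``by_codon`` (3 blocks
    pooling codon positions across genes) or ``by_gene_and_codon``
    (3 x n_genes blocks). Codon positions are assigned walking each gene's
    sites in reading order starting from its ``reading_frame_offset``;
    terminal incomplete codons are permitted.
    """
    if mode not in {"unpartitioned", "by_gene", "by_codon", "by_gene_and_codon"}:
        raise PartitionError(f"unknown partition mode: {mode!r}")
    if mode in {"by_codon", "by_gene_and_codon"}:
        for g in genes:
            if not g.coding:
                raise PartitionError(
                    f"gene {g.name!r} is non-coding; codon modes need coding genes"
                )

    if mode == "unpartitioned":
        all_sites: list[int] = []
        seen: set[int] = set()
        for g in genes:
            for s in g.sites(aln.n_sites):
                if s not in seen:
                    seen.add(s)
                    all_sites.append(s)
        return PartitionScheme(mode, (("all", tuple(all_sites)),))

    if mode == "by_gene":
        blocks = tuple(
            (g.name, tuple(g.sites(aln.n_sites))) for g in genes
        )
        return PartitionScheme(mode, blocks)

    # Codon position of each site, walking the gene in reading order.
    def positions(g: GeneAnnotation) -> dict[int, list[int]]:
        sites = g.sites(aln.n_sites)
        if g.strand == "-":
            sites = sites[::-1]
        by_pos: dict[int, list[int]] = {1: [], 2: [], 3: []}
        for i, s in enumerate(sites):
            pos = ((i - g.reading_frame_offset) % 3) + 1
            by_pos[pos].append(s)
        return by_pos

    if mode == "by_codon":
        pooled: dict[int, list[int]] = {1: [], 2: [], 3: []}
        for g in genes:
            for pos, sites in positions(g).items():
                pooled[pos].extend(sites)
        blocks = tuple(
            (f"pos{pos}", tuple(pooled[pos])) for pos in (1, 2, 3)
        )
        return PartitionScheme(mode, blocks)

    # by_gene_and_codon
    blocks_list: list[tuple[str, tuple[int, ...]]] = []
    for g in genes:
        by_pos = positions(g)
        for pos in (1, 2, 3):
            blocks_list.append((f"{g.name}_pos{pos}", tuple(by_pos[pos])))
    return PartitionScheme(mode, tuple(blocks_list))


def collapse_haplotypes(
    aln: Alignment, partition_name: str = "alignment"
) -> HaplotypeSummary:
    """Group identical sequences (exact string equality) into haplotypes.

    A gap or ambiguity difference creates a distinct haplotype; no character
    is ignored. Haplotype ids are assigned 1..k in order of first appearance.
    """
    ids: dict[str, int] = {}
    collapse: dict[str, int] = {}
    for i, label in enumerate(aln.taxon_labels):
        seq = aln.row(i)
        if seq not in ids:
            ids[seq] = len(ids) + 1
        collapse[label] = ids[seq]
    return HaplotypeSummary(
        partition_name=partition_name,
        n_sequences=aln.n_taxa,
        n_unique_haplotypes=len(ids),
        collapse_map=collapse,
    )
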