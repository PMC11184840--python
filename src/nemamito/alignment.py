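"""Codon-partitioned alignment handling.

Consumes per-gene nucleotide alignments (produced upstream by an external
aligner), assigns codon positions cyclically from the alignment frame,
concatenates genes into the "PCG-genome" alignment with boundary and
codon-position maps, and computes resolved-site masks.

Masking is codon-granular: a codon containing any gap or ambiguity in a
taxon is masked for that taxon as a whole, so that codon-level statistics
never mix resolved and unresolved positions within one codon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .gencode import INVERTEBRATE_MITO, GeneticCode, genetic_code
from .genomes import PCG_NAMES, read_fasta

#: canonical gene order for concatenation (COX1..ATP6)
GENE_ORDER = PCG_NAMES

_UNAMBIGUOUS = frozenset("ACGT")


@dataclass
class AlignmentBlock:
    """A codon-framed alignment of one gene (or the concatenated PCG-genome)."""

    gene: str
    taxa: list[str]
    rows: list[str]                       # aligned sequences, same order as taxa
    gene_of_column: list[str] = field(default_factory=list)
    missing_taxa: dict[str, list[str]] = field(default_factory=dict)  # gene -> taxa all-gap

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"{self.gene}: ragged alignment rows, lengths {sorted(lengths)}")
        if self.n_columns % 3:
            raise ValueError(f"{self.gene}: alignment length {self.n_columns} not divisible by 3")
        if not self.gene_of_column:
            self.gene_of_column = [self.gene] * self.n_columns

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def codon_position_of_column(self) -> np.ndarray:
        """Codon position (1/2/3) of each column, cycling within each gene segment."""
        out = np.empty(self.n_columns, dtype=int)
        i = 0
        while i < self.n_columns:
            g = self.gene_of_column[i]
            j = i
            while j < self.n_columns and self.gene_of_column[j] == g:
                j += 1
            out[i:j] = np.arange(j - i) % 3 + 1
            i = j
        return out

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def gene_boundaries(self) -> dict[str, tuple[int, int]]:
        """Half-open column span of each gene segment, in order."""
        bounds: dict[str, tuple[int, int]] = {}
        i = 0
        while i < self.n_columns:
            g = self.gene_of_column[i]
            j = i
            while j < self.n_columns and self.gene_of_column[j] == g:
                j += 1
            bounds[g] = (i, j)
            i = j
        return bounds

    def slice_columns(self, start: int, end: int, gene: str | None = None) -> "AlignmentBlock":
        name = gene if gene is not None else self.gene_of_column[start]
        return AlignmentBlock(
            gene=name,
            taxa=list(self.taxa),
            rows=[r[start:end] for r in self.rows],
            gene_of_column=self.gene_of_column[start:end],
        )


def read_alignment(path: str | Path, gene: str | None = None, offset: int = 0) -> AlignmentBlock:
    """Read one aligned FASTA into an :class:`AlignmentBlock`.

    ``offset`` drops leading columns so that the remaining length is a
    multiple of three (the alignment frame is trusted from input).  Raises
    on ragged rows; a length not divisible by 3 raises with a hint to set
    the offset.
    """
    path = Path(path)
    seqs = read_fasta(path)
    if not seqs:
        raise ValueError(f"{path}: empty alignment")
    name = gene if gene is not None else path.stem
    rows = [s[offset:] for s in seqs.values()]
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        raise ValueError(f"{path}: ragged alignment rows, lengths {sorted(lengths)}")
    if lengths.pop() % 3:
        raise ValueError(
            f"{path}: alignment length not divisible by 3 after offset {offset}; "
            "pass a per-gene offset matching the reading frame"
        )
    return AlignmentBlock(gene=name, taxa=list(seqs), rows=rows)


def check_reading_frame(
    block: AlignmentBlock, code: GeneticCode | None = None
) -> dict[str, list[int]]:
    """Internal stop codons per taxon among gap-free codons.

    Returns taxon -> 0-based codon indices of internal stops.  A stop at a
    taxon's last gap-free codon is terminal, not internal.
    """
    code = code or genetic_code(INVERTEBRATE_MITO)
    report: dict[str, list[int]] = {}
    n_codons = block.n_columns // 3
    for taxon, row in zip(block.taxa, block.rows):
        stops = []
        last_clean = -1
        for i in range(n_codons):
            codon = row[3 * i : 3 * i + 3]
            if set(codon) <= _UNAMBIGUOUS:
                last_clean = i
                if code.is_stop(codon):
                    stops.append(i)
        report[taxon] = [i for i in stops if i < last_clean]
    return report


def concatenate(
    blocks: Sequence[AlignmentBlock],
    taxa_order: Sequence[str] | None = None,
    gene_order: Sequence[str] | None = None,
) -> AlignmentBlock:
    """Concatenate per-gene blocks into the PCG-genome alignment.

    Genes are ordered canonically (COX1..ATP6, override via ``gene_order``);
    taxa missing a gene receive an all-gap segment and are recorded in
    ``missing_taxa``.  A taxon present in no block is an error.
    """
    by_gene = {b.gene: b for b in blocks}
    order = [g for g in (gene_order or GENE_ORDER) if g in by_gene]
    order += [b.gene for b in blocks if b.gene not in order]
    all_taxa: list[str] = []
    for b in blocks:
        for t in b.taxa:
            if t not in all_taxa:
                all_taxa.append(t)
    taxa = list(taxa_order) if taxa_order is not None else all_taxa
    for t in taxa:
        if not any(t in b.taxa for b in blocks):
            raise ValueError(f"taxon {t} present in no alignment block")
    parts: dict[str, list[str]] = {t: [] for t in taxa}
    gene_of_column: list[str] = []
    missing: dict[str, list[str]] = {}
    for gene in order:
        block = by_gene[gene]
        gene_of_column.extend([gene] * block.n_columns)
        gap = "-" * block.n_columns
        for t in taxa:
            if t in block.taxa:
                parts[t].append(block.row(t))
            else:
                parts[t].append(gap)
                missing.setdefault(gene, []).append(t)
    return AlignmentBlock(
        gene="PCG-genome",
        taxa=taxa,
        rows=["".join(parts[t]) for t in taxa],
        gene_of_column=gene_of_column,
        missing_taxa=missing,
    )


@dataclass
class SiteMask:
    """Resolved-site flags for an alignment and a taxa subset.

    ``taxon_ok[i, c]`` is True when taxon i's whole codon containing column
    c is unambiguous A/C/G/T; ``resolved`` requires that of every taxon in
    the subset, so resolved implies pairwise-resolved for every pair.
    """

    taxa: list[str]
    taxon_ok: np.ndarray   # (n_taxa, n_columns) bool
    resolved: np.ndarray   # (n_columns,) bool

    def pairwise_resolved(self, a: str, b: str) -> np.ndarray:
        i, j = self.taxa.index(a), self.taxa.index(b)
        return self.taxon_ok[i] & self.taxon_ok[j]

    @property
    def n_resolved(self) -> int:
        return int(self.resolved.sum())


def build_site_mask(block: AlignmentBlock, taxa_subset: Sequence[str] | None = None) -> SiteMask:
    """Codon-granular resolved-site mask for a taxa subset (default: all taxa)."""
    taxa = list(taxa_subset) if taxa_subset is not None else list(block.taxa)
    if not taxa:
        raise ValueError("empty taxa subset")
    n_cols = block.n_columns
    acgt = np.frombuffer(b"ACGT", dtype=np.uint8)
    char_ok = np.zeros((len(taxa), n_cols), dtype=bool)
    for i, t in enumerate(taxa):
        char_ok[i] = np.isin(np.frombuffer(block.row(t).encode(), dtype=np.uint8), acgt)
    codon_ok = char_ok.reshape(len(taxa), n_cols // 3, 3).all(axis=2)
    taxon_ok = np.repeat(codon_ok, 3, axis=1)
    return SiteMask(taxa=taxa, taxon_ok=taxon_ok, resolved=taxon_ok.all(axis=0))


def write_concatenated(
    block: AlignmentBlock, fasta_path: str | Path, partition_path: str | Path
) -> None:
    """Write the concatenated alignment plus its partition table.

    The partition table is a TSV (gene, start, end; 1-based inclusive
    columns) followed in a sibling ``.raxml.txt`` file by RAxML-style
    partition lines for interoperability.
    """
    fasta_path, partition_path = Path(fasta_path), Path(partition_path)
    with open(fasta_path, "w") as fh:
        for taxon, row in zip(block.taxa, block.rows):
            fh.write(f">{taxon}\n{row}\n")
    bounds = block.gene_boundaries()
    with open(partition_path, "w") as fh:
        fh.write("gene\tstart\tend\n")
        for gene, (s, e) in bounds.items():
            fh.write(f"{gene}\t{s + 1}\t{e}\n")
    raxml = partition_path.with_suffix(".raxml.txt")
    with open(raxml, "w") as fh:
        for gene, (s, e) in bounds.items():
            fh.write(f"DNA, {gene} = {s + 1}-{e}\n")
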