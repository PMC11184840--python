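"""Composition statistics: lengths, %GC/%AT, and strand skews.

GC skew = (G - C)/(G + C) and AT skew = (A - T)/(A + T), computed on a
designated strand: the stored (COX1-oriented) strand for whole genomes and
the coding strand for genes.  Positive GC skew marks guanine excess, the
signature this family of genomes shows most strongly at third codon
positions.  Only unambiguous A/C/G/T count; IUPAC ambiguity codes and gaps
are excluded from numerator and denominator alike, and a zero denominator
yields ``None`` (an explicitly undefined value, excluded from summaries with
an exclusion count) rather than a silent NaN.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genomes import CodingSequence, Mitogenome


def _counts(seq: str) -> Counter:
    return Counter(seq.upper())


def gc_skew(seq: str) -> float | None:
    """(G - C)/(G + C) over unambiguous bases; None when no G or C."""
    c = _counts(seq)
    denom = c["G"] + c["C"]
    if denom == 0:
        return None
    return (c["G"] - c["C"]) / denom


def at_skew(seq: str) -> float | None:
    """(A - T)/(A + T) over unambiguous bases; None when no A or T."""
    c = _counts(seq)
    denom = c["A"] + c["T"]
    if denom == 0:
        return None
    return (c["A"] - c["T"]) / denom


def pct_gc(seq: str) -> float | None:
    """Percent G+C among unambiguous A/C/G/T; None on empty input."""
    c = _counts(seq)
    denom = c["A"] + c["C"] + c["G"] + c["T"]
    if denom == 0:
        return None
    return 100.0 * (c["G"] + c["C"]) / denom


def codon_position_subsequence(nt: str, position: int) -> str:
    """Every third nucleotide of a frame-trimmed cds, starting at a codon position (1-3)."""
    if position not in (1, 2, 3):
        raise ValueError(f"codon position must be 1, 2 or 3, got {position}")
    return nt[position - 1 :: 3]


def codon_position_skew(cds: CodingSequence | str, position: int) -> float | None:
    """GC skew of one codon position of a frame-trimmed coding sequence."""
    nt = cds.nt if isinstance(cds, CodingSequence) else cds
    return gc_skew(codon_position_subsequence(nt, position))


@dataclass
class CompositionRecord:
    """All composition metrics for one genome, at every resolution."""

    species_id: str
    genome_length: int
    pcg_total_length: int
    pcg_proportion: float
    genome_pct_gc: float | None
    pcg_pct_gc: float | None
    genome_gc_skew: float | None
    genome_at_skew: float | None
    pcg_gc_skew: float | None
    pcg_at_skew: float | None
    per_gene: dict[str, tuple[int, float | None, float | None, float | None]] = field(
        default_factory=dict
    )  # gene -> (length, pct_gc, gc_skew, at_skew)
    per_codon_position: dict[tuple[str, int], float | None] = field(default_factory=dict)

    #: metrics exposed to group summaries and trait tests
    SCALAR_METRICS = (
        "genome_length", "pcg_total_length", "pcg_proportion",
        "genome_pct_gc", "pcg_pct_gc",
        "genome_gc_skew", "genome_at_skew", "pcg_gc_skew", "pcg_at_skew",
    )


def genome_summary(genome: Mitogenome, cdss: Sequence[CodingSequence]) -> CompositionRecord:
    """Compute the full composition record for one genome.

    Genome-level metrics are computed on the full stored strand (including
    rRNA/tRNA and noncoding regions); per-gene and codon-position metrics on
    the coding strand of each extracted PCG.
    """
    if not cdss:
        raise ValueError(f"{genome.id}: no PCGs extracted, cannot summarize")
    pcg_concat = "".join(c.nt for c in cdss)
    per_gene = {}
    per_pos = {}
    for cds in cdss:
        per_gene[cds.gene] = (
            len(cds.nt), pct_gc(cds.nt), gc_skew(cds.nt), at_skew(cds.nt)
        )
        for pos in (1, 2, 3):
            per_pos[(cds.gene, pos)] = codon_position_skew(cds, pos)
    total = sum(len(c.nt) for c in cdss)
    return CompositionRecord(
        species_id=genome.id,
        genome_length=len(genome.sequence),
        pcg_total_length=total,
        pcg_proportion=total / len(genome.sequence),
        genome_pct_gc=pct_gc(genome.sequence),
        pcg_pct_gc=pct_gc(pcg_concat),
        genome_gc_skew=gc_skew(genome.sequence),
        genome_at_skew=at_skew(genome.sequence),
        pcg_gc_skew=gc_skew(pcg_concat),
        pcg_at_skew=at_skew(pcg_concat),
        per_gene=per_gene,
        per_codon_position=per_pos,
    )


@dataclass(frozen=True)
class MetricSummary:
    n: int
    mean: float
    stdev: float | None  # None for single-member groups
    min: float
    max: float
    n_excluded: int      # undefined / missing values dropped


@dataclass
class CladeSummary:
    group: str
    metrics: dict[str, MetricSummary]


def clade_summary(
    records: Iterable[CompositionRecord],
    labels: Mapping[str, str | None],
    metrics: Sequence[str] = CompositionRecord.SCALAR_METRICS,
) -> list[CladeSummary]:
    """Per-group summary statistics (n, mean, sample stdev, min, max).

    ``labels`` maps species_id to a group label; species with a missing
    label, and undefined metric values, are excluded and counted.  Groups
    empty after exclusion are omitted.
    """
    groups: dict[str, list[CompositionRecord]] = {}
    for rec in records:
        label = labels.get(rec.species_id)
        if label is None:
            continue
        groups.setdefault(label, []).append(rec)
    out = []
    for label in sorted(groups):
        summaries = {}
        for metric in metrics:
            values = [getattr(r, metric) for r in groups[label]]
            kept = [v for v in values if v is not None]
            if not kept:
                continue
            n = len(kept)
            mean = sum(kept) / n
            stdev = (
                math.sqrt(sum((v - mean) ** 2 for v in kept) / (n - 1))
                if n > 1
                else None
            )
            summaries[metric] = MetricSummary(
                n=n, mean=mean, stdev=stdev, min=min(kept), max=max(kept),
                n_excluded=len(values) - n,
            )
        if summaries:
            out.append(CladeSummary(group=label, metrics=summaries))
    return out


def composition_table(
    records: Sequence[CompositionRecord], order: Sequence[str] | None = None
) -> pd.DataFrame:
    """Wide species x metric table (one row per genome)."""
    rows = []
    for rec in records:
        row: dict[str, object] = {"species_id": rec.species_id}
        for metric in CompositionRecord.SCALAR_METRICS:
            row[metric] = getattr(rec, metric)
        for gene, (length, gc, gsk, ask) in sorted(rec.per_gene.items()):
            row[f"{gene}_length"] = length
            row[f"{gene}_pct_gc"] = gc
            row[f"{gene}_gc_skew"] = gsk
            row[f"{gene}_at_skew"] = ask
        rows.append(row)
    df = pd.DataFrame(rows).set_index("species_id")
    if order is not None:
        df = df.reindex([s for s in order if s in df.index])
    return df


def codon_skew_matrix(
    records: Sequence[CompositionRecord], order: Sequence[str] | None = None
) -> pd.DataFrame:
    """Heatmap-ready species x (gene, codon position) GC-skew matrix."""
    rows = []
    for rec in records:
        row: dict[str, object] = {"species_id": rec.species_id}
        for (gene, pos), skew in sorted(rec.per_codon_position.items()):
            row[f"{gene}_pos{pos}"] = skew
        rows.append(row)
    df = pd.DataFrame(rows).set_index("species_id")
    if order is not None:
        df = df.reindex([s for s in order if s in df.index])
    return df
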