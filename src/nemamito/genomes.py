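"""Reading and normalizing annotated mitochondrial genomes.

Parses GenBank flat files into :class:`Mitogenome` records, reconciles the
heterogeneous gene names found in public annotations onto the 12 protein
coding genes (PCGs) shared by nematode mitogenomes, extracts in-frame coding
sequences with correct strand and reading frame, checks genome completeness
(12 PCGs + 22 tRNAs + 2 rRNAs + circularity) and rotates circular genomes to
the conventional COX1-first orientation.

All coordinates are 0-based half-open on the stored strand; GenBank's
1-based inclusive convention is converted at the parsing boundary.  A gene
spanning the circular origin is stored with ``wraps_origin=True`` and
``end < start``; its genomic slice is ``seq[start:] + seq[:end]``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .gencode import INVERTEBRATE_MITO, GeneticCode, genetic_code, reverse_complement

#: the 12 mitochondrial protein-coding genes shared across Nematoda
PCG_NAMES = (
    "COX1", "COX2", "COX3", "CYTB",
    "NAD1", "NAD2", "NAD3", "NAD4", "NAD4L", "NAD5", "NAD6",
    "ATP6",
)

TAXONOMY_RANKS = (
    "class", "subclass", "order", "suborder",
    "infraorder", "superfamily", "family", "genus",
)

TRAIT_NAMES = ("feeding_habit", "habitat", "reproduction")

#: values treated as missing in trait tables
MISSING_TOKENS = frozenset({"", "NA", "N/A", "NaN", "nan", "None", "."})


class GenomeParseError(ValueError):
    """Raised for malformed GenBank records or inconsistent annotations."""


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature on a mitogenome."""

    raw_name: str
    norm_name: str          # PCG name, or TRNA / RRNA / OTHER
    start: int              # 0-based, on the stored strand
    end: int                # half-open; < start only when wraps_origin
    strand: str             # '+' or '-'
    frame_offset: int = 0   # GenBank codon_start - 1
    wraps_origin: bool = False

    def length(self, genome_length: int) -> int:
        if self.wraps_origin:
            return genome_length - self.start + self.end
        return self.end - self.start


@dataclass
class Mitogenome:
    """An annotated (usually circular) mitochondrial genome."""

    id: str
    sequence: str
    is_circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)
    taxonomy: dict[str, str | None] = field(default_factory=dict)
    traits: dict[str, str | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise GenomeParseError(f"{self.id}: empty sequence")

    def pcg_features(self) -> list[GeneFeature]:
        return [f for f in self.features if f.norm_name in PCG_NAMES]


@dataclass(frozen=True)
class CodingSequence:
    """Frame-trimmed coding-strand nucleotide sequence for one PCG."""

    species_id: str
    gene: str
    nt: str
    source_strand: str
    has_internal_stop: bool

    @property
    def n_codons(self) -> int:
        return len(self.nt) // 3


@dataclass(frozen=True)
class CompletenessReport:
    n_pcgs: int
    n_trnas: int
    n_rrnas: int
    circularized: bool

    @property
    def is_complete(self) -> bool:
        return (
            self.n_pcgs == 12
            and self.n_trnas == 22
            and self.n_rrnas == 2
            and self.circularized
        )


def _load_synonym_table() -> dict[str, str]:
    table: dict[str, str] = {}
    text = resources.files("nemamito.data").joinpath("gene_synonyms.tsv").read_text()
    reader = csv.reader(
        (line for line in text.splitlines() if line and not line.startswith("#")),
        delimiter="\t",
    )
    header = next(reader)
    if header != ["synonym", "normalized"]:
        raise GenomeParseError("gene_synonyms.tsv: unexpected header")
    for syn, norm in reader:
        table[syn] = norm
    return table


_SYNONYMS = _load_synonym_table()
_STRIP = str.maketrans("", "", " -_.")


def normalize_gene_name(raw: str, extra: Mapping[str, str] | None = None) -> str:
    """Map an annotated gene name onto a canonical PCG name.

    Matching is case-insensitive and ignores spaces, hyphens, underscores and
    dots; unmatched names map to ``"OTHER"``.  ``extra`` supplies
    user-provided synonyms (same keying rules) that take precedence.
    """
    key = raw.strip().lower().translate(_STRIP)
    if extra:
        cleaned = {k.strip().lower().translate(_STRIP): v for k, v in extra.items()}
        if key in cleaned:
            return cleaned[key]
    return _SYNONYMS.get(key, "OTHER")


def _feature_name(feat) -> str:
    for qual in ("gene", "product", "label", "note"):
        if qual in feat.qualifiers:
            return str(feat.qualifiers[qual][0])
    return feat.type


def _convert_location(feat, genome_length: int, record_id: str) -> tuple[int, int, str, bool]:
    """Convert a Biopython location to (start, end, strand, wraps_origin)."""
    parts = sorted(feat.location.parts, key=lambda p: int(p.start))
    strand = "-" if feat.location.strand == -1 else "+"
    if len(parts) == 1:
        return int(parts[0].start), int(parts[0].end), strand, False
    if (
        len(parts) == 2
        and int(parts[0].start) == 0
        and int(parts[1].end) == genome_length
    ):
        # join(a..L, 1..b): spans the circular origin
        return int(parts[1].start), int(parts[0].end), strand, True
    raise GenomeParseError(
        f"{record_id}: unsupported compound location {feat.location}"
    )


def read_genbank(path: str | Path, synonyms: Mapping[str, str] | None = None) -> list[Mitogenome]:
    """Read a GenBank flat file into a list of :class:`Mitogenome`.

    Raises :class:`GenomeParseError` naming the offending record when a
    sequence is absent or a feature location cannot be interpreted.
    """
    genomes: list[Mitogenome] = []
    for record in SeqIO.parse(str(path), "genbank"):
        seq = str(record.seq).upper()
        if not seq:
            raise GenomeParseError(f"{record.id}: record has no sequence")
        circular = record.annotations.get("topology", "") == "circular"
        features: list[GeneFeature] = []
        for feat in record.features:
            if feat.type not in ("CDS", "tRNA", "rRNA"):
                continue
            raw = _feature_name(feat)
            if feat.type == "CDS":
                norm = normalize_gene_name(raw, synonyms)
            elif feat.type == "tRNA":
                norm = "TRNA"
            else:
                norm = "RRNA"
            start, end, strand, wraps = _convert_location(feat, len(seq), record.id)
            offset = int(feat.qualifiers.get("codon_start", ["1"])[0]) - 1
            if not 0 <= offset < 3:
                raise GenomeParseError(f"{record.id}: codon_start {offset + 1} out of range")
            features.append(
                GeneFeature(raw, norm, start, end, strand, offset, wraps)
            )
        genomes.append(
            Mitogenome(
                id=record.id,
                sequence=seq,
                is_circular=circular,
                features=features,
            )
        )
    return genomes


def feature_slice(genome: Mitogenome, feat: GeneFeature) -> str:
    """Genomic nucleotides of a feature on the stored strand, origin-aware."""
    if feat.wraps_origin:
        return genome.sequence[feat.start :] + genome.sequence[: feat.end]
    return genome.sequence[feat.start : feat.end]


def extract_pcgs(
    genome: Mitogenome, code: GeneticCode | None = None
) -> list[CodingSequence]:
    """Extract frame-trimmed coding sequences for every annotated PCG.

    Minus-strand genes are reverse complemented onto the coding strand; the
    ``codon_start`` offset is dropped and any trailing partial codon is
    truncated (incomplete stops completed by polyadenylation are not padded).
    Internal stops are flagged by translation under the genetic code
    (default: invertebrate mitochondrial).
    """
    code = code or genetic_code(INVERTEBRATE_MITO)
    seen: dict[str, GeneFeature] = {}
    out: list[CodingSequence] = []
    for feat in genome.pcg_features():
        if feat.norm_name in seen:
            raise GenomeParseError(
                f"{genome.id}: duplicate annotation for {feat.norm_name}: "
                f"{seen[feat.norm_name]} and {feat}"
            )
        seen[feat.norm_name] = feat
        nt = feature_slice(genome, feat)
        if feat.strand == "-":
            nt = reverse_complement(nt)
        nt = nt[feat.frame_offset :]
        nt = nt[: len(nt) - len(nt) % 3]
        n_codons = len(nt) // 3
        if n_codons < 2:
            raise GenomeParseError(
                f"{genome.id}: {feat.norm_name} shorter than 2 codons after trimming"
            )
        internal = any(
            code.is_stop(nt[i : i + 3]) for i in range(0, 3 * (n_codons - 1), 3)
        )
        out.append(
            CodingSequence(
                species_id=genome.id,
                gene=feat.norm_name,
                nt=nt,
                source_strand=feat.strand,
                has_internal_stop=internal,
            )
        )
    return out


def validate_completeness(genome: Mitogenome) -> CompletenessReport:
    """Count PCGs/tRNAs/rRNAs and report assembly completeness."""
    pcgs = {f.norm_name for f in genome.pcg_features()}
    return CompletenessReport(
        n_pcgs=len(pcgs),
        n_trnas=sum(1 for f in genome.features if f.norm_name == "TRNA"),
        n_rrnas=sum(1 for f in genome.features if f.norm_name == "RRNA"),
        circularized=genome.is_circular,
    )


def _remap_after_revcomp(feat: GeneFeature, L: int) -> GeneFeature:
    length = feat.length(L)
    new_start = (L - feat.start - length) % L
    wraps = new_start + length > L
    new_end = new_start + length - L if wraps else new_start + length
    return replace(
        feat,
        start=new_start,
        end=new_end,
        strand="-" if feat.strand == "+" else "+",
        wraps_origin=wraps,
    )


def _remap_after_rotation(feat: GeneFeature, r: int, L: int) -> GeneFeature:
    length = feat.length(L)
    new_start = (feat.start - r) % L
    wraps = new_start + length > L
    new_end = new_start + length - L if wraps else new_start + length
    return replace(feat, start=new_start, end=new_end, wraps_origin=wraps)


def orient_to_cox1(genome: Mitogenome) -> Mitogenome:
    """Rotate a circular genome so COX1 starts at position 0 on the + strand.

    The whole genome is reverse complemented first when COX1 is annotated on
    the minus strand.  Composition metrics are unchanged by rotation (and
    sign-flipped by the strand flip, which is applied to every feature
    consistently).  Idempotent: a COX1-first genome is returned unchanged.
    """
    if not genome.is_circular:
        raise GenomeParseError(
            f"{genome.id}: refusing to rotate a non-circular genome"
        )
    cox1 = [f for f in genome.features if f.norm_name == "COX1"]
    if not cox1:
        raise GenomeParseError(f"{genome.id}: no COX1 feature to orient to")
    feat = cox1[0]
    seq = genome.sequence
    feats = list(genome.features)
    L = len(seq)
    if feat.strand == "-":
        seq = reverse_complement(seq)
        feats = [_remap_after_revcomp(f, L) for f in feats]
        feat = next(f for f in feats if f.norm_name == "COX1")
    r = feat.start
    if r == 0 and seq == genome.sequence:
        return genome
    seq = seq[r:] + seq[:r]
    feats = [_remap_after_rotation(f, r, L) for f in feats]
    return Mitogenome(
        id=genome.id,
        sequence=seq,
        is_circular=True,
        features=feats,
        taxonomy=dict(genome.taxonomy),
        traits=dict(genome.traits),
    )


def read_trait_table(path: str | Path) -> dict[str, tuple[dict, dict]]:
    """Read the species -> taxonomy + life-trait TSV.

    Expected columns: ``species_id``, the eight taxonomy ranks coarse to fine
    (class .. genus) and the three traits (feeding_habit, habitat,
    reproduction).  Missing cells come back as ``None``, never as an empty
    category.  Duplicate species or an absent required column raise.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ("species_id",) + TAXONOMY_RANKS + TRAIT_NAMES
    for col in required:
        if col not in df.columns:
            raise ValueError(f"trait table {path}: missing required column '{col}'")
    dupes = df["species_id"][df["species_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"trait table {path}: duplicated species {dupes}")

    def clean(value: str) -> str | None:
        return None if value.strip() in MISSING_TOKENS else value.strip()

    out: dict[str, tuple[dict, dict]] = {}
    for _, row in df.iterrows():
        taxonomy = {rank: clean(row[rank]) for rank in TAXONOMY_RANKS}
        traits = {trait: clean(row[trait]) for trait in TRAIT_NAMES}
        out[row["species_id"]] = (taxonomy, traits)
    return out


def attach_traits(
    genomes: Iterable[Mitogenome], table: Mapping[str, tuple[dict, dict]]
) -> None:
    """Attach taxonomy and trait labels from a trait table, in place."""
    for g in genomes:
        if g.id in table:
            taxonomy, traits = table[g.id]
            g.taxonomy = dict(taxonomy)
            g.traits = dict(traits)


def write_gene_fastas(cdss: Iterable[CodingSequence], outdir: str | Path) -> list[Path]:
    """Write per-gene multi-species FASTA files named ``GENE.fasta``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_gene: dict[str, list[CodingSequence]] = {}
    for cds in cdss:
        by_gene.setdefault(cds.gene, []).append(cds)
    paths = []
    for gene in sorted(by_gene):
        path = outdir / f"{gene}.fasta"
        with open(path, "w") as fh:
            for cds in by_gene[gene]:
                fh.write(f">{cds.species_id}\n{cds.nt}\n")
        paths.append(path)
    return paths


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` map."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
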