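"""Synthetic mitogenome datasets with known ground truth.

Generates everything the pipeline consumes: annotated circular genomes with
prescribed %GC and codon-position GC skews (12 PCGs, 22 tRNA and 2 rRNA
placeholder features, noncoding spacers), per-gene codon alignments
diverged from a shared root at prescribed dN/dS, a five-member outgroup
panel at deeper divergence, trait tables with planted effects, a Newick
display tree, and a machine-readable ground-truth sidecar.

Codon sampling solves a 62-codon frequency vector whose stop-conditioned
marginals hit the composition targets exactly in expectation (a fixed-point
adjustment absorbs the shift that conditioning on stop-free codons would
otherwise introduce).  Divergence is a per-codon Gillespie simulation:
single-nucleotide proposals weighted kappa-fold for transitions, stop
proposals rejected, non-synonymous proposals accepted with probability
omega; every accepted event is logged as synonymous or non-synonymous.

Default study conditions: 20 species over four clades, gene lengths
approximating the 12 nematode mitochondrial PCGs (about 10.2 kb of coding
sequence in a roughly 14.5 kb genome), 25% GC with a strong third-position
G skew, shallow ingroup and deep outgroup divergence, purifying omega
throughout, and trait effects planted on both composition (third-position
skew shifts for parasites) and rates (feeding-habit-specific omega).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .gencode import (
    INVERTEBRATE_MITO,
    GeneticCode,
    codon_neighbors,
    genetic_code,
    reverse_complement,
)
from .genomes import PCG_NAMES

NUCS = "ACGT"

#: approximate codon counts of the 12 nematode mitochondrial PCGs
DEFAULT_GENE_LENGTHS: dict[str, int] = {
    "COX1": 520, "COX2": 230, "COX3": 260, "CYTB": 370,
    "NAD1": 290, "NAD2": 280, "NAD3": 115, "NAD4": 410,
    "NAD4L": 80, "NAD5": 520, "NAD6": 140, "ATP6": 200,
}

OUTGROUP_IDS = (
    "Hypsibius_dujardini",
    "Ramazzottius_varieornatus",
    "Limulus_polyphemus",
    "Anopheles_gambiae",
    "Lithobius_forficatus",
)

CLADES = ("Enoplea", "Tylenchina", "Rhabditina", "Spirurina")

_FEEDING_BY_CLADE = {
    "Enoplea": (("animal_parasite", 0.4), ("omnivore", 0.3), ("predator", 0.3)),
    "Tylenchina": (("plant_parasite", 0.5), ("fungivore", 0.25), ("bacterivore", 0.25)),
    "Rhabditina": (("bacterivore", 0.6), ("animal_parasite", 0.4)),
    # entirely animal-parasitic and amphimictic: exercises skipped blocks
    "Spirurina": (("animal_parasite", 1.0),),
}
_HABITATS = (
    ("terrestrial", 0.5), ("freshwater", 0.15), ("marine", 0.1),
    ("animal_associated", 0.15), ("insect_associated", 0.1),
)
_REPRODUCTION = (("amphimictic", 0.6), ("parthenogenetic", 0.3), ("hermaphroditic", 0.1))


@dataclass
class SyntheticConfig:
    """All knobs of the generator; the defaults are the study conditions."""

    seed: int
    n_species: int = 20
    clades: tuple[str, ...] = CLADES
    gene_lengths: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GENE_LENGTHS))
    target_gc: float = 0.25
    target_pos_skews: tuple[float, float, float] = (0.25, -0.05, 0.40)
    noncoding_fraction: float = 0.30
    ingroup_divergence: float = 0.05   # expected fraction of sites changed from root
    outgroup_divergence: float = 0.15
    kappa: float = 2.0
    omega_by_feeding: dict[str, float] = field(
        default_factory=lambda: {
            "animal_parasite": 0.05, "plant_parasite": 0.08,
            "bacterivore": 0.15, "fungivore": 0.12,
            "omnivore": 0.20, "predator": 0.20,
        }
    )
    omega_outgroup: float = 0.10
    skew_shift_by_feeding: dict[str, float] = field(
        default_factory=lambda: {"animal_parasite": -0.35, "plant_parasite": 0.12}
    )
    minus_strand_prob: float = 0.25
    wrap_last_gene: bool = False
    table_id: int = INVERTEBRATE_MITO

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for g, n in self.gene_lengths.items():
            if n < 2:
                raise ValueError(f"{g}: gene length must be >= 2 codons")
        if not 0 <= self.noncoding_fraction < 1:
            raise ValueError("noncoding_fraction must be in [0, 1)")


# ---------------------------------------------------------------------------
# codon-frequency solver and sampling

class InfeasibleTargets(ValueError):
    """Composition targets unreachable by the stop-free codon alphabet."""


def _position_dists(gc: list[float], skews: list[float]) -> list[dict[str, float]]:
    out = []
    for g, s in zip(gc, skews):
        out.append({
            "G": g * (1 + s) / 2, "C": g * (1 - s) / 2,
            "A": (1 - g) / 2, "T": (1 - g) / 2,
        })
    return out


def solve_codon_distribution(
    code: GeneticCode,
    target_gc: float,
    target_pos_skews: tuple[float, float, float],
    tol: float = 1e-9,
    max_iter: int = 500,
) -> tuple[list[str], np.ndarray]:
    """Stop-free codon frequencies matching GC and per-position skew targets.

    Solves per-position nucleotide parameters by fixed-point iteration so
    that the *stop-conditioned* codon distribution has exactly the target
    expected GC content and per-position GC skews.  Raises
    :class:`InfeasibleTargets`, reporting the nearest feasible point, when
    the iteration cannot close the gap.
    """
    if not 0 < target_gc < 1:
        raise InfeasibleTargets(f"target GC {target_gc} outside (0, 1)")
    for s in target_pos_skews:
        if not -1 <= s <= 1:
            raise InfeasibleTargets(f"target skew {s} outside [-1, 1]")
    sense = list(code.sense_codons)
    gc = [target_gc] * 3
    sk = [min(0.999, max(-0.999, s)) for s in target_pos_skews]
    realized_gc, realized_sk = target_gc, list(target_pos_skews)
    probs = np.ones(len(sense)) / len(sense)
    for _ in range(max_iter):
        q = _position_dists(gc, sk)
        probs = np.array(
            [q[0][c[0]] * q[1][c[1]] * q[2][c[2]] for c in sense]
        )
        total = probs.sum()
        if total <= 0:
            raise InfeasibleTargets("all probability mass on stop codons")
        probs /= total
        marg = [
            {b: sum(p for c, p in zip(sense, probs) if c[pos] == b) for b in NUCS}
            for pos in range(3)
        ]
        realized_sk = []
        gcs = []
        for pos in range(3):
            g, c = marg[pos]["G"], marg[pos]["C"]
            gcs.append(g + c)
            realized_sk.append((g - c) / (g + c) if g + c > 0 else 0.0)
        realized_gc = sum(gcs) / 3
        err = abs(realized_gc - target_gc) + sum(
            abs(a - b) for a, b in zip(realized_sk, target_pos_skews)
        )
        if err < tol:
            break
        for pos in range(3):
            sk[pos] = min(0.999999, max(-0.999999, sk[pos] + (target_pos_skews[pos] - realized_sk[pos])))
            gc[pos] = min(0.99, max(0.01, gc[pos] + (target_gc - gcs[pos])))
    else:
        if err > 1e-3:
            raise InfeasibleTargets(
                f"targets gc={target_gc}, skews={target_pos_skews} infeasible; "
                f"nearest feasible gc={realized_gc:.4f}, skews="
                f"{[round(s, 4) for s in realized_sk]}"
            )
    return sense, probs


def sample_codon_sequence(
    n_codons: int,
    code: GeneticCode,
    target_gc: float,
    target_pos_skews: tuple[float, float, float],
    rng: np.random.Generator,
) -> str:
    """Sample a stop-free codon sequence hitting composition targets in expectation."""
    if n_codons < 2:
        raise ValueError("need at least 2 codons")
    sense, probs = solve_codon_distribution(code, target_gc, target_pos_skews)
    cum = np.cumsum(probs)
    cum[-1] = 1.0
    idx = np.searchsorted(cum, rng.random(n_codons))
    return "".join(sense[i] for i in idx)


# ---------------------------------------------------------------------------
# codon-level Gillespie divergence

@lru_cache(maxsize=64)
def _rate_table(table_id: int, omega: float, kappa: float):
    code = genetic_code(table_id)
    nbrs = codon_neighbors(table_id)
    table = {}
    for codon in code.sense_codons:
        entries = []
        tot = 0.0
        for nbr, _pos, syn, ts, stop in nbrs[codon]:
            if stop:
                continue
            w = (kappa if ts else 1.0) * (1.0 if syn else omega)
            if w <= 0:
                continue
            tot += w
            entries.append((tot, nbr, syn))
        table[codon] = (tot, tuple(entries))
    return table


def evolve_sequence(
    seq: str,
    t: float,
    omega: float,
    kappa: float,
    code: GeneticCode,
    rng: np.random.Generator,
) -> tuple[str, int, int]:
    """Evolve an in-frame stop-free sequence for time ``t``.

    Returns ``(descendant, n_synonymous_events, n_nonsynonymous_events)``;
    ``t = 0`` is the identity and ``omega = 0`` can log no non-synonymous
    event.
    """
    if t < 0 or omega < 0:
        raise ValueError("t and omega must be >= 0")
    table = _rate_table(code.table_id, float(omega), float(kappa))
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if t == 0:
        return seq, 0, 0
    totals = np.array([table[c][0] for c in codons])
    with np.errstate(divide="ignore"):
        waits = rng.exponential(1.0, len(codons)) / np.where(totals > 0, totals, np.inf)
    sd = nd = 0
    for idx in np.flatnonzero(waits < t):
        c = codons[idx]
        time = waits[idx]
        while True:
            tot, entries = table[c]
            u = rng.random() * tot
            for cum, nbr, syn in entries:
                if u <= cum:
                    c = nbr
                    if syn:
                        sd += 1
                    else:
                        nd += 1
                    break
            tot2 = table[c][0]
            if tot2 <= 0:
                break
            time += rng.exponential(1.0 / tot2)
            if time >= t:
                break
        codons[idx] = c
    return "".join(codons), sd, nd


def divergence_time(
    seq: str, target_prop: float, omega: float, kappa: float, code: GeneticCode
) -> float:
    """Evolution time giving an expected fraction of nucleotide sites changed.

    Inverts the Jukes-Cantor forward map p = 3/4 (1 - exp(-4m/3)) to the
    expected substitutions per site m, then divides by the sequence's mean
    per-site event rate under the process.  ``target_prop`` must be < 0.75.
    """
    if not 0 <= target_prop < 0.75:
        raise ValueError("target proportion must be in [0, 0.75)")
    if target_prop == 0:
        return 0.0
    table = _rate_table(code.table_id, float(omega), float(kappa))
    totals = [table[seq[i : i + 3]][0] for i in range(0, len(seq), 3)]
    rate_per_site = sum(totals) / len(totals) / 3.0
    m = -0.75 * math.log1p(-4.0 * target_prop / 3.0)
    return m / rate_per_site


def resample_third_positions(
    seq: str,
    code: GeneticCode,
    gc3: float,
    skew3: float,
    rng: np.random.Generator,
) -> tuple[str, int]:
    """Resample synonymous third positions toward a shifted pos-3 composition.

    For each codon the third base is redrawn among the synonymous, stop-free
    alternatives with weights from the target pos-3 nucleotide distribution,
    leaving the protein untouched.  Returns the new sequence and the count
    of codons changed (all changes are synonymous).
    """
    q3 = _position_dists([gc3] * 3, [skew3] * 3)[2]
    out = []
    changed = 0
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        aa = code.translate(codon)
        options = [
            codon[:2] + b
            for b in NUCS
            if not code.is_stop(codon[:2] + b) and code.translate(codon[:2] + b) == aa
        ]
        weights = np.array([q3[o[2]] for o in options])
        if weights.sum() <= 0 or len(options) == 1:
            out.append(codon)
            continue
        pick = options[int(np.searchsorted(np.cumsum(weights / weights.sum()), rng.random()))]
        if pick != codon:
            changed += 1
        out.append(pick)
    return "".join(out), changed


# ---------------------------------------------------------------------------
# dataset assembly

@dataclass
class GroundTruth:
    """Everything the generator planted, keyed for test consumption."""

    config: SyntheticConfig
    species: list[str]
    clade_of: dict[str, str]
    traits: dict[str, dict[str, str]]
    omega_true: dict[str, float]
    planted_cds: dict[tuple[str, str], tuple[str, str, bool]]  # (sp, gene) -> (nt, strand, wraps)
    alignment_rows: dict[tuple[str, str], str]                 # (sp, gene) -> codon row
    events: dict[tuple[str, str], tuple[int, int]]             # (sp, gene) -> (Sd, Nd) vs root
    outgroups: tuple[str, ...] = OUTGROUP_IDS


def _weighted_choice(rng: np.random.Generator, options) -> str:
    names = [o for o, _ in options]
    w = np.array([p for _, p in options], dtype=float)
    w /= w.sum()
    return names[int(np.searchsorted(np.cumsum(w), rng.random()))]


def _assign_species(cfg: SyntheticConfig, rng: np.random.Generator):
    species, clade_of, traits = [], {}, {}
    for i in range(cfg.n_species):
        clade = cfg.clades[i % len(cfg.clades)]
        sp = f"{clade}_sp{i:02d}"
        species.append(sp)
        clade_of[sp] = clade
        feeding = _weighted_choice(rng, _FEEDING_BY_CLADE.get(clade, _FEEDING_BY_CLADE["Rhabditina"]))
        habitat = _weighted_choice(rng, _HABITATS)
        repro = "amphimictic" if clade == "Spirurina" else _weighted_choice(rng, _REPRODUCTION)
        traits[sp] = {"feeding_habit": feeding, "habitat": habitat, "reproduction": repro}
    return species, clade_of, traits


_CLASS_OF = {"Enoplea": "Enoplea", "Tylenchina": "Chromadorea",
             "Rhabditina": "Chromadorea", "Spirurina": "Chromadorea"}
_SUBCLASS_OF = {"Enoplea": "Dorylaimia", "Tylenchina": "Chromadoria",
                "Rhabditina": "Chromadoria", "Spirurina": "Chromadoria"}
_ORDER_OF = {"Enoplea": "Dorylaimida", "Tylenchina": "Rhabditida",
             "Rhabditina": "Rhabditida", "Spirurina": "Rhabditida"}


def _taxonomy_row(sp: str, i: int, clade: str) -> dict[str, str]:
    return {
        "class": _CLASS_OF.get(clade, "Chromadorea"),
        "subclass": _SUBCLASS_OF.get(clade, "Chromadoria"),
        "order": _ORDER_OF.get(clade, "Rhabditida"),
        "suborder": clade,
        "infraorder": f"{clade}_morpha{i % 2}",
        "superfamily": f"{clade}_oidea{i % 3}",
        "family": f"{clade}_idae{i % 4}",
        "genus": f"{clade}_genus{i}",
    }


def _noncoding(n: int, gc: float, rng: np.random.Generator) -> str:
    q = _position_dists([gc], [0.0])[0]
    bases = np.array(list(NUCS))
    cum = np.cumsum([q[b] for b in NUCS])
    cum[-1] = 1.0
    return "".join(bases[np.searchsorted(cum, rng.random(n))])


def _feature_location(start: int, end: int, strand: str, wraps: bool, L: int):
    s = 1 if strand == "+" else -1
    if not wraps:
        return FeatureLocation(start, end, strand=s)
    head = FeatureLocation(start, L, strand=s)
    tail = FeatureLocation(0, end, strand=s)
    # parts in transcription order
    return CompoundLocation([head, tail] if s == 1 else [tail, head])


def build_dataset(cfg: SyntheticConfig, outdir: str | Path) -> GroundTruth:
    """Generate and write a complete synthetic dataset; returns the ground truth.

    Layout under ``outdir``: ``genomes/<species>.gb`` (annotated circular
    GenBank), ``alignments/<GENE>.fasta`` (gap-free codon alignments
    including the outgroup panel), ``traits.tsv``, ``tree.nwk`` and
    ``ground_truth/*.tsv``.  Byte-reproducible for a fixed config.
    """
    outdir = Path(outdir)
    (outdir / "genomes").mkdir(parents=True, exist_ok=True)
    (outdir / "alignments").mkdir(exist_ok=True)
    (outdir / "ground_truth").mkdir(exist_ok=True)
    code = genetic_code(cfg.table_id)
    rng = np.random.default_rng(cfg.seed)

    species, clade_of, traits = _assign_species(cfg, rng)
    omega_true = {
        sp: cfg.omega_by_feeding[traits[sp]["feeding_habit"]] for sp in species
    }
    genes = [g for g in PCG_NAMES if g in cfg.gene_lengths]
    minus_genes = {g for g in genes if rng.random() < cfg.minus_strand_prob}

    # root sequences and per-lineage divergence
    roots = {
        g: sample_codon_sequence(cfg.gene_lengths[g], code, cfg.target_gc,
                                 cfg.target_pos_skews, rng)
        for g in genes
    }
    alignment_rows: dict[tuple[str, str], str] = {}
    events: dict[tuple[str, str], tuple[int, int]] = {}
    for sp in species:
        omega = omega_true[sp]
        shift = cfg.skew_shift_by_feeding.get(traits[sp]["feeding_habit"], 0.0)
        for g in genes:
            t = divergence_time(roots[g], cfg.ingroup_divergence, omega, cfg.kappa, code)
            seq, sd, nd = evolve_sequence(roots[g], t, omega, cfg.kappa, code, rng)
            if shift:
                target3 = min(0.999, max(-0.999, cfg.target_pos_skews[2] + shift))
                seq, extra = resample_third_positions(seq, code, cfg.target_gc, target3, rng)
                sd += extra
            alignment_rows[(sp, g)] = seq
            events[(sp, g)] = (sd, nd)
    for og in OUTGROUP_IDS:
        for g in genes:
            t = divergence_time(roots[g], cfg.outgroup_divergence,
                                cfg.omega_outgroup, cfg.kappa, code)
            seq, sd, nd = evolve_sequence(roots[g], t, cfg.omega_outgroup, cfg.kappa, code, rng)
            alignment_rows[(og, g)] = seq
            events[(og, g)] = (sd, nd)

    # per-gene alignment FASTAs (gap-free, ingroup then outgroups)
    for g in genes:
        with open(outdir / "alignments" / f"{g}.fasta", "w") as fh:
            for sp in species + list(OUTGROUP_IDS):
                fh.write(f">{sp}\n{alignment_rows[(sp, g)]}\n")

    # assemble circular annotated genomes
    planted: dict[tuple[str, str], tuple[str, str, bool]] = {}
    rna_lengths = [700, 960] + [60] * 22  # 2 rRNAs + 22 tRNAs
    for sp in species:
        cds_of = {g: alignment_rows[(sp, g)] + "TAA" for g in genes}
        coding_total = sum(len(v) for v in cds_of.values())
        # per-species spacer variation: real genomes vary mostly in noncoding DNA
        noncoding_total = max(
            sum(rna_lengths) + len(genes),
            round(
                coding_total
                * cfg.noncoding_fraction
                / (1 - cfg.noncoding_fraction)
                * rng.uniform(0.7, 1.4)
            ),
        )
        pad_total = noncoding_total - sum(rna_lengths)
        pad_each = pad_total // len(genes)
        pad_rem = pad_total % len(genes)

        seq_parts: list[str] = []
        feats: list[dict] = []  # name, type, start, end, strand, wraps
        pos = 0
        rnas = [("rrnL", "rRNA", 700), ("rrnS", "rRNA", 960)] + [
            (f"trn{chr(65 + k)}", "tRNA", 60) for k in range(22)
        ]
        # distribute RNAs round-robin over the 12 spacers
        spacer_rnas: list[list] = [[] for _ in genes]
        for k, rna in enumerate(rnas):
            spacer_rnas[k % len(genes)].append(rna)
        for gi, g in enumerate(genes):
            nt = cds_of[g]
            strand = "-" if g in minus_genes else "+"
            genomic = reverse_complement(nt) if strand == "-" else nt
            feats.append({"name": g, "type": "CDS", "start": pos,
                          "end": pos + len(nt), "strand": strand, "wraps": False})
            seq_parts.append(genomic)
            pos += len(nt)
            planted[(sp, g)] = (nt, strand, False)
            # spacer with its RNA placeholders
            for name, ftype, length in spacer_rnas[gi]:
                feats.append({"name": name, "type": ftype, "start": pos,
                              "end": pos + length, "strand": "+", "wraps": False})
                seq_parts.append(_noncoding(length, cfg.target_gc, rng))
                pos += length
            pad = pad_each + (1 if gi < pad_rem else 0)
            seq_parts.append(_noncoding(pad, cfg.target_gc, rng))
            pos += pad
        genome_seq = "".join(seq_parts)
        L = len(genome_seq)

        if cfg.wrap_last_gene:
            last = next(f for f in feats if f["name"] == genes[-1])
            r = last["start"] + (last["end"] - last["start"]) // 2
            genome_seq = genome_seq[r:] + genome_seq[:r]
            for f in feats:
                length = f["end"] - f["start"]
                ns = (f["start"] - r) % L
                wraps = ns + length > L
                f["start"], f["wraps"] = ns, wraps
                f["end"] = ns + length - L if wraps else ns + length
            for g in genes:
                f = next(x for x in feats if x["name"] == g)
                planted[(sp, g)] = (cds_of[g], f["strand"], f["wraps"])

        record = SeqRecord(
            Seq(genome_seq),
            id=sp,
            name=sp[:16],
            description=f"synthetic nematode mitochondrial genome, clade {clade_of[sp]}",
            annotations={"molecule_type": "DNA", "topology": "circular",
                         "organism": sp},
        )
        for f in feats:
            loc = _feature_location(f["start"], f["end"], f["strand"], f["wraps"], L)
            qualifiers = {"gene": [f["name"]]}
            if f["type"] == "CDS":
                qualifiers["codon_start"] = ["1"]
                qualifiers["transl_table"] = [str(cfg.table_id)]
            record.features.append(SeqFeature(loc, type=f["type"], qualifiers=qualifiers))
        SeqIO.write([record], str(outdir / "genomes" / f"{sp}.gb"), "genbank")

    # trait table
    with open(outdir / "traits.tsv", "w") as fh:
        cols = ["species_id", "class", "subclass", "order", "suborder", "infraorder",
                "superfamily", "family", "genus", "feeding_habit", "habitat", "reproduction"]
        fh.write("\t".join(cols) + "\n")
        for i, sp in enumerate(species):
            tax = _taxonomy_row(sp, i, clade_of[sp])
            row = [sp] + [tax[c] for c in cols[1:9]] + [traits[sp][c] for c in cols[9:]]
            fh.write("\t".join(row) + "\n")

    # display tree: clades as polytomies, outgroups basal
    clade_groups = {
        c: [sp for sp in species if clade_of[sp] == c] for c in cfg.clades
    }
    ingroup = ",".join(
        "(" + ",".join(clade_groups[c]) + ")" for c in cfg.clades if clade_groups[c]
    )
    newick = f"(({ingroup}),({','.join(OUTGROUP_IDS)}));\n"
    (outdir / "tree.nwk").write_text(newick)

    # ground-truth sidecar
    with open(outdir / "ground_truth" / "planted_cds.tsv", "w") as fh:
        fh.write("species_id\tgene\tstrand\twraps_origin\tnt\n")
        for (sp, g), (nt, strand, wraps) in sorted(planted.items()):
            fh.write(f"{sp}\t{g}\t{strand}\t{int(wraps)}\t{nt}\n")
    with open(outdir / "ground_truth" / "events.tsv", "w") as fh:
        fh.write("species_id\tgene\tsd_true\tnd_true\tomega_true\n")
        for (sp, g), (sd, nd) in sorted(events.items()):
            om = omega_true.get(sp, cfg.omega_outgroup)
            fh.write(f"{sp}\t{g}\t{sd}\t{nd}\t{om}\n")
    (outdir / "ground_truth" / "targets.json").write_text(
        json.dumps(
            {
                "target_gc": cfg.target_gc,
                "target_pos_skews": list(cfg.target_pos_skews),
                "seed": cfg.seed,
                "omega_by_feeding": cfg.omega_by_feeding,
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )

    return GroundTruth(
        config=cfg,
        species=species,
        clade_of=clade_of,
        traits=traits,
        omega_true=omega_true,
        planted_cds=planted,
        alignment_rows=alignment_rows,
        events=events,
    )
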