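"""Pairwise synonymous / non-synonymous substitution rates (counting method).

Implements a Nei-Gojobori-type estimator under the invertebrate
mitochondrial code: expected synonymous (S) and non-synonymous (N) site
counts per codon by single-nucleotide neighbor enumeration, pairwise
difference counts averaged with equal weight over all minimal stop-free
mutational paths, proportions pS = Sd/S and pN = Nd/N, and a Jukes-Cantor
multiple-hit correction d = -(3/4) ln(1 - (4/3) p).  Each ingroup sequence's
per-gene rates are averaged over a panel of outgroup sequences (the study
design uses five: two tardigrades and three arthropods), and dN:dS is the
ratio of the averaged rates.

A counting estimator cannot correct divergences with p >= 3/4; such pairs
are flagged saturated and excluded from outgroup averages, mirroring the
missing cells that maximum-likelihood engines produce on the same data for
want of resolved sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .alignment import AlignmentBlock
from .gencode import INVERTEBRATE_MITO, GeneticCode, codon_neighbors, genetic_code

_UNAMBIGUOUS = frozenset("ACGT")

#: default minimum comparable codons for an estimable pair
MIN_CODONS = 30

STATUS_OK = "ok"
STATUS_SAT_DS = "saturated_dS"
STATUS_SAT_DN = "saturated_dN"
STATUS_INSUFFICIENT = "insufficient_sites"


def count_sites(codon: str, code: GeneticCode) -> tuple[float, float]:
    """Expected synonymous and non-synonymous site counts of one sense codon.

    At each of the three positions, the synonymous fraction is the share of
    synonymous changes among the single-nucleotide changes that do not
    create a stop codon; stop-creating changes are excluded from that
    position's denominator.  Site counts always satisfy s + n = 3.
    """
    codon = codon.upper()
    if code.is_stop(codon):
        raise ValueError(f"stop codon {codon} has no site decomposition")
    if not set(codon) <= _UNAMBIGUOUS or len(codon) != 3:
        raise ValueError(f"ambiguous or malformed codon {codon!r}")
    per_pos_syn = [0, 0, 0]
    per_pos_valid = [0, 0, 0]
    for _, pos, syn, _, stop in codon_neighbors(code.table_id)[codon]:
        if stop:
            continue
        per_pos_valid[pos] += 1
        if syn:
            per_pos_syn[pos] += 1
    s = sum(
        (per_pos_syn[p] / per_pos_valid[p]) if per_pos_valid[p] else 0.0
        for p in range(3)
    )
    return s, 3.0 - s


def count_differences(
    codon_a: str, codon_b: str, code: GeneticCode
) -> tuple[float, float, bool]:
    """Synonymous / non-synonymous difference counts between two sense codons.

    Differences are classified along all minimal single-step paths between
    the codons; paths passing through a stop codon are discarded and the
    remaining paths weighted equally.  Returns ``(sd, nd, used_stop_paths)``
    where the flag marks the degenerate case in which every minimal path
    passes through a stop and stop-containing paths had to be used.
    ``sd + nd`` equals the Hamming distance of the pair.
    """
    a, b = codon_a.upper(), codon_b.upper()
    for c in (a, b):
        if code.is_stop(c):
            raise ValueError(f"stop codon {c} in difference count")
        if not set(c) <= _UNAMBIGUOUS or len(c) != 3:
            raise ValueError(f"ambiguous or malformed codon {c!r}")
    diff_pos = [i for i in range(3) if a[i] != b[i]]
    if not diff_pos:
        return 0.0, 0.0, False

    def classify(order: tuple[int, ...]) -> tuple[float, float] | None:
        sd = nd = 0
        cur = a
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if code.is_stop(nxt):
                return None
            if code.translate(cur) == code.translate(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd

    paths = [classify(order) for order in permutations(diff_pos)]
    legal = [p for p in paths if p is not None]
    used_stop_paths = not legal
    if used_stop_paths:
        # all minimal paths run through a stop; classify anyway, flagged
        legal = []
        for order in permutations(diff_pos):
            sd = nd = 0
            cur = a
            for pos in order:
                nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
                same = (not code.is_stop(nxt) and not code.is_stop(cur)
                        and code.translate(cur) == code.translate(nxt))
                sd, nd = (sd + 1, nd) if same else (sd, nd + 1)
                cur = nxt
            legal.append((sd, nd))
    sd = sum(p[0] for p in legal) / len(legal)
    nd = sum(p[1] for p in legal) / len(legal)
    return sd, nd, used_stop_paths


@lru_cache(maxsize=None)
def _sites_cached(table_id: int, codon: str) -> tuple[float, float]:
    return count_sites(codon, genetic_code(table_id))


@lru_cache(maxsize=None)
def _diffs_cached(table_id: int, a: str, b: str) -> tuple[float, float, bool]:
    return count_differences(a, b, genetic_code(table_id))


def jukes_cantor(p: float) -> float | None:
    """JC multiple-hit correction; None when p >= 3/4 (saturated)."""
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass(frozen=True)
class PairwiseRateEstimate:
    """NG86-style pairwise rate estimate for one gene and taxon pair."""

    taxon_a: str
    taxon_b: str
    gene: str
    n_codons_compared: int
    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    pS: float | None
    pN: float | None
    dS: float | None
    dN: float | None
    omega: float | None
    status: str


def _comparable_codon(codon: str, code: GeneticCode) -> bool:
    return set(codon) <= _UNAMBIGUOUS and len(codon) == 3 and not code.is_stop(codon)


def ng86_pairwise(
    seq_a: str,
    seq_b: str,
    code: GeneticCode | None = None,
    *,
    gene: str = "",
    taxon_a: str = "a",
    taxon_b: str = "b",
    min_codons: int = MIN_CODONS,
) -> PairwiseRateEstimate:
    """Pairwise dN/dS between two aligned coding rows.

    Codons containing a gap, ambiguity or stop in either taxon are masked
    pairwise.  Site counts are averaged over the two sequences; the JC
    correction is applied to pS and pN separately.  Status is
    ``insufficient_sites`` below ``min_codons`` comparable codons and
    ``saturated_dS``/``saturated_dN`` when the correction is undefined.
    """
    code = code or genetic_code(INVERTEBRATE_MITO)
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned rows differ in length")
    tid = code.table_id
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    s_a = s_b = sd = nd = 0.0
    n_comp = 0
    for i in range(0, len(seq_a) - len(seq_a) % 3, 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        if not (_comparable_codon(ca, code) and _comparable_codon(cb, code)):
            continue
        n_comp += 1
        s_a += _sites_cached(tid, ca)[0]
        s_b += _sites_cached(tid, cb)[0]
        if ca != cb:
            d_s, d_n, _ = _diffs_cached(tid, ca, cb)
            sd += d_s
            nd += d_n
    S = (s_a + s_b) / 2.0
    N = 3.0 * n_comp - S

    def build(status, pS=None, pN=None, dS=None, dN=None, omega=None):
        return PairwiseRateEstimate(
            taxon_a=taxon_a, taxon_b=taxon_b, gene=gene,
            n_codons_compared=n_comp, S_sites=S, N_sites=N, Sd=sd, Nd=nd,
            pS=pS, pN=pN, dS=dS, dN=dN, omega=omega, status=status,
        )

    if n_comp < min_codons or S <= 0 or N <= 0:
        return build(STATUS_INSUFFICIENT)
    pS, pN = sd / S, nd / N
    dS, dN = jukes_cantor(pS), jukes_cantor(pN)
    if dS is None:
        return build(STATUS_SAT_DS, pS=pS, pN=pN, dN=dN)
    if dN is None:
        return build(STATUS_SAT_DN, pS=pS, pN=pN, dS=dS)
    omega = dN / dS if dS > 0 else None
    return build(STATUS_OK, pS=pS, pN=pN, dS=dS, dN=dN, omega=omega)


@dataclass(frozen=True)
class OutgroupAveragedRate:
    """A species' per-gene rates averaged over the outgroup panel."""

    species_id: str
    gene: str
    dN_mean: float | None
    dS_mean: float | None
    omega_of_means: float | None
    n_outgroups_used: int

    @property
    def missing(self) -> bool:
        return self.n_outgroups_used == 0


def average_over_outgroups(
    ingroup_row: str,
    ingroup_id: str,
    outgroup_rows: Mapping[str, str],
    gene: str = "",
    code: GeneticCode | None = None,
    min_codons: int = MIN_CODONS,
) -> OutgroupAveragedRate:
    """Average a sequence's pairwise rates over the outgroup panel.

    Only status-ok pairs contribute; a species with no estimable outgroup
    pair comes back missing (``n_outgroups_used == 0``), the analogue of a
    rate cell lost to unresolved sites.  dN:dS is the ratio of the averaged
    dN and dS (robust to near-zero dS in single pairs), not the average of
    per-pair ratios.
    """
    dns, dss = [], []
    for og_id, og_row in outgroup_rows.items():
        est = ng86_pairwise(
            ingroup_row, og_row, code, gene=gene,
            taxon_a=ingroup_id, taxon_b=og_id, min_codons=min_codons,
        )
        if est.status == STATUS_OK:
            dns.append(est.dN)
            dss.append(est.dS)
    if not dns:
        return OutgroupAveragedRate(ingroup_id, gene, None, None, None, 0)
    dn_mean = sum(dns) / len(dns)
    ds_mean = sum(dss) / len(dss)
    omega = dn_mean / ds_mean if ds_mean > 0 else None
    return OutgroupAveragedRate(ingroup_id, gene, dn_mean, ds_mean, omega, len(dns))


def rates_table(
    gene_blocks: Iterable[AlignmentBlock],
    outgroup_ids: Sequence[str],
    code: GeneticCode | None = None,
    min_codons: int = MIN_CODONS,
) -> pd.DataFrame:
    """Per-species, per-gene outgroup-averaged rates in long format.

    Columns: species_id, gene, dN_mean, dS_mean, omega, n_outgroups_used,
    status.  Ingroup species are every taxon not in ``outgroup_ids``; genes
    whose alignment lacks some outgroup proceed with those available.
    """
    rows = []
    for block in gene_blocks:
        outgroups = {t: block.row(t) for t in outgroup_ids if t in block.taxa}
        for taxon in block.taxa:
            if taxon in outgroup_ids:
                continue
            avg = average_over_outgroups(
                block.row(taxon), taxon, outgroups, gene=block.gene,
                code=code, min_codons=min_codons,
            )
            rows.append(
                {
                    "species_id": avg.species_id,
                    "gene": avg.gene,
                    "dN_mean": avg.dN_mean,
                    "dS_mean": avg.dS_mean,
                    "omega": avg.omega_of_means,
                    "n_outgroups_used": avg.n_outgroups_used,
                    "status": "missing" if avg.missing else "ok",
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "species_id", "gene", "dN_mean", "dS_mean",
            "omega", "n_outgroups_used", "status",
        ],
    )
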