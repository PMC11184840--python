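"""Genetic-code tables and codon-level utilities.

Codes are keyed by NCBI translation-table number; the default throughout the
package is table 5 (invertebrate mitochondrial), under which AGA/AGG encode
serine, ATA methionine and TGA tryptophan, leaving TAA and TAG as the only
stop codons.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
_PURINES = frozenset("AG")

_COMPLEMENT = str.maketrans(
    "ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
    "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb",
)

INVERTEBRATE_MITO = 5  # NCBI translation table id


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware, case kept)."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_transition(a: str, b: str) -> bool:
    """True when a->b is a purine<->purine or pyrimidine<->pyrimidine change."""
    return a != b and (a in _PURINES) == (b in _PURINES)


@dataclass(frozen=True)
class GeneticCode:
    """A nuclear or organellar genetic code.

    Attributes
    ----------
    table_id : NCBI translation-table number.
    codon_to_aa : map of all 64 codons to one-letter amino acids, with stop
        codons mapped to ``"*"``.
    stop_codons : the stop-codon set.
    """

    table_id: int
    codon_to_aa: Mapping[str, str]
    stop_codons: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64:
            raise ValueError("genetic code must map all 64 codons")

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c in sorted(self.codon_to_aa) if c not in self.stop_codons)

    def translate(self, codon: str) -> str:
        """One-letter amino acid for a codon; '*' for a stop codon."""
        return self.codon_to_aa[codon.upper()]

    def is_stop(self, codon: str) -> bool:
        return codon.upper() in self.stop_codons

    def translate_cds(self, nt: str) -> str:
        """Translate an in-frame nucleotide string codon by codon.

        Codons containing non-ACGT characters translate to 'X'.
        """
        aas = []
        for i in range(0, len(nt) - len(nt) % 3, 3):
            codon = nt[i : i + 3].upper()
            aas.append(self.codon_to_aa.get(codon, "X"))
        return "".join(aas)


@lru_cache(maxsize=None)
def genetic_code(table_id: int = INVERTEBRATE_MITO) -> GeneticCode:
    """Load a genetic code by NCBI translation-table number."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    if len(mapping) != 64:  # tables omit nothing else, but be defensive
        raise ValueError(f"translation table {table_id} is incomplete")
    return GeneticCode(
        table_id=table_id,
        codon_to_aa=mapping,
        stop_codons=frozenset(table.stop_codons),
    )


@lru_cache(maxsize=None)
def codon_neighbors(table_id: int) -> dict[str, tuple[tuple[str, int, bool, bool, bool], ...]]:
    """Single-nucleotide neighborhoods of every codon under a code.

    Returns, per codon, a tuple of ``(neighbor, position, is_synonymous,
    is_transition, is_stop)`` over the nine single-nucleotide mutants.
    ``is_synonymous`` is False whenever either codon is a stop.
    """
    code = genetic_code(table_id)
    out: dict[str, tuple[tuple[str, int, bool, bool, bool], ...]] = {}
    for codon in code.codon_to_aa:
        aa = code.codon_to_aa[codon]
        nbrs = []
        for pos in range(3):
            for base in NUCLEOTIDES:
                if base == codon[pos]:
                    continue
                mutant = codon[:pos] + base + codon[pos + 1 :]
                stop = mutant in code.stop_codons
                syn = (not stop) and aa != "*" and code.codon_to_aa[mutant] == aa
                nbrs.append((mutant, pos, syn, is_transition(codon[pos], base), stop))
        out[codon] = tuple(nbrs)
    return out
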