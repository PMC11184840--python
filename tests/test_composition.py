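"""Skew, %GC and summary-statistic behavior."""

import math

import numpy as np
import pytest

from nemamito.composition import (
    at_skew,
    clade_summary,
    codon_position_skew,
    codon_position_subsequence,
    composition_table,
    gc_skew,
    genome_summary,
    pct_gc,
)
from nemamito.gencode import reverse_complement
from nemamito.genomes import CodingSequence, GeneFeature, Mitogenome, extract_pcgs


@pytest.mark.parametrize(
    "func, seq, expected",
    [
        (gc_skew, "GGGC", 0.5),
        (gc_skew, "ATATAT", None),
        (at_skew, "AAT", 1 / 3),
        (at_skew, "GC", None),
        (pct_gc, "GCGC", 100.0),
        (pct_gc, "ATGC", 50.0),
        (pct_gc, "ATGCN", 50.0),  # ambiguity excluded from both sides
        (pct_gc, "", None),
        (gc_skew, "GGNNCC", 0.0),
    ],
)
def test_point_values(func, seq, expected):
    result = func(seq)
    if expected is None:
        assert result is None
    else:
        assert result == pytest.approx(expected)


def test_skew_antisymmetry_under_complementation(rng):
    for _ in range(200):
        seq = "".join(rng.choice(list("ACGT"), rng.integers(1, 120)))
        rc = reverse_complement(seq)
        for skew in (gc_skew, at_skew):
            s, s_rc = skew(seq), skew(rc)
            if s is None:
                assert s_rc is None
            else:
                assert s_rc == pytest.approx(-s)
                assert -1 <= s <= 1
        # a sequence concatenated with its complement is balanced
        both = gc_skew(seq + rc)
        assert both is None or both == pytest.approx(0.0)


def test_codon_positions_partition_the_sequence(rng):
    for _ in range(50):
        n = int(rng.integers(2, 60))
        seq = "".join(rng.choice(list("ACGT"), 3 * n))
        subs = [codon_position_subsequence(seq, p) for p in (1, 2, 3)]
        assert all(len(s) == n for s in subs)
        assert sorted("".join(subs)) == sorted(seq)


def test_codon_position_skew_examples():
    assert codon_position_skew("GATGCTGGT", 3) is None  # positions 3: T,T,T
    assert codon_position_skew("GATGCTGGT", 1) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        codon_position_skew("GATGCTGGT", 4)


def _genome_with_pcgs(seq, features):
    g = Mitogenome(id="g", sequence=seq, is_circular=True, features=features)
    return g, extract_pcgs(g)


def test_genome_summary_fields():
    seq = "ATGAAATTTGGG" + "ATGCCCTAA" + "T" * 9
    feats = [
        GeneFeature("cox1", "COX1", 0, 12, "+"),
        GeneFeature("nad3", "NAD3", 12, 21, "+"),
    ]
    g, cdss = _genome_with_pcgs(seq, feats)
    rec = genome_summary(g, cdss)
    assert rec.genome_length == 30
    assert rec.pcg_total_length == 21
    assert rec.pcg_proportion == pytest.approx(21 / 30)
    assert rec.per_gene["COX1"][0] == 12
    assert ("NAD3", 3) in rec.per_codon_position
    assert rec.pcg_total_length == sum(v[0] for v in rec.per_gene.values())


def test_genome_summary_requires_pcgs():
    g = Mitogenome(id="g", sequence="ACGT", is_circular=True)
    with pytest.raises(ValueError):
        genome_summary(g, [])


def test_generator_targets_recovered(dataset):
    """Planted composition targets are recovered from emitted genomes."""
    from pathlib import Path

    from nemamito.genomes import read_genbank

    outdir, truth = dataset
    cfg = truth.config
    # pool positionwise skew over all species/genes with no trait shift
    neutral = [
        sp for sp in truth.species
        if truth.traits[sp]["feeding_habit"] not in cfg.skew_shift_by_feeding
    ]
    assert neutral
    pooled = {1: [], 2: [], 3: []}
    gcs = []
    for sp in neutral:
        g = read_genbank(Path(outdir, "genomes", f"{sp}.gb"))[0]
        cdss = extract_pcgs(g)
        rec = genome_summary(g, cdss)
        gcs.append(rec.genome_pct_gc)
        for cds in cdss:
            sub = [codon_position_subsequence(cds.nt[:-3], p) for p in (1, 2, 3)]
            for p in (1, 2, 3):
                pooled[p].append(sub[p - 1])
    # lineage divergence from the root decays planted skews toward the
    # mutation process's stationary composition, fastest at third positions
    # where most (synonymous) changes land; the solver/sampler themselves
    # are exact (see test_simulate), so allow that drift here
    for p, tol in ((1, 0.08), (2, 0.08), (3, 0.13)):
        realized = gc_skew("".join(pooled[p]))
        assert realized == pytest.approx(cfg.target_pos_skews[p - 1], abs=tol)
    # the planted ordering (strong pos-3 G skew, weak pos-2) survives
    skew_of = {p: gc_skew("".join(pooled[p])) for p in (1, 2, 3)}
    assert skew_of[3] > skew_of[1] > skew_of[2]
    assert np.mean(gcs) == pytest.approx(100 * cfg.target_gc, abs=2.0)


def test_clade_summary_matches_brute_force(rng):
    from nemamito.composition import CompositionRecord

    records = []
    labels = {}
    for i in range(50):
        rec = CompositionRecord(
            species_id=f"sp{i}",
            genome_length=int(rng.integers(12000, 20000)),
            pcg_total_length=10000, pcg_proportion=0.7,
            genome_pct_gc=float(rng.uniform(15, 40)),
            pcg_pct_gc=None if i % 7 == 0 else float(rng.uniform(15, 40)),
            genome_gc_skew=0.1, genome_at_skew=0.0,
            pcg_gc_skew=0.2, pcg_at_skew=-0.1,
        )
        records.append(rec)
        labels[rec.species_id] = f"clade{i % 3}" if i % 11 else None
    summaries = {s.group: s for s in clade_summary(records, labels)}
    # independent accumulation
    for group, s in summaries.items():
        for metric in ("genome_length", "genome_pct_gc", "pcg_pct_gc"):
            vals = [
                getattr(r, metric) for r in records
                if labels[r.species_id] == group and getattr(r, metric) is not None
            ]
            ms = s.metrics[metric]
            assert ms.n == len(vals)
            assert ms.mean == pytest.approx(np.mean(vals))
            assert ms.min == min(vals) and ms.max == max(vals)
            assert ms.min <= ms.mean <= ms.max
            if len(vals) > 1:
                assert ms.stdev == pytest.approx(np.std(vals, ddof=1))


def test_clade_summary_two_point_and_singleton():
    from nemamito.composition import CompositionRecord

    def rec(i, length):
        return CompositionRecord(
            species_id=f"s{i}", genome_length=length, pcg_total_length=1,
            pcg_proportion=0.5, genome_pct_gc=25.0, pcg_pct_gc=25.0,
            genome_gc_skew=0.0, genome_at_skew=0.0, pcg_gc_skew=0.0, pcg_at_skew=0.0,
        )

    out = clade_summary(
        [rec(0, 12000), rec(1, 14000), rec(2, 13000)],
        {"s0": "a", "s1": "a", "s2": "b"},
    )
    a = next(s for s in out if s.group == "a").metrics["genome_length"]
    assert a.mean == 13000
    assert a.stdev == pytest.approx(1414.2, abs=0.1)
    b = next(s for s in out if s.group == "b").metrics["genome_length"]
    assert b.stdev is None


def test_composition_table_row_order_follows_tree(dataset):
    outdir, truth = dataset
    from pathlib import Path

    from nemamito.genomes import read_genbank

    records = []
    for sp in truth.species[:4]:
        g = read_genbank(Path(outdir, "genomes", f"{sp}.gb"))[0]
        records.append(genome_summary(g, extract_pcgs(g)))
    order = [truth.species[2], truth.species[0]]
    df = composition_table(records, order=order)
    assert list(df.index) == order
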