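"""Counting dN/dS estimator: sites, differences, correction, outgroup averaging."""

import itertools

import numpy as np
import pytest

from conftest import oracle_differences, oracle_sites
from nemamito.rates import (
    STATUS_INSUFFICIENT,
    STATUS_OK,
    STATUS_SAT_DS,
    average_over_outgroups,
    count_differences,
    count_sites,
    jukes_cantor,
    ng86_pairwise,
    rates_table,
)
from nemamito.simulate import divergence_time, evolve_sequence, sample_codon_sequence


def test_count_sites_phe_example(code):
    s, n = count_sites("TTT", code)
    assert s == pytest.approx(1 / 3)   # only TTT->TTC is synonymous
    assert n == pytest.approx(8 / 3)


def test_fourfold_codon_third_position_fully_synonymous(code):
    # GGA (Gly): all three third-position changes synonymous
    s_gga, _ = count_sites("GGA", code)
    s_gg_only_pos12 = oracle_sites("GGA", code)[0] - 1.0
    assert s_gga == pytest.approx(1.0 + s_gg_only_pos12)
    assert s_gga >= 1.0


def test_count_sites_rejects_stops_and_ambiguity(code):
    with pytest.raises(ValueError):
        count_sites("TAA", code)
    with pytest.raises(ValueError):
        count_sites("ANG", code)


def test_site_conservation_for_every_sense_codon(code):
    for codon in code.sense_codons:
        s, n = count_sites(codon, code)
        assert s + n == pytest.approx(3.0)
        assert 0 <= s <= 3


def test_count_differences_basics(code):
    assert count_differences("TTT", "TTT", code)[:2] == (0.0, 0.0)
    sd, nd, flagged = count_differences("TTT", "TTA", code)
    assert (sd, nd) == (0.0, 1.0)  # Phe -> Leu
    assert not flagged


def test_count_differences_matches_path_oracle(code):
    rng = np.random.default_rng(7)
    sense = code.sense_codons
    pairs = [(sense[i], sense[j]) for i, j in
             rng.integers(0, len(sense), size=(300, 2)) if sense[i] != sense[j]]
    for a, b in pairs:
        sd, nd, _ = count_differences(a, b, code)
        osd, ond = oracle_differences(a, b, code)
        assert sd == pytest.approx(osd)
        assert nd == pytest.approx(ond)
        hamming = sum(x != y for x, y in zip(a, b))
        assert sd + nd == pytest.approx(hamming)


def test_count_differences_symmetric(code):
    rng = np.random.default_rng(3)
    sense = code.sense_codons
    for _ in range(100):
        a, b = (sense[i] for i in rng.integers(0, len(sense), 2))
        assert count_differences(a, b, code) == count_differences(b, a, code)


def test_jukes_cantor_small_divergence_linearization():
    for p in np.linspace(1e-6, 0.01, 25):
        d = jukes_cantor(p)
        assert abs(d - p) <= 1e-4
    assert jukes_cantor(0.75) is None
    assert jukes_cantor(0.9) is None


def test_ng86_identical_sequences(code):
    seq = "ATGAAATTTGGGCCC" * 10
    est = ng86_pairwise(seq, seq, code)
    assert est.status == STATUS_OK
    assert est.dN == est.dS == 0.0
    assert est.S_sites + est.N_sites == pytest.approx(3 * est.n_codons_compared)


def test_ng86_synonymous_only_divergence(code, rng):
    seq = sample_codon_sequence(2000, code, 0.25, (0.2, 0.0, 0.4), rng)
    t = divergence_time(seq, 0.05, 0.0, 1.0, code)
    desc, sd, nd = evolve_sequence(seq, t, 0.0, 1.0, code, rng)
    assert nd == 0
    est = ng86_pairwise(seq, desc, code)
    assert est.status == STATUS_OK
    # multi-hit codons can pick up fractional Nd through path averaging even
    # when every event was synonymous; dN stays negligible next to dS
    assert est.dN <= 1e-3
    assert est.dS > 0.1
    assert est.dS > 50 * est.dN


def test_ng86_single_step_synonymous_changes_give_exactly_zero_dn(code):
    from nemamito.gencode import codon_neighbors

    nbrs = codon_neighbors(code.table_id)
    base = ("TTA", "GGA", "CCT", "CGA", "ACC", "GTT") * 20
    changed = []
    for i, codon in enumerate(base):
        if i % 3 == 0:
            syn = [n for n, _, is_syn, _, _ in nbrs[codon] if is_syn]
            changed.append(syn[0])
        else:
            changed.append(codon)
    est = ng86_pairwise("".join(base), "".join(changed), code)
    assert est.Nd == 0.0
    assert est.dN == 0.0
    assert est.dS > 0.0


def test_ng86_saturation_status(code):
    # every codon changed synonymously: pS far above the correction domain
    est = ng86_pairwise("TTA" * 40, "TTG" * 40, code)
    assert est.status == STATUS_SAT_DS
    assert est.dS is None


def test_ng86_insufficient_sites(code):
    est = ng86_pairwise("ATG" * 10, "ATG" * 10, code, min_codons=30)
    assert est.status == STATUS_INSUFFICIENT
    est2 = ng86_pairwise("---" * 40, "ATG" * 40, code)
    assert est2.status == STATUS_INSUFFICIENT
    assert est2.n_codons_compared == 0


def test_ng86_symmetry(code, rng):
    seq = sample_codon_sequence(500, code, 0.3, (0.1, 0.0, 0.3), rng)
    t = divergence_time(seq, 0.08, 0.3, 2.0, code)
    desc, _, _ = evolve_sequence(seq, t, 0.3, 2.0, code, rng)
    a = ng86_pairwise(seq, desc, code)
    b = ng86_pairwise(desc, seq, code)
    assert a.dS == pytest.approx(b.dS)
    assert a.dN == pytest.approx(b.dN)
    assert a.S_sites == pytest.approx(b.S_sites)


def test_ng86_masks_stop_and_ambiguous_codons_pairwise(code):
    base = "ATGAAATTTGGGCCC" * 8
    with_stop = "TAA" + base[3:]
    with_amb = "NNN" + base[3:]
    for variant in (with_stop, with_amb):
        est = ng86_pairwise(base, variant, code, min_codons=5)
        assert est.n_codons_compared == len(base) // 3 - 1


def test_average_over_outgroups_exclusion_and_means(code, rng):
    seq = sample_codon_sequence(400, code, 0.25, (0.2, 0.0, 0.4), rng)
    outgroups = {}
    expected_dn, expected_ds = [], []
    for i in range(3):
        t = divergence_time(seq, 0.06 + 0.02 * i, 0.2, 1.0, code)
        desc, _, _ = evolve_sequence(seq, t, 0.2, 1.0, code, rng)
        outgroups[f"og{i}"] = desc
        est = ng86_pairwise(seq, desc, code)
        expected_dn.append(est.dN)
        expected_ds.append(est.dS)
    # two unusable outgroups: one saturated, one all-gap
    outgroups["sat"] = "".join(
        "TTG" if seq[i : i + 3] == "TTA" else
        "TTA" if seq[i : i + 3] == "TTG" else "CGA"
        for i in range(0, len(seq), 3)
    )
    outgroups["gap"] = "-" * len(seq)
    avg = average_over_outgroups(seq, "in", outgroups, gene="COX1", code=code)
    assert avg.n_outgroups_used == 3
    assert avg.dN_mean == pytest.approx(np.mean(expected_dn))
    assert avg.dS_mean == pytest.approx(np.mean(expected_ds))
    assert avg.omega_of_means == pytest.approx(avg.dN_mean / avg.dS_mean)
    assert not avg.missing


def test_average_over_outgroups_all_failed_is_missing(code):
    avg = average_over_outgroups("ATG" * 50, "in", {"og": "-" * 150}, code=code)
    assert avg.missing
    assert avg.n_outgroups_used == 0


def test_rates_table_shape_and_purifying_omega(dataset, code):
    from nemamito.alignment import read_alignment
    from nemamito.simulate import OUTGROUP_IDS

    outdir, truth = dataset
    blocks = [
        read_alignment(outdir / "alignments" / f"{g}.fasta")
        for g in ("COX1", "NAD5", "ATP6")
    ]
    df = rates_table(blocks, OUTGROUP_IDS, code)
    assert len(df) == 3 * len(truth.species)
    ok = df[df["status"] == "ok"]
    assert len(ok) > 0
    # simulator used strongly purifying omega everywhere
    assert (ok["omega"].dropna() < 1).all()
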