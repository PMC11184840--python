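"""Mitogenome parsing, PCG extraction, orientation and trait-table I/O."""

from pathlib import Path

import numpy as np
import pytest

from nemamito.composition import at_skew, gc_skew, pct_gc
from nemamito.genomes import (
    CodingSequence,
    GeneFeature,
    GenomeParseError,
    Mitogenome,
    extract_pcgs,
    feature_slice,
    normalize_gene_name,
    orient_to_cox1,
    read_fasta,
    read_genbank,
    read_trait_table,
    validate_completeness,
    write_gene_fastas,
)


@pytest.mark.parametrize(
    "raw, expected",
    [
        ("COI", "COX1"),
        ("cox1", "COX1"),
        ("CO1", "COX1"),
        ("ND4L", "NAD4L"),
        ("nad4l", "NAD4L"),
        ("cob", "CYTB"),
        ("CYTB", "CYTB"),
        ("ATPase6", "ATP6"),
        ("atp-6", "ATP6"),
        ("NADH dehydrogenase subunit 2", "NAD2"),
        ("hypothetical protein", "OTHER"),
        ("16S ribosomal RNA", "OTHER"),
    ],
)
def test_normalize_gene_name(raw, expected):
    assert normalize_gene_name(raw) == expected


def test_normalize_gene_name_user_synonyms_take_precedence():
    assert normalize_gene_name("mystery", extra={"Mystery": "NAD6"}) == "NAD6"


def _genome(seq, features, circular=True):
    return Mitogenome(id="t", sequence=seq, is_circular=circular, features=features)


def test_extract_minus_strand_reverse_complements():
    # genomic slice TTACATTGA on minus strand -> coding TCAATGTAA, terminal TAA
    g = _genome(
        "CC" + "TTACATTGA" + "GG",
        [GeneFeature("nad3", "NAD3", 2, 11, "-")],
    )
    (cds,) = extract_pcgs(g)
    assert cds.nt == "TCAATGTAA"
    assert cds.n_codons == 3
    assert cds.source_strand == "-"
    assert not cds.has_internal_stop


def test_extract_flags_internal_stop():
    g = _genome("ATTTAAATT", [GeneFeature("nad3", "NAD3", 0, 9, "+")])
    (cds,) = extract_pcgs(g)
    assert cds.has_internal_stop  # TAA at codon 2 of 3


def test_extract_truncates_trailing_partial_codon():
    g = _genome("ATGAAACCCG", [GeneFeature("nad3", "NAD3", 0, 10, "+")])
    (cds,) = extract_pcgs(g)
    assert cds.n_codons == 3
    assert cds.nt == "ATGAAACCC"


def test_extract_respects_codon_start_offset():
    g = _genome("GATGAAACCC", [GeneFeature("nad3", "NAD3", 0, 10, "+", frame_offset=1)])
    (cds,) = extract_pcgs(g)
    assert cds.nt == "ATGAAACCC"


def test_extract_origin_wrapping_feature():
    # gene occupies [8, 12) + [0, 5): slice is TTTTT... across the origin
    seq = "ATGGC" + "CCC" + "AAAA"
    g = _genome(seq, [GeneFeature("cox2", "COX2", 8, 5, "+", wraps_origin=True)])
    assert feature_slice(g, g.features[0]) == "AAAA" + "ATGGC"
    (cds,) = extract_pcgs(g)
    assert cds.nt == "AAAAATGGC"


def test_extract_rejects_duplicate_pcg_annotations():
    feats = [GeneFeature("cox1", "COX1", 0, 6, "+"), GeneFeature("COI", "COX1", 6, 12, "+")]
    with pytest.raises(GenomeParseError, match="duplicate"):
        extract_pcgs(_genome("ATGATGATGATG", feats))


def test_extract_rejects_sub_two_codon_cds():
    with pytest.raises(GenomeParseError, match="2 codons"):
        extract_pcgs(_genome("ATGCCC", [GeneFeature("nad3", "NAD3", 0, 4, "+")]))


def test_read_genbank_empty_file(tmp_path):
    path = tmp_path / "empty.gb"
    path.write_text("")
    assert read_genbank(path) == []


def test_orientation_rotates_cox1_to_zero(rng):
    L = 2000
    seq = "".join(rng.choice(list("ACGT"), L))
    feats = [
        GeneFeature("cox1", "COX1", 100, 1600, "+"),
        GeneFeature("trnA", "TRNA", 1700, 1760, "+"),
    ]
    g = _genome(seq, feats)
    rotated = orient_to_cox1(g)
    cox1 = next(f for f in rotated.features if f.norm_name == "COX1")
    assert (cox1.start, cox1.end) == (0, 1500)
    assert feature_slice(rotated, cox1) == feature_slice(g, g.features[0])
    # composition metrics are rotation-invariant
    for metric in (gc_skew, at_skew, pct_gc):
        assert metric(rotated.sequence) == pytest.approx(metric(seq))


def test_orientation_is_idempotent(rng):
    seq = "".join(rng.choice(list("ACGT"), 300))
    g = _genome(seq, [GeneFeature("cox1", "COX1", 0, 150, "+")])
    assert orient_to_cox1(g) is g


def test_orientation_handles_minus_strand_cox1(rng):
    seq = "".join(rng.choice(list("ACGT"), 600))
    g = _genome(seq, [GeneFeature("cox1", "COX1", 90, 390, "-")])
    before = extract_pcgs(g)[0].nt
    rotated = orient_to_cox1(g)
    cox1 = next(f for f in rotated.features if f.norm_name == "COX1")
    assert cox1.strand == "+"
    assert cox1.start == 0
    assert extract_pcgs(rotated)[0].nt == before


def test_orientation_refuses_non_circular():
    g = _genome("ATGATG", [GeneFeature("cox1", "COX1", 0, 6, "+")], circular=False)
    with pytest.raises(GenomeParseError, match="non-circular"):
        orient_to_cox1(g)


def test_orientation_requires_cox1():
    g = _genome("ATGATG", [GeneFeature("nad3", "NAD3", 0, 6, "+")])
    with pytest.raises(GenomeParseError, match="COX1"):
        orient_to_cox1(g)


def test_completeness_report_logic():
    feats = [GeneFeature(g, g, 10 * i, 10 * i + 6, "+") for i, g in enumerate(
        ["COX1", "COX2", "COX3", "CYTB", "NAD1", "NAD2", "NAD3", "NAD4",
         "NAD4L", "NAD5", "NAD6", "ATP6"]
    )]
    feats += [GeneFeature(f"t{i}", "TRNA", 200 + 2 * i, 202 + 2 * i, "+") for i in range(22)]
    feats += [GeneFeature(f"r{i}", "RRNA", 300 + 5 * i, 305 + 5 * i, "+") for i in range(2)]
    g = _genome("A" * 400, feats)
    rep = validate_completeness(g)
    assert (rep.n_pcgs, rep.n_trnas, rep.n_rrnas) == (12, 22, 2)
    assert rep.is_complete
    g_linear = _genome("A" * 400, feats, circular=False)
    assert not validate_completeness(g_linear).is_complete


def test_trait_table_roundtrip(tmp_path):
    cols = ("species_id class subclass order suborder infraorder superfamily "
            "family genus feeding_habit habitat reproduction").split()
    lines = ["\t".join(cols),
             "\t".join(["sp1"] + ["x"] * 8 + ["animal_parasite", "NA", "amphimictic"])]
    path = tmp_path / "traits.tsv"
    path.write_text("\n".join(lines) + "\n")
    table = read_trait_table(path)
    taxonomy, traits = table["sp1"]
    assert traits["feeding_habit"] == "animal_parasite"
    assert traits["habitat"] is None  # NA -> missing marker, not empty category
    assert taxonomy["genus"] == "x"


def test_trait_table_rejects_duplicates_and_missing_columns(tmp_path):
    cols = ("species_id class subclass order suborder infraorder superfamily "
            "family genus feeding_habit habitat reproduction").split()
    dup = tmp_path / "dup.tsv"
    dup.write_text("\n".join(["\t".join(cols)] + ["\t".join(["sp1"] + ["x"] * 11)] * 2))
    with pytest.raises(ValueError, match="duplicated"):
        read_trait_table(dup)
    short = tmp_path / "short.tsv"
    short.write_text("species_id\tclass\nsp1\tx\n")
    with pytest.raises(ValueError, match="habitat|subclass"):
        read_trait_table(short)


def test_gene_fasta_roundtrip(tmp_path):
    cdss = [
        CodingSequence("sp1", "COX1", "ATGAAATTT", "+", False),
        CodingSequence("sp2", "COX1", "ATGAAGTTT", "-", False),
        CodingSequence("sp1", "NAD3", "ATGCCC", "+", False),
    ]
    paths = write_gene_fastas(cdss, tmp_path)
    assert sorted(p.name for p in paths) == ["COX1.fasta", "NAD3.fasta"]
    back = read_fasta(tmp_path / "COX1.fasta")
    assert back == {"sp1": "ATGAAATTT", "sp2": "ATGAAGTTT"}


def test_reader_recovers_generator_genomes(dataset):
    outdir, truth = dataset
    files = sorted(Path(outdir, "genomes").glob("*.gb"))
    assert len(files) == len(truth.species)
    g = read_genbank(files[0])[0]
    assert g.is_circular
    assert validate_completeness(g).is_complete
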