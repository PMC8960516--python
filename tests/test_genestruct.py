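"""Gene-structure engine: intervals, CDS extraction, translation, alignment
optimality and determinism, deletion characterization, exon mapping."""

import itertools

import pytest
from hypothesis import given, strategies as st

from oryzatools import (
    AlignScoring,
    AlphabetError,
    AlignmentError,
    CoordinateError,
    DeletionReport,
    GeneModel,
    GenomicInterval,
    ModelError,
    align_global,
    boundary_deletion_length,
    characterize_deletion,
    deletion_events,
    exon1_protein_span,
    extract_cds,
    interval_length,
    map_exons,
    translate,
)
from helpers import enumerate_oracle_score, gotoh_oracle_score


# ---------------------------------------------------------------------------
# intervals
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "start,end,expected",
    [
        (40_361_934, 40_364_270, 2337),  # the sd1 locus
        (40_361_934, 40_362_421, 488),   # Sanger-validated exon-1 region
        (5, 5, 1),
    ],
)
def test_interval_length(start, end, expected):
    assert interval_length(GenomicInterval("chr1", start, end)) == expected


def test_inverted_interval_rejected():
    with pytest.raises(CoordinateError):
        GenomicInterval("chr1", 10, 9)


def test_locus_length_equals_exons_plus_introns(anchored_scenario, cds_scenario):
    for model in (
        anchored_scenario.ref_model,
        anchored_scenario.alt_model,
        cds_scenario.ref_model,
        cds_scenario.alt_model,
    ):
        total = sum(e.length for e in model.exons) + sum(
            i.length for i in model.introns
        )
        assert interval_length(model.locus) == total


# ---------------------------------------------------------------------------
# CDS extraction and translation
# ---------------------------------------------------------------------------

def _single_exon_model(chrom, start, end, strand="+"):
    iv = GenomicInterval(chrom, start, end, strand)
    return GeneModel("g1", "t1", iv, [iv], [iv])


def test_extract_cds_plus_strand_substring():
    genome = "AAACCCGGGTTTACGTACGT"
    model = _single_exon_model("c", 4, 9)
    assert extract_cds(genome, model) == "CCCGGG"


def test_extract_cds_minus_strand_two_segments_hand_checked():
    # genome (20 bp):      12345678901234567890
    genome = "ATGCATGCATGCATGCATGC"
    # minus-strand gene, exons at 3-8 and 13-17 (genomic), transcription
    # order is 13-17 then 3-8; hand enumeration:
    #   seg 13-17 = ATGCA -> revcomp TGCAT
    #   seg 3-8   = GCATGC -> revcomp GCATGC
    iv1 = GenomicInterval("c", 13, 17, "-")
    iv2 = GenomicInterval("c", 3, 8, "-")
    locus = GenomicInterval("c", 1, 20, "-")
    model = GeneModel("g1", "t1", locus, [iv1, iv2], [iv1, iv2])
    assert extract_cds(genome, model) == "TGCAT" + "GCATGC"


def test_extract_cds_out_of_bounds():
    with pytest.raises(CoordinateError):
        extract_cds("ACGT", _single_exon_model("c", 2, 10))


def test_derived_cds_intronized_and_deleted_components(cds_scenario):
    """The derived CDS lacks 363 nt of reference coding sequence: 280 nt
    deleted from the genome plus 83 nt decommissioned into the new intron."""
    ref_cds = extract_cds(cds_scenario.ref_genome, cds_scenario.ref_model)
    alt_cds = extract_cds(cds_scenario.alt_genome, cds_scenario.alt_model)
    assert len(ref_cds) - len(alt_cds) == 363
    assert cds_scenario.truth.cds_deletion_bp == 280
    assert cds_scenario.truth.intronic_deletion_bp == 83
    intron1 = cds_scenario.alt_model.introns[0]
    assert intron1.length == 83


@pytest.mark.parametrize(
    "cds,protein",
    [
        ("ATGGTG", "MV"),
        ("CAG", "Q"),   # glutamine in the tall reference...
        ("CGG", "R"),   # ...mutated to arginine in the semidwarfs
        ("TAA", "*"),
    ],
)
def test_translate_examples(cds, protein):
    assert translate(cds).protein == protein


def test_translate_synonymous_pair():
    assert translate("TAC").protein == translate("TAT").protein == "Y"


def test_translate_reports_trailing_partial_codon():
    t = translate("ATGGTGCC")
    assert t.protein == "MV"
    assert t.trailing == "CC"


def test_translate_rejects_ambiguity_and_short_input():
    with pytest.raises(AlphabetError):
        translate("ATGNNN")
    with pytest.raises(AlphabetError):
        translate("AT")


def test_translate_extract_roundtrip_from_known_protein():
    # build a two-exon gene encoding a known protein, with an intron
    protein = "MKVLFAE"
    codons = {
        "M": "ATG", "K": "AAA", "V": "GTT", "L": "CTG",
        "F": "TTT", "A": "GCC", "E": "GAA",
    }
    cds = "".join(codons[aa] for aa in protein) + "TAA"
    exon1, exon2 = cds[:10], cds[10:]
    intron = "GTAAGTTTTTTTAG"
    genome = "CCCC" + exon1 + intron + exon2 + "CCCC"
    e1 = GenomicInterval("c", 5, 5 + len(exon1) - 1)
    e2 = GenomicInterval("c", 5 + len(exon1) + len(intron),
                         5 + len(exon1) + len(intron) + len(exon2) - 1)
    model = GeneModel("g", "t", GenomicInterval("c", 5, e2.end), [e1, e2], [e1, e2])
    assert translate(extract_cds(genome, model)).protein == protein + "*"


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def test_identical_strings_align_without_gaps():
    aln = align_global("ACGTACGT", "ACGTACGT")
    assert aln.percent_identity == 100.0
    assert aln.row_a == aln.row_b == "ACGTACGT"
    assert aln.coverage_a == aln.coverage_b == 100.0


def test_align_global_rejects_empty_input():
    with pytest.raises(AlignmentError):
        align_global("", "ACGT")


def test_alignment_score_matches_dp_oracle_on_all_short_two_letter_inputs():
    """Optimality against an independent Gotoh DP for every pair of
    non-empty strings of length <= 6 over {A, C}."""
    sc = AlignScoring()
    strings = [
        "".join(t)
        for n in range(1, 7)
        for t in itertools.product("AC", repeat=n)
    ]
    for a in strings:
        for b in strings:
            got = align_global(a, b, sc).score
            want = gotoh_oracle_score(a, b, sc)
            assert got == pytest.approx(want), (a, b)


def test_alignment_score_matches_exhaustive_enumeration_on_tiny_inputs():
    sc = AlignScoring()
    strings = [
        "".join(t)
        for n in range(1, 5)
        for t in itertools.product("AG", repeat=n)
    ]
    import random

    rnd = random.Random(0)
    for _ in range(150):
        a, b = rnd.choice(strings), rnd.choice(strings)
        assert align_global(a, b, sc).score == pytest.approx(
            enumerate_oracle_score(a, b, sc)
        ), (a, b)


@given(
    a=st.text(alphabet="ACGT", min_size=1, max_size=12),
    b=st.text(alphabet="ACGT", min_size=1, max_size=12),
)
def test_alignment_rows_degap_to_inputs(a, b):
    aln = align_global(a, b)
    assert aln.row_a.replace("-", "") == a
    assert aln.row_b.replace("-", "") == b
    assert 0.0 <= aln.percent_identity <= 100.0
    assert 0.0 < aln.coverage_a <= 100.0


def test_anchored_pair_aligns_with_single_interrupted_block(anchored_scenario):
    """The engineered pair aligns with one reference-only block interrupted
    by exactly one matched column."""
    sc = anchored_scenario
    ref = sc.ref_genome[sc.ref_model.locus.start - 1: sc.ref_model.locus.end]
    alt = sc.alt_genome[sc.alt_model.locus.start - 1: sc.alt_model.locus.end]
    aln = align_global(ref, alt)
    events = deletion_events(aln, max_anchor_run=2)
    assert len(events) == 1
    assert events[0].anchored_bases == 1
    assert events[0].deleted_bp == 382
    assert events[0].columns == 383


# ---------------------------------------------------------------------------
# deletion characterization
# ---------------------------------------------------------------------------

def test_identical_gene_pair_gives_empty_report():
    genome = "TTTT" + "ATGGTTCCAGGCTAA" + "TTTT"
    model = _single_exon_model("c", 5, 19)
    rep = characterize_deletion(genome, model, genome, model)
    assert rep == DeletionReport()


def test_missing_cds_annotation_is_model_error():
    genome = "TTTTATGGTTCCAGGCTAATTTT"
    model = _single_exon_model("c", 5, 19)
    no_cds = GeneModel("g", "t", model.locus, model.exons, [])
    with pytest.raises(ModelError):
        characterize_deletion(genome, model, genome, no_cds)


# ---------------------------------------------------------------------------
# boundary arithmetic and exon-1 span
# ---------------------------------------------------------------------------

def test_boundary_deletion_length_worked_example():
    assert boundary_deletion_length(981, 599) == 382


def test_boundary_deletion_length_identity_and_error():
    assert boundary_deletion_length(1234, 1234) == 0
    with pytest.raises(CoordinateError):
        boundary_deletion_length(599, 981)


def test_boundary_arithmetic_matches_scenario_truth(anchored_scenario):
    ref_exon1 = anchored_scenario.ref_model.exons[0].length
    alt_exon1 = anchored_scenario.alt_model.exons[0].length
    assert (
        boundary_deletion_length(ref_exon1, alt_exon1)
        == anchored_scenario.truth.genomic_deletion_bp
    )


@pytest.mark.parametrize("length,expected", [(293, 98), (3, 1), (294, 98)])
def test_exon1_protein_span(length, expected):
    assert exon1_protein_span(length) == expected


def test_exon1_protein_span_rejects_zero():
    with pytest.raises(CoordinateError):
        exon1_protein_span(0)


# ---------------------------------------------------------------------------
# exon mapping
# ---------------------------------------------------------------------------

def _model_from_cds_layout(chrom, pieces):
    """pieces: list of ('exon'|'intron', length); returns (model, genome)."""
    import numpy as np

    rng = np.random.default_rng(42)
    exons, pos = [], 1
    seq = []
    for kind, length in pieces:
        if kind == "exon":
            exons.append(GenomicInterval(chrom, pos, pos + length - 1))
        seq.append("".join(rng.choice(list("ACGT"), size=length)))
        pos += length
    genome = "".join(seq)
    locus = GenomicInterval(chrom, 1, pos - 1)
    return GeneModel("g", "t", locus, exons, list(exons)), genome


def test_map_exons_identical_models_identity():
    model, genome = _model_from_cds_layout("c", [("exon", 30), ("intron", 20),
                                                 ("exon", 30)])
    prot = translate(extract_cds(genome, model)).protein
    aln = align_global(prot, prot)
    emap = map_exons(aln, model, model)
    assert emap.exon_gaps == []
    for b in emap.boundaries:
        assert b.other_protein_position == b.protein_position


def test_map_exons_one_vs_two_exon_same_protein():
    """Same protein, one model with an intron: boundary map is identity on
    the protein and the intron appears only in the second model."""
    cds = "ATGGTTCCAGGCGAATTGTAA"
    g1 = "AA" + cds + "AA"
    m1 = GeneModel(
        "g1", "t1", GenomicInterval("c", 3, 3 + len(cds) - 1),
        [GenomicInterval("c", 3, 3 + len(cds) - 1)],
        [GenomicInterval("c", 3, 3 + len(cds) - 1)],
    )
    intron = "GTTTTTAG"
    g2 = "AA" + cds[:10] + intron + cds[10:] + "AA"
    e1 = GenomicInterval("c", 3, 12)
    e2 = GenomicInterval("c", 13 + len(intron), 12 + len(intron) + len(cds) - 10)
    m2 = GeneModel("g2", "t2", GenomicInterval("c", 3, e2.end), [e1, e2], [e1, e2])
    p1 = translate(extract_cds(g1, m1)).protein
    p2 = translate(extract_cds(g2, m2)).protein
    assert p1 == p2
    emap = map_exons(align_global(p1, p2), m1, m2)
    assert emap.exon_gaps == []
    assert [b.model for b in emap.boundaries] == ["b"]
    assert emap.boundaries[0].other_protein_position == \
        emap.boundaries[0].protein_position
    assert emap.introns_a == [] and len(emap.introns_b) == 1


def test_map_exons_derived_pair_shows_one_exon_gap(cds_scenario):
    """The derived model shows a single exon-gap span (its lost coding
    region) overlapping its own exon-1/exon-2 junction."""
    sc = cds_scenario
    p_ref = translate(extract_cds(sc.ref_genome, sc.ref_model)).protein
    p_alt = translate(extract_cds(sc.alt_genome, sc.alt_model)).protein
    aln = align_global(p_ref, p_alt)
    emap = map_exons(aln, sc.ref_model, sc.alt_model)
    gaps = [g for g in emap.exon_gaps if g.missing_in == "b"]
    assert len(gaps) == 1
    gap = gaps[0]
    assert gap.other_protein_end - gap.other_protein_start + 1 == 121  # 363/3
    # the derived exon-1/exon-2 boundary (at aa 98) abuts the gap
    alt_boundary = [b for b in emap.boundaries if b.model == "b"][0]
    assert alt_boundary.protein_position == 98
    assert gap.other_protein_start == 99


def test_map_exons_rejects_inconsistent_translation(cds_scenario):
    sc = cds_scenario
    aln = align_global("MKV", "MKV")
    with pytest.raises(ModelError):
        map_exons(aln, sc.ref_model, sc.alt_model)
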