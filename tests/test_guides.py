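"""PAM scanning against an exhaustive oracle; selection policy; cloning oligos."""

import numpy as np
import pytest

from genomecut.guides import (
    GuideSelectionError,
    annealed_core_mismatches,
    count_occurrences,
    make_cloning_oligos,
    pam_matches,
    scan_pams,
    select_guides,
)
from genomecut.model import AnnotatedGenome, CandidateRegion, GeneRecord, revcomp
from genomecut.regions import find_regions


def exhaustive_scan_oracle(seq, region_start, region_end, spacer_len=22):
    """Sliding-window re-derivation of every TTN site on both strands."""
    sites = set()
    for i in range(region_start, region_end - (3 + spacer_len) + 1):
        if seq[i : i + 2] == "TT":
            sites.add(("+", i, seq[i + 3 : i + 3 + spacer_len]))
    for j in range(region_start + spacer_len, region_end - 3 + 1):
        # minus-strand TTN: top strand reads N,A,A at [j, j+3)
        if seq[j + 1 : j + 3] == "AA":
            sites.add(("-", j - spacer_len, revcomp(seq[j - spacer_len : j])))
    return sites


def region_genome(seq):
    genes = [GeneRecord("G_0001", 0, len(seq), "+", "nonessential")]
    genome = AnnotatedGenome("toy", seq, genes, circular=False)
    region = CandidateRegion(0, len(seq), ("G_0001",))
    return genome, region


def test_scan_pams_matches_exhaustive_oracle_on_toy_region():
    rng = np.random.default_rng(17)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 60)])
    genome, region = region_genome(seq)
    got = {(g.strand, g.footprint_start, g.protospacer) for g in scan_pams(genome, region)}
    assert got == exhaustive_scan_oracle(seq, 0, 60)


def test_scan_pams_matches_oracle_on_random_regions(small_genome):
    genome, truth = small_genome
    for region in truth.planted_regions:
        got = {
            (g.strand, g.footprint_start, g.protospacer)
            for g in scan_pams(genome, region)
        }
        assert got == exhaustive_scan_oracle(genome.sequence, region.start, region.end)


def test_no_tt_sequence_yields_no_guides():
    genome, region = region_genome("ACAG" * 20)
    assert scan_pams(genome, region) == []


def test_region_too_short_warns_and_returns_empty():
    genome, region = region_genome("TTACGTACGTACGTACGTAC")  # 20 < 25
    with pytest.warns(UserWarning, match="shorter"):
        assert scan_pams(genome, region) == []


def test_every_protospacer_is_22nt_and_inside_region(small_genome):
    genome, truth = small_genome
    for region in truth.planted_regions:
        for g in scan_pams(genome, region):
            assert len(g.protospacer) == 22
            assert g.pam_seq[:2] == "TT"
            assert region.start <= g.footprint_start < g.footprint_end <= region.end


def test_hit_count_counts_both_strands():
    # site occurs once forward; its reverse complement elsewhere adds a hit
    core = "TTA" + "ACGTACGTACGTACGTACGTAC"
    seq = "GGGCGC" + core + "GCGCCC" + revcomp(core) + "GGGCC"
    genome, region = region_genome(seq)
    guides = [g for g in scan_pams(genome, region) if g.site_seq == core]
    assert guides and guides[0].genome_hit_count == 2


def test_selection_prefers_unique_guides():
    rng = np.random.default_rng(5)
    filler = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 200)])
    dup = "TTG" + "CAGCAGATCGATCGGATGCACT"
    seq = filler[:50] + dup + filler[50:120] + dup + filler[120:]
    genome, region = region_genome(seq)
    cands = scan_pams(genome, region)
    assert any(g.genome_hit_count > 1 for g in cands)
    selected = select_guides(cands, k=2)
    assert all(g.genome_hit_count == 1 for g in selected)


def test_selection_errors_when_too_few_unique():
    dup = "TTG" + "CAGCAGATCGATCGGATGCACT"
    seq = ("GCGC" + dup) * 2 + "GCGC"
    genome, region = region_genome(seq)
    cands = [g for g in scan_pams(genome, region) if g.site_seq == dup]
    with pytest.raises(GuideSelectionError, match="require_unique"):
        select_guides(cands, k=1)


def test_selected_guides_near_both_region_ends(small_genome):
    genome, truth = small_genome
    region = truth.planted_regions[0]
    sel = select_guides(scan_pams(genome, region), k=2)
    assert len(sel) == 2
    third = region.length_bp / 3
    assert sel[0].footprint_start < region.start + third
    assert sel[1].footprint_end > region.end - third


def test_selection_deterministic(small_genome):
    genome, truth = small_genome
    region = truth.planted_regions[0]
    a = select_guides(scan_pams(genome, region), k=2)
    b = select_guides(scan_pams(genome, region), k=2)
    assert a == b


def test_iupac_pam_patterns():
    assert pam_matches("TTA", "TTN")
    assert pam_matches("TTTC", "TTTV")
    assert not pam_matches("TTTT", "TTTV")  # V excludes T
    genome, region = region_genome("TTTC" + "A" * 22 + "GGGGG" * 4)
    strict = scan_pams(genome, region, pam="TTTV", spacer_len=22)
    assert [(g.strand, g.pam_seq) for g in strict] == [("+", "TTTC")]


def test_cloning_oligos_anneal_perfectly():
    genome, region = region_genome("TTG" + "ACGT" * 8)
    guide = scan_pams(genome, region, spacer_len=22)[0]
    pair = make_cloning_oligos(guide, overhangs=("ACGT", "TTAA"))
    assert annealed_core_mismatches(pair) == 0
    assert pair.core == guide.pam_seq + guide.protospacer
    # duplex length contract: core + one 4-nt overhang per oligo
    assert len(pair.top_oligo) == 4 + 25
    assert len(pair.bottom_oligo) == 4 + 25
    assert pair.bottom_oligo[4:] == revcomp(pair.top_oligo[4:])


def test_bad_overhangs_rejected():
    genome, region = region_genome("TTG" + "ACGT" * 8)
    guide = scan_pams(genome, region)[0]
    with pytest.raises(ValueError, match="4-nt"):
        make_cloning_oligos(guide, overhangs=("ACG", "TTAA"))


def test_count_occurrences_is_overlapping():
    assert count_occurrences("AAAA", "AA") == 3


def test_seed_check_rejects_guides_with_repeated_seed_region():
    # two sites share PAM + first 8 nt of spacer but diverge afterwards:
    # full-length unique, seed-region not
    seed8 = "GATCGACT"
    a = "TTG" + seed8 + "ACGTACGTACGTAC"
    b = "TTG" + seed8 + "TGCATGCATGCATG"
    rng = np.random.default_rng(44)
    filler = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 120)])
    genome, region = region_genome(filler[:40] + a + filler[40:80] + b + filler[80:])
    cands = [g for g in scan_pams(genome, region) if g.site_seq in (a, b)]
    assert all(g.genome_hit_count == 1 for g in cands)
    with pytest.raises(GuideSelectionError, match="seed_check"):
        select_guides(
            cands, k=1, seed_check=8, genome_seq=genome.sequence
        )
    # with a longer seed the two sites are distinguishable again
    assert select_guides(cands, k=1, seed_check=12, genome_seq=genome.sequence)
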