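"""Arms, fusion PCR simulation, genotyping discrimination, in-silico PCR oracle."""

import numpy as np
import pytest

from genomecut.constructs import (
    ConstructConfig,
    FusionPrimer,
    InsufficientFlankError,
    PrimerDesignError,
    design_arms,
    design_editing_construct,
    design_fusion_primers,
    design_genotyping_primers,
    find_cloning_site_hits,
    insilico_pcr,
    simulate_fusion_pcr,
)
from genomecut.model import AnnotatedGenome, CandidateRegion, GeneRecord, revcomp
from genomecut.plans import apply_step
from genomecut.regions import filter_regions, find_regions


def test_arm_coordinates_are_exact(design_genome):
    genome, truth = design_genome
    region = truth.planted_regions[0]
    up, down = design_arms(genome, region, arm_bp=1000)
    assert (up.start, up.end) == (region.start - 1000, region.start)
    assert (down.start, down.end) == (region.end, region.end + 1000)
    # string-slice oracle: arms are exactly the WT flanks of the excised region
    wt = genome.sequence
    excised = wt[: region.start] + wt[region.end :]
    window = excised[region.start - 1000 : region.start + 1000]
    assert up.seq + down.seq == window


def test_arm_too_close_to_end_of_linear_genome_errors():
    genes = [GeneRecord("G1", 100, 600, "+", "nonessential")]
    genome = AnnotatedGenome("t", "ACGT" * 500, genes, circular=False)
    region = CandidateRegion(100, 600, ("G1",))
    with pytest.raises(InsufficientFlankError):
        design_arms(genome, region, arm_bp=500)


def test_arms_wrap_origin_on_circular_genome():
    rng = np.random.default_rng(2)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 2000)])
    genes = [GeneRecord("G1", 100, 600, "+", "nonessential")]
    genome = AnnotatedGenome("t", seq, genes, circular=True)
    region = CandidateRegion(100, 600, ("G1",))
    up, _ = design_arms(genome, region, arm_bp=300)
    assert up.seq == seq[-200:] + seq[:100]


def test_fusion_pcr_reconstructs_arm_junction(design_genome):
    genome, truth = design_genome
    region = truth.planted_regions[1]
    arms = design_arms(genome, region, arm_bp=800)
    primers = design_fusion_primers(arms, ConstructConfig(arm_bp=800))
    fused = simulate_fusion_pcr(genome.sequence, primers)
    assert fused == arms[0].seq + arms[1].seq


def test_fusion_pcr_inserts_payload_between_arms(design_genome):
    genome, truth = design_genome
    region = truth.planted_regions[1]
    arms = design_arms(genome, region, arm_bp=800)
    payload = genome.sequence[region.start + 500 : region.start + 1700]
    primers = design_fusion_primers(arms, ConstructConfig(arm_bp=800), payload)
    fused = simulate_fusion_pcr(genome.sequence, primers, payload_seq=payload)
    assert fused == arms[0].seq + payload + arms[1].seq


def test_fusion_without_tails_gives_no_product(design_genome):
    genome, truth = design_genome
    region = truth.planted_regions[1]
    arms = design_arms(genome, region, arm_bp=800)
    primers = design_fusion_primers(arms, ConstructConfig(arm_bp=800))
    untailed = [FusionPrimer(p.name, p.anneal_seq, "", p.tm) for p in primers]
    assert simulate_fusion_pcr(genome.sequence, untailed) is None


def test_fusion_primer_tails_are_reciprocal(design_genome):
    genome, truth = design_genome
    region = truth.planted_regions[0]
    arms = design_arms(genome, region, arm_bp=800)
    cfg = ConstructConfig(arm_bp=800, tail_len=20)
    upF, upR, dnF, dnR = design_fusion_primers(arms, cfg)
    assert upF.tail == "" and dnR.tail == ""
    assert upR.tail == revcomp(arms[1].seq[:20])
    assert dnF.tail == arms[0].seq[-20:]


def test_insilico_pcr_constructed_template():
    fwd = "ACGTACGTACGTACGTAC"
    rev = "GGATCCGGATCCGGATCC"
    template = fwd + "T" * 100 + revcomp(rev)
    products = insilico_pcr(template, fwd, rev)
    assert len(products) == 1
    assert products[0].length == len(template)
    assert products[0].seq == template
    assert insilico_pcr("A" * 200, fwd, rev) == []


def test_insilico_pcr_rejects_short_primers():
    with pytest.raises(ValueError, match=">= 15"):
        insilico_pcr("A" * 100, "ACGT", "ACGTACGTACGTACG")


def test_insilico_pcr_matches_brute_force_oracle():
    rng = np.random.default_rng(31)
    bases = np.array(list("ACGT"))
    template = "".join(bases[rng.integers(0, 4, 50_000)])
    rc_template = revcomp(template)
    for _ in range(100):
        # half the primers are sampled from the template so products exist
        if rng.random() < 0.5:
            i = int(rng.integers(0, len(template) - 4000))
            fwd = template[i : i + 20]
            j = int(rng.integers(i + 20, i + 4000))
            rev = revcomp(template[j : j + 20])
        else:
            fwd = "".join(bases[rng.integers(0, 4, 18)])
            rev = "".join(bases[rng.integers(0, 4, 18)])
        got = {(a.start, a.end) for a in insilico_pcr(template, fwd, rev)}
        # oracle: test all (i, j) binding-position pairs by string matching
        fpos = [
            k for k in range(len(template) - len(fwd) + 1)
            if template[k : k + len(fwd)] == fwd
        ]
        rc = revcomp(rev)
        rpos = [
            k for k in range(len(template) - len(rc) + 1)
            if template[k : k + len(rc)] == rc
        ]
        expected = {
            (i, j + len(rc))
            for i in fpos
            for j in rpos
            if j >= i + len(fwd) and j + len(rc) - i <= 5000
        }
        assert got == expected


def test_insilico_pcr_tolerates_5prime_mismatches_when_asked():
    rng = np.random.default_rng(9)
    template = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 2000)])
    fwd = template[100:120]
    rev = revcomp(template[600:620])
    # corrupt one base well outside the 3'-terminal 8 nt of each primer
    fwd_mut = fwd[:2] + ("A" if fwd[2] != "A" else "C") + fwd[3:]
    rev_mut = rev[:3] + ("G" if rev[3] != "G" else "T") + rev[4:]
    assert insilico_pcr(template, fwd_mut, rev_mut) == []
    relaxed = insilico_pcr(template, fwd_mut, rev_mut, allow_5prime_mismatches=1)
    assert [(a.start, a.end) for a in relaxed] == [(100, 620)]


def test_genotyping_discrimination_on_synthetic_deletion(design_genome):
    genome, truth = design_genome
    region = truth.planted_regions[2]
    construct = design_editing_construct(genome, region)
    edited = apply_step(genome, construct)
    fr = construct.genotype_primers["FR"]
    fprp = construct.genotype_primers["FpRp"]
    # F/R: wild type only
    wt_products = insilico_pcr(genome.sequence, fr.fwd_seq, fr.rev_seq)
    assert [a.length for a in wt_products] == [fr.expected_wt_bp]
    assert insilico_pcr(edited.sequence, fr.fwd_seq, fr.rev_seq) == []
    # F'/R': mutant only, exactly one junction product of the predicted size
    assert insilico_pcr(genome.sequence, fprp.fwd_seq, fprp.rev_seq) == []
    mut_products = insilico_pcr(edited.sequence, fprp.fwd_seq, fprp.rev_seq)
    assert [a.length for a in mut_products] == [fprp.expected_mut_bp]
    # junction fidelity: the product is the spliced upstream+downstream WT DNA
    junction = (
        genome.sequence[fprp.fwd_pos : region.start]
        + genome.sequence[region.end : fprp.rev_pos]
    )
    assert mut_products[0].seq == junction


def test_genotyping_rejects_region_too_small_for_size_split():
    rng = np.random.default_rng(8)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 30_000)])
    genes = [GeneRecord("G1", 10_000, 12_000, "+", "nonessential")]
    genome = AnnotatedGenome("t", seq, genes, circular=False)
    region = CandidateRegion(10_000, 12_000, ("G1",))
    with pytest.raises(PrimerDesignError, match="too small"):
        design_genotyping_primers(genome, region)


def test_primer_constraints_hold(design_genome):
    genome, truth = design_genome
    cfg = ConstructConfig()
    construct = design_editing_construct(genome, truth.planted_regions[0], cfg=cfg)
    for pair in construct.genotype_primers.values():
        for seq in (pair.fwd_seq, pair.rev_seq):
            assert cfg.primers.min_len <= len(seq) <= cfg.primers.max_len
        assert cfg.primers.tm_min <= pair.tm_fwd <= cfg.primers.tm_max
        assert cfg.primers.tm_min <= pair.tm_rev <= cfg.primers.tm_max
        assert abs(pair.tm_fwd - pair.tm_rev) <= cfg.primers.max_delta_tm


def test_cloning_site_check_flags_bamhi():
    from genomecut.constructs import HomologyArm

    arm = HomologyArm("up", 0, 30, "AAAAGGATCCAAAAAAAAAAAAAAAAAAAA")
    clean = HomologyArm("down", 30, 60, "ACGT" * 7 + "AC")
    assert find_cloning_site_hits((arm, clean)) == ["up:GGATCC"]
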