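"""Design one complete deletion: guides, oligos, arms, primers, and checks.

For a single candidate region this designs the two Cpf1 guides (TTN PAM,
22-nt spacer, unique in the genome), their AarI-adapter cloning oligos, the
1 kb homology arms with fusion-PCR primers, and the two genotyping pairs —
then verifies the design in silico: the fused donor reconstructs the arms,
F/R amplifies only the wild type, and F'/R' only the deletion mutant.
"""

from genomecut import (
    apply_step,
    design_editing_construct,
    filter_regions,
    find_regions,
    gen_genome,
    insilico_pcr,
    simulate_fusion_pcr,
)

genome, _ = gen_genome(n_genes=80, region_size_targets=[12_000], seed=7)
region = filter_regions(find_regions(genome), 10_000)[0]
construct = design_editing_construct(genome, region, marker="Km")

print(f"region {region.name}: {region.length_bp:,} bp")
for g in construct.guides:
    print(f"  guide {g.strand} @ {g.footprint_start:,}: PAM {g.pam_seq} + "
          f"{g.protospacer} (GC {g.gc_fraction:.2f}, genome hits "
          f"{g.genome_hit_count})")
for o in construct.oligos:
    print(f"  oligo top    5'-{o.top_oligo}-3'")
    print(f"  oligo bottom 5'-{o.bottom_oligo}-3'")
print(f"  arms: up [{construct.arm_up.start:,}, {construct.arm_up.end:,}), "
      f"down [{construct.arm_down.start:,}, {construct.arm_down.end:,})")

# two-step fusion PCR in silico: the donor is exactly up-arm + down-arm
donor = simulate_fusion_pcr(genome.sequence, construct.fusion_primers)
assert donor == construct.arm_up.seq + construct.arm_down.seq
print(f"  fused donor: {len(donor):,} bp (arms joined seamlessly)")

# genotyping: sizes as a gel would show them
edited = apply_step(genome, construct)
fr = construct.genotype_primers["FR"]
fprp = construct.genotype_primers["FpRp"]
for name, pair in [("F/R", fr), ("F'/R'", fprp)]:
    wt = [a.length for a in insilico_pcr(genome.sequence, pair.fwd_seq, pair.rev_seq)]
    mut = [a.length for a in insilico_pcr(edited.sequence, pair.fwd_seq, pair.rev_seq)]
    print(f"  {name}: WT products {wt or 'none'}, mutant products {mut or 'none'}")
# F/R gives a band on the wild type only (its template is deleted in the
# mutant); F'/R' gives a short junction band only once the region is gone.
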