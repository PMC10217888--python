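"""Plan a stepwise multi-deletion campaign with alternating Km/Sp markers.

Builds a seven-step plan (one editing construct per region, designed against
the predicted genome at each step), applies it, and also shows a
deletion-replacement construct that removes a span while retaining an
interior gene on the donor.
"""

from genomecut import (
    apply_plan,
    apply_step,
    build_plan,
    build_replacement_construct,
    filter_regions,
    find_regions,
    gen_genome,
)

targets = [11_000, 12_500, 14_000, 10_500, 13_000, 15_000, 11_800]
genome, _ = gen_genome(n_genes=150, region_size_targets=targets, seed=19)
regions = filter_regions(find_regions(genome), 10_000)

plan = build_plan(genome, regions, start_marker="Km")
print(f"wild type: {len(genome):,} bp; {len(plan.steps)} deletion steps")
for s in plan.steps:
    print(f"  step {s.index}: delete {s.construct.region.name} "
          f"({s.construct.region.length_bp:,} bp) with the {s.marker} plasmid "
          f"-> {s.predicted_genome_bp:,} bp "
          f"({100 * s.cumulative_reduction_fraction:.2f}% removed)")
edited = apply_plan(genome, plan)
print(f"final predicted genome: {len(edited):,} bp "
      f"(reduced by {100 * plan.final_reduction_fraction:.2f}%)")

# deletion-replacement: remove a whole span but keep one interior gene
region = regions[0]
keep = region.member_locus_tags[2]
construct = build_replacement_construct(
    genome, region.start, region.end, [keep], flank_bp=200
)
replaced = apply_step(genome, construct)
g = genome.gene(keep)
print(f"replacement: span {region.name} removed, {keep} retained "
      f"({construct.payload[0].source_end - construct.payload[0].source_start:,} bp "
      f"payload incl. flanks); gene present "
      f"{replaced.sequence.count(genome.sequence[g.start:g.end])}x afterwards")
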