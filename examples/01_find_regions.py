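"""Find large contiguous nonessential regions in an annotated genome.

Builds a synthetic chromosome whose genes carry essential / beneficial /
nonessential labels (with three large nonessential runs planted), then
enumerates all maximal nonessential runs and keeps those over 10 kb — the
deletion candidates of a genome-reduction campaign.
"""

from genomecut import filter_regions, find_regions, gen_genome, region_stats

genome, truth = gen_genome(
    n_genes=200, region_size_targets=[12_000, 15_500, 11_200], seed=42
)
regions = find_regions(genome)               # every maximal nonessential run
over_10kb = filter_regions(regions, 10_000)  # strictly over 10 kb
stats = region_stats(regions, over_10kb, len(genome))

print(f"chromosome: {len(genome):,} bp, {len(genome.genes)} genes")
print(f"nonessential runs: {stats.n_regions_total}")
print(f"over 10 kb: {stats.n_regions_over_threshold}, "
      f"{stats.total_bp_over_threshold:,} bp "
      f"({stats.percent_of_genome}% of the chromosome)")
for r in over_10kb:
    print(f"  {r.name}: [{r.start:,}, {r.end:,}) {r.length_bp:,} bp, "
          f"{len(r.member_locus_tags)} genes, flanked by "
          f"{r.left_flank_tag}/{r.right_flank_tag}")

# The percentage is the fraction of the chromosome that could be removed by
# deleting every over-10 kb run; the planted regions come back exactly.
assert {(r.start, r.end) for r in truth.planted_regions} == {
    (r.start, r.end) for r in over_10kb
}
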