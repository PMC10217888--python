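# genomecut

Design and verification toolkit for CRISPR/Cpf1 (Cas12a)-driven
large-fragment genome reduction in bacteria, built around the workflow used
to streamline the chromosome of the cyanobacterium *Synechococcus elongatus*:
polyploid chromosomes, a replicative editing plasmid that keeps cleaving
unedited copies, and stepwise deletion of large nonessential regions with
alternating selection markers.

It is aimed at people planning a reduction campaign on an annotated genome
with per-gene essentiality calls (from transposon mutagenesis or similar),
and at people who want the downstream verification arithmetic — in-silico
genotyping, FPKM, differential expression, segregation checks — in one
reproducible place.

## What it does

Given a genome (FASTA), gene models (GFF3) and a three-way essentiality
table (`essential` / `beneficial` / `nonessential`):

1. **Region finding** — enumerate every maximal run of consecutive
   nonessential genes (essential, beneficial and unlabeled genes break runs;
   a nonessential gene overlapping a breaker is poisoned) and keep runs over
   a size threshold (default strictly > 10 kb). Summary statistics report
   count, total bp and percent of the chromosome.
2. **Guide design** — scan each region for Cpf1 sites: `TTN` PAM with the
   22 nt immediately 3′ of it as the protospacer, on both strands. Two
   guides per region are selected (unique full-length genome match
   mandatory, GC 0.3–0.7 preferred, one guide near each region end), and
   each is emitted as an annealing-oligo pair with 4-nt sticky ends for an
   AarI-digested vector. Because both cut sites lie inside the deletion, the
   repaired chromosome is no longer a target — which is what lets the
   replicative plasmid drive segregation in a polyploid cell.
3. **Construct design** — 1 kb homology arms abutting the region; four
   fusion-PCR primers (outer primers at the distal arm ends, inner primers
   with reciprocal 20-nt tails so the two arm amplicons overlap-extend into
   one donor); two genotyping pairs: `F/R` inside the region (band on wild
   type only) and `F′/R′` across the junction (band ≤ 5 kb only once the
   region is gone — on the wild type the same pair would have to span the
   whole region and yields nothing). All of it verified by exact-match
   in-silico PCR.
4. **Campaign planning** — an ordered multi-step plan, one region per step,
   Km/Sp markers alternating so each editing plasmid can be selected after
   the previous one is cured; the predicted genome (sequence + lifted
   annotations) is recomputed at every step. Regions interrupted by isolated
   essential genes are handled by deletion-replacement: the retained genes
   (with native flanks) come back as a payload between the arms, and guides
   are placed so the donor is not re-cut.
5. **Expression verification** — FPKM
   (`counts x 1e9 / (gene_kb x library_size)`), the stated DEG criterion
   (pooled two-sided Fisher's exact test per gene, Benjamini–Hochberg FDR
   < 0.05, fold change > 2 on pseudocounted FPKM means), DEG summaries
   (up/down counts, > 32-fold subset, per-set mean FPKM), and per-region
   segregation verdicts from residual expression in deleted regions.
6. **Synthetic data** — seeded generators for essentiality-annotated genomes
   with planted nonessential runs of exact sizes and negative-binomial count
   matrices with planted fold changes and deletion leakage, so the whole
   pipeline is testable without any external dataset.

## Worked example

```bash
python examples/01_find_regions.py
```

```
chromosome: 258,723 bp, 241 genes
nonessential runs: 55
over 10 kb: 3, 38,700 bp (14.96% of the chromosome)
  0064-0074: [68,466, 80,466) 12,000 bp, 11 genes, flanked by SYN_0063/SYN_0075
  0083-0096: [92,235, 107,735) 15,500 bp, 14 genes, flanked by SYN_0082/SYN_0097
  0141-0150: [153,524, 164,724) 11,200 bp, 10 genes, flanked by SYN_0140/SYN_0151
```

Each line is one deletion candidate: a maximal nonessential run named by its
first and last member locus tags, its coordinates and size, and the nearest
non-deletable gene on each side. The header line is the genome-reduction
budget: how much of the chromosome sits in over-10 kb nonessential runs.

The other examples design a complete deletion construct and check its
genotyping logic (`02_design_deletion.py`), build and apply a seven-step
alternating-marker campaign (`03_plan_campaign.py`), and run the
FPKM/DEG/segregation verification on simulated counts
(`04_expression_verification.py`).

The same stages are available as a CLI for shell use:

```bash
genomecut simulate --seed 4 --n-genes 60 --targets 12000,11000 --out-dir fix/
genomecut find-regions --fasta fix/genome.fasta --gff fix/genome.gff3 \
    --essentiality fix/essentiality.tsv --min-kb 10 --out regions.bed
genomecut run --out-dir out/        # full pipeline on a synthetic genome
```

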