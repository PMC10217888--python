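# Methods

This note records the models, conventions and deliberate choices behind
`genomecut`, in the spirit of a methods supplement: what is computed, under
which assumptions, and where the genuinely open design decisions were made.

## Coordinates and data model

All internal coordinates are 0-based half-open; conversion happens only at
the I/O boundary (GFF3 is 1-based inclusive on disk, BED6 0-based
half-open). Genomes are single chromosomes; the circular flag is honored by
sequence slicing (homology arms may wrap the origin) but region and guide
search never wrap the origin, and origin-spanning *edits* are rejected —
campaigns on real chromosomes do not need them and supporting them would
complicate every downstream coordinate lift for no practical gain.

Essentiality is a three-way label (essential / beneficial / nonessential)
plus `unknown` for genes absent from the table. Unrecognized category
strings are an error, never coerced: silent mapping hides data problems.

## Region finding

A candidate region is a maximal run of consecutive deletable genes.
Deletable defaults to exactly the `nonessential` class: beneficial genes
break runs (deleting them costs fitness; a flag relaxes this), unlabeled
genes break runs (the safe reading of missing evidence), and a nonessential
gene whose interval overlaps a breaker gene is itself poisoned, because its
DNA cannot be removed without touching the breaker.

Region span defaults to the **gene extent** (start of the first member to
end of the last member). The alternative, end of the left breaker to start
of the right breaker, is available as `span="inter-breaker"`; it adds the
flanking intergenic DNA. Gene extent is the conservative, unambiguous
choice. The size filter is strict (`> min_bp`): an "over 10 kb" region of
exactly 10,000 bp is excluded.

The enumeration is tested for exact equivalence against an O(n²)
brute-force window oracle on hundreds of random label sequences, including
genomes with overlapping gene models.

## Guide design

PAM is `TTN` with a 22-nt protospacer immediately 3′ of it on the PAM
strand — the permissive Cpf1 PAM; stricter patterns (e.g. `TTTV`) can be
given as IUPAC strings. Off-target assessment is exact full-length matching
of PAM+protospacer against both strands of the genome: uniqueness
(`genome_hit_count == 1`) is the mandatory selection filter. This is the
defensible minimum, not a mismatch-tolerant activity model; an optional
seed-region check additionally requires the PAM plus the PAM-proximal N-mer
to be unique.

Selection places one guide near each region end (anchors evenly spaced for
k > 2), preferring GC in [0.3, 0.7], with deterministic tie-breaking. Both
cut sites inside the deletion encode the central biological contract: the
repaired chromosome carries neither target, so the replicative editing
plasmid keeps cleaving only unedited copies and drives segregation.

Cloning oligos rebuild PAM+spacer as an annealed duplex with two 4-nt 5′
overhangs. AarI cuts outside its recognition site, so the overhang
sequences are a property of the vector stock; the defaults are documented
placeholders and must be set to match the actual vector.

## Construct design

Homology arms default to 1000 bp (configurable 100–3000) and abut the
region exactly. Arms are screened for BamHI/BglII sites (the vector cloning
window); hits produce a warning and are recorded on the construct.

Primer melting temperatures come from Biopython's nearest-neighbor
calculation (`MeltingTemp.Tm_NN`, default SantaLucia parameters, 50 mM Na+,
25 nM strands). Genotyping primers are searched in a ±60 nt window around
their nominal anchor with lengths 18–28 nt, Tm 55–65 °C, pairwise ΔTm ≤
3 °C, 3′-terminal G/C preferred, best-first deterministic scan. Fusion
primers are a special case: their anchors are fixed at the exact arm ends
(so the fused donor reconstructs the arms base-for-base), leaving length as
the only degree of freedom; they are therefore allowed 16–45 nt, which on
AT- or GC-skewed arm ends is what makes the Tm window reachable at all.
Inner fusion primers carry reciprocal 20-nt 5′ tails (reverse complement of
the start of the next fragment, and the end of the previous fragment), so
the two arm amplicons — and the payload, when present — share terminal
overlaps for the second-step PCR. The two-step PCR is simulated literally
(tailed amplification, then largest-exact-overlap extension) and tested to
reconstruct `up + (payload) + down` exactly, with the no-tail case as a
negative control.

Genotyping geometry: `F/R` anneal ~300 bp into the region with a ~800 bp
product; `F′/R′` anneal ~1200 bp outside each junction. The mutant junction
product must be ≤ `max_amplicon` (default 5000 bp, a proxy for what a
standard extension time amplifies) while the wild-type product spans the
whole region and exceeds it, hence is reported as absent. Regions too small
for that size split are rejected rather than given ambiguous primers.

In-silico PCR uses exact full-length primer matching on the top strand
(forward) and bottom strand (reverse), all products ≤ `max_amplicon`,
sorted; no match is an empty list, not an error. An optional relaxed mode
tolerates N mismatches outside the 3′-terminal 8 nt of each primer,
mirroring how tailed primers behave on a template. Exact matching is what
makes the predictor testable against a trivial string-matching oracle.

## Campaign planning

Steps alternate the Km and Sp resistance markers (plasmid curing between
steps is assumed, not modeled). Default ordering is the input order, with
`size-desc` offered; for disjoint regions the final genome is
order-independent, which the tests assert. Each step's construct is
designed against the predicted genome at that step: coordinates are
re-derived from the lifted annotation rather than offset lazily, and
`apply_step` verifies the arms base-for-base against the current genome
first, so a stale plan fails loudly (`ArmMismatchError`) instead of
splicing the wrong DNA. Genes inside (or straddling) a deleted span are
dropped; downstream genes shift; retained payload genes are re-annotated at
their new positions.

Deletion-replacement builds a construct whose payload is the retained
interior essential genes, each padded with 200 bp of native flanking DNA in
genomic order. The padding is a heuristic for carrying native promoters —
a declared biological risk, not a guarantee of expression — and guides are
constrained to avoid the retained (padded) source intervals so the edited
chromosome is not re-cut.

## Expression verification

FPKM uses the gene-assigned library size: `FPKM[g,s] = counts[g,s] x 1e9 /
(length_bp[g] x column_total[s])`, with the per-sample total summed over
the genes of the matrix (not a separate all-mapped-reads total). The
normalization identity `sum_g FPKM x kb = 1e6` is asserted numerically.

DEG calling implements the stated criterion literally: replicate counts are
pooled per condition; each gene gets a 2x2 table (gene vs rest-of-library
in each condition) tested with the two-sided Fisher's exact test under the
probability-summation convention (all tables no more likely than observed);
Benjamini–Hochberg adjustment runs over all quantified genes; fold change
is `(mean_FPKM_b + 1) / (mean_FPKM_a + 1)` — the 1-FPKM pseudocount tames
near-zero baselines, which are common — and calls are strict (`fc > 2`,
`q < 0.05`; a gene at exactly 2-fold is not called). Deleted genes are
tested but flagged and left out of downregulated counts, since their loss
is the edit itself. A `per_replicate` variant (Bonferroni-adjusted minimum
Fisher p over replicate pairings) is available as a robustness check.

Two caveats are part of the model, asserted by the tests rather than
hidden. First, the pooled Fisher test is a test of pooled proportions: it
is well calibrated under a Poisson null (the suite checks the q < 0.05
fraction on a 2000-gene, 3-vs-3 null simulation) but anticonservative under
negative-binomial overdispersion — on real replicated data a count model is
the better tool; this module reimplements the stated criterion, not
Cuffdiff. Second, FPKM is compositional: planting strong upregulations
depresses every other gene's FPKM, which can produce apparent
downregulation with no count change.

Segregation verdicts are per deleted region: member-gene FPKM averaged per
condition, the report carrying heat-map-style mean log10(FPKM+1) values,
and the verdict driven by the linear residual fraction (mutant over
wild-type mean FPKM): `segregated` below 0.05, `failed` above 0.5,
`partial` between. The thresholds are declared defaults for "no or very
few residual reads", not measured constants; the linear ratio is used for
the verdict because it tracks the fraction of unedited chromosome copies
directly (a 30% leak shows up as ≈ 0.3), whereas a ratio of log-FPKM means
compresses exactly the signal being judged. Flanking genes are checked in
the opposite direction — they must not be depleted — as a guard against
deletions eating into neighbors.

## Synthetic data

The generator emulates the study system at desk scale. Defaults: gene
essentiality drawn iid at 26.4% essential / 5.8% beneficial / 64.2%
nonessential (the 718/157/1748-of-2723 proportions); lognormal gene lengths
(median ≈ 900 bp, σ = 0.4 in log space); geometric intergenic gaps (mean ≈
100 bp); uniform-composition sequence at a configurable GC. These are
plausible bacterial scales declared as constants, not measurements.
Planted nonessential runs have exact gene-extent spans, essential guard
genes on both sides, and interior placement on the chromosome (so arms and
junction primers always have flanking room); background runs are capped at
5 deletable genes so planted runs are the only large ones. Counts are
negative-binomial (variance `mu + phi mu^2`, `phi = 0.1` by default, 0 =
Poisson) around a lognormal baseline, with planted fold changes and a
deletion `leak_rate` that scales deleted-region means (0 = fully
segregated). One seed fans out to independent per-component streams; the
same seed reproduces fixtures byte for byte.

What passing tests on these fixtures do **not** show: real essentiality
data has spatial structure (operons, co-essential pairs) that iid labels
lack; real RNA-seq has positional and GC biases, multimapping, and
overdispersion structure beyond a single NB parameter; and the generator
says nothing about which deletions will actually segregate in a living
polyploid cell — the study system's three never-segregating regions have
no counterpart here.

## Problem sizes

The default test suite and the acceptance script run on genomes of tens to
hundreds of kilobases with tens to hundreds of genes, 500 random genomes
for the region-finder oracle, 100 regions for the guide contracts, 50
deletion fixtures for genotyping, and 2000-gene expression simulations —
sizes chosen so the whole battery completes in a few minutes on one core
while still exercising every code path at realistic densities.

## Known limitations

No mismatch-tolerant off-target scoring, crRNA secondary structure, or
guide-activity prediction; no thermodynamic dimer/hairpin screening beyond
the Tm model; no model of plasmid curing kinetics or polyploid segregation
dynamics; no read alignment or quantification (count matrices are the
input); no GO/KEGG enrichment. Multi-chromosome genomes and non-chromosomal
replicons are out of scope.
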