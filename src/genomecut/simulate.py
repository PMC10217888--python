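"""Synthetic genomes, count matrices and ground truth for exercising the toolkit.

Everything downstream of this module is tested against fixtures generated
here, with the planted truth emitted alongside each fixture. Defaults mirror
the study system at desk scale: a single circular chromosome whose genes
carry a three-way essentiality split of roughly 26% essential / 6%
beneficial / 64% nonessential (the 718/157/1748-of-2723 proportions),
lognormal gene lengths with a median near 900 bp, and short intergenic gaps
with a mean near 100 bp — plausible bacterial scales, declared here as
constants rather than measured values.

A single ``seed`` fans out to independent per-component RNG streams, so the
same seed always yields byte-identical fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import AnnotatedGenome, CandidateRegion, CountMatrix, GeneRecord

#: essential, beneficial, nonessential fractions (718/157/1748 of 2723)
DEFAULT_ESSENTIALITY_FRACS = (0.2637, 0.0577, 0.6420)


@dataclass
class SyntheticTruth:
    """What was planted, so tests can check it was recovered."""

    seed: int
    planted_regions: list[CandidateRegion] = field(default_factory=list)
    planted_deg: dict[str, float] = field(default_factory=dict)
    deleted_tags: tuple[str, ...] = ()
    leak_rate: float | None = None


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def gen_genome(
    n_genes: int = 300,
    essentiality_fracs: tuple[float, float, float] = DEFAULT_ESSENTIALITY_FRACS,
    region_size_targets: list[int] | None = None,
    gc: float = 0.5,
    gene_len_median: int = 900,
    gene_len_sigma: float = 0.4,
    intergenic_mean: int = 100,
    max_background_run: int = 5,
    chrom_id: str = "synchrom",
    seed: int = 0,
) -> tuple[AnnotatedGenome, SyntheticTruth]:
    """A random annotated genome, optionally with planted nonessential runs.

    Background genes draw iid essentiality labels from ``essentiality_fracs``
    (the remainder to 1 becomes ``unknown``), except that any background run
    of deletable genes is capped at ``max_background_run`` genes by forcing
    an essential gene, so planted runs are the only large ones. Each entry of
    ``region_size_targets`` plants one contiguous nonessential run whose
    gene-extent span is exactly that many bp, flanked by essential guard
    genes, at a random position; planted runs are recorded in the truth.
    """
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    fracs = np.asarray(essentiality_fracs, dtype=float)
    if fracs.sum() > 1.0 + 1e-9 or np.any(fracs < 0):
        raise ValueError("essentiality fractions must be non-negative, sum <= 1")
    targets = list(region_size_targets or [])
    layout_rng, seq_rng, label_rng = _rngs(seed, 3)

    # background labels with run capping
    cats = ["essential", "beneficial", "nonessential", "unknown"]
    probs = np.append(fracs, max(0.0, 1.0 - fracs.sum()))
    probs = probs / probs.sum()
    labels: list[str] = []
    run = 0
    for _ in range(n_genes):
        lab = cats[label_rng.choice(4, p=probs)]
        if lab in ("nonessential", "beneficial"):
            run += 1
            if run > max_background_run:
                lab = "essential"
                run = 0
        else:
            run = 0
        labels.append(lab)

    # plan planted blocks: each is [guard, member..., guard] with exact span
    blocks: list[list[tuple[str, int, int | None]]] = []  # (label, length, fixed_gap)
    for target in targets:
        m = max(1, round(target / (gene_len_median + 200)))
        intra_gap = 100
        body = target - (m - 1) * intra_gap
        if body < m:
            raise ValueError(f"region target {target} bp too small to plant")
        base, extra = divmod(body, m)
        lens = [base + (1 if i < extra else 0) for i in range(m)]
        guard_len = int(
            np.clip(layout_rng.lognormal(np.log(gene_len_median), gene_len_sigma), 150, 5000)
        )
        block = [("essential", guard_len, None)]
        for i, L in enumerate(lens):
            block.append(("nonessential", L, intra_gap if i > 0 else None))
        block.append(("essential", guard_len, None))
        blocks.append(block)

    # interleave planted blocks at random background positions; slots at the
    # very ends are avoided so planted regions sit interior to the chromosome
    # (downstream design needs flanking room for arms and junction primers)
    if blocks:
        lo, hi = min(2, n_genes), max(n_genes - 1, min(2, n_genes) + 1)
        if hi - lo < len(blocks):
            raise ValueError(
                f"cannot place {len(blocks)} planted regions among {n_genes} genes"
            )
        insert_at = sorted(layout_rng.choice(np.arange(lo, hi), size=len(blocks), replace=False))
    else:
        insert_at = []
    order: list[tuple[str, int | None, int | None, int | None]] = []
    # entries: (label, length or None->draw, fixed_gap or None->draw, block_id)
    block_pos = {pos: i for i, pos in enumerate(insert_at)}
    for pos in range(n_genes + 1):
        if pos in block_pos:
            for label, length, gap in blocks[block_pos[pos]]:
                order.append((label, length, gap, block_pos[pos]))
        if pos < n_genes:
            order.append((labels[pos], None, None, None))

    # lay out coordinates and draw sequence lengths
    genes: list[GeneRecord] = []
    members_by_block: dict[int, list[int]] = {i: [] for i in range(len(blocks))}
    cursor = 0
    for label, length, gap, block_id in order:
        g = (
            gap
            if gap is not None
            else int(layout_rng.geometric(1.0 / intergenic_mean))
        )
        L = (
            length
            if length is not None
            else int(
                np.clip(
                    layout_rng.lognormal(np.log(gene_len_median), gene_len_sigma),
                    60,
                    20000,
                )
            )
        )
        start = cursor + g
        strand = "+" if layout_rng.random() < 0.5 else "-"
        genes.append(GeneRecord("PENDING", start, start + L, strand, label))
        if block_id is not None and label == "nonessential":
            members_by_block[block_id].append(len(genes) - 1)
        cursor = start + L
    total_len = cursor + int(layout_rng.geometric(1.0 / intergenic_mean)) + 200

    # sequential locus tags in genomic order
    genes = [
        GeneRecord(f"SYN_{i + 1:04d}", g.start, g.end, g.strand, g.essentiality)
        for i, g in enumerate(genes)
    ]
    sequence = _random_dna(seq_rng, total_len, gc)
    genome = AnnotatedGenome(
        chrom_id=chrom_id, sequence=sequence, genes=genes, circular=True
    )

    planted_regions = []
    for block_id, idxs in members_by_block.items():
        members = [genes[i] for i in idxs]
        planted_regions.append(
            CandidateRegion(
                start=members[0].start,
                end=members[-1].end,
                member_locus_tags=tuple(m.locus_tag for m in members),
                left_flank_tag=genes[idxs[0] - 1].locus_tag,
                right_flank_tag=genes[idxs[-1] + 1].locus_tag,
            )
        )
    planted_regions.sort(key=lambda r: r.start)
    truth = SyntheticTruth(seed=seed, planted_regions=planted_regions)
    return genome, truth


def gen_counts(
    genome: AnnotatedGenome,
    deg_spec: dict[str, float] | None = None,
    depth: int = 1_000_000,
    dispersion: float = 0.1,
    n_reps: int = 3,
    deleted_tags: tuple[str, ...] = (),
    leak_rate: float = 0.0,
    baseline_sigma: float = 1.0,
    seed: int = 0,
) -> tuple[CountMatrix, SyntheticTruth]:
    """Negative-binomial count matrices for a WT and a mutant condition.

    Per gene, a lognormal baseline sets the relative expression; the mutant
    mean is the baseline times the planted fold change from ``deg_spec``
    (``{locus_tag: fold_change}``). Genes of deleted regions
    (``deleted_tags``) have their mutant mean multiplied by ``leak_rate``
    (0 = fully segregated: zero counts; 0.3 = 30% residual chromosome
    copies). ``dispersion`` is the NB overdispersion (variance =
    mu + dispersion * mu^2); 0 gives Poisson counts. Sample columns are
    ``WT_1..n`` then ``MUT_1..n``.
    """
    if not genome.genes:
        raise ValueError("genome has no genes")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    deg_spec = deg_spec or {}
    base_rng, noise_rng = _rngs(seed ^ 0x5EED, 2)

    tags = [g.locus_tag for g in genome.genes]
    lengths = np.array([g.length_bp for g in genome.genes], dtype=np.int64)
    baseline = base_rng.lognormal(mean=0.0, sigma=baseline_sigma, size=len(tags))
    weights = baseline * lengths / lengths.mean()
    weights = weights / weights.sum()

    fc = np.ones(len(tags))
    for i, t in enumerate(tags):
        if t in deg_spec:
            fc[i] = deg_spec[t]
    deleted_mask = np.array([t in set(deleted_tags) for t in tags])
    mut_scale = fc * np.where(deleted_mask, leak_rate, 1.0)

    def draw(mu: np.ndarray) -> np.ndarray:
        mu = np.maximum(mu, 0.0)
        if dispersion == 0:
            return noise_rng.poisson(mu)
        n = 1.0 / dispersion
        p = n / (n + mu)
        out = np.zeros(mu.shape, dtype=np.int64)
        pos = mu > 0
        out[pos] = noise_rng.negative_binomial(n, p[pos])
        return out

    samples, cols, conditions = [], [], {}
    for r in range(1, n_reps + 1):
        s = f"WT_{r}"
        samples.append(s)
        conditions[s] = "WT"
        cols.append(draw(depth * weights))
    for r in range(1, n_reps + 1):
        s = f"MUT_{r}"
        samples.append(s)
        conditions[s] = "MUT"
        cols.append(draw(depth * weights * mut_scale))

    counts = CountMatrix(
        gene_ids=tags,
        gene_lengths_bp=lengths,
        samples=samples,
        counts=np.stack(cols, axis=1),
        conditions=conditions,
    )
    truth = SyntheticTruth(
        seed=seed,
        planted_deg=dict(deg_spec),
        deleted_tags=tuple(deleted_tags),
        leak_rate=leak_rate,
    )
    return counts, truth


__all__ = [
    "DEFAULT_ESSENTIALITY_FRACS",
    "SyntheticTruth",
    "gen_counts",
    "gen_genome",
]
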