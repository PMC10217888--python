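"""FPKM, differential expression, and segregation verification.

The DEG criterion implemented here is the stated one: per gene, replicate
fragment counts are pooled within each condition, a 2x2 table
``[gene_a, rest_a; gene_b, rest_b]`` is tested with a two-sided Fisher's
exact test (probability-summation convention), p-values are Benjamini-
Hochberg adjusted across all tested genes, and a gene is called up when its
FPKM fold change exceeds 2 with q < 0.05 (down symmetrically, < 0.5).

A caveat worth stating up front: pooling replicates makes the Fisher test a
test of the *pooled proportions* and it is anticonservative under biological
overdispersion (negative-binomial noise). It is well calibrated under a
Poisson null — which the test suite asserts — but on real replicated data a
count model (e.g. a negative-binomial GLM) is the better tool; this module
implements the simple stated criterion, it does not reproduce Cuffdiff.

Segregation verification: in polyploid cyanobacteria an edit is only
complete once every chromosome copy carries it. A fully segregated deletion
leaves essentially no RNA-seq signal in the deleted region, so per region we
compare expression of member genes between mutant and wild type and call a
verdict from the residual fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import CandidateRegion, CountMatrix


@dataclass(frozen=True)
class DegRecord:
    gene_id: str
    mean_fpkm_a: float
    mean_fpkm_b: float
    fold_change: float      # (mean_fpkm_b + eps) / (mean_fpkm_a + eps)
    log2_fc: float
    p_value: float
    q_value: float
    direction: str          # up / down / ns
    excluded_deleted: bool


@dataclass(frozen=True)
class RegionSegregation:
    region_name: str
    n_genes: int
    mean_log_fpkm_wt: float     # mean over member genes of log10(FPKM+1)
    mean_log_fpkm_mut: float
    residual_fraction: float    # linear-scale mutant/WT mean FPKM
    verdict: str                # segregated / partial / failed
    flank_ok: bool


@dataclass(frozen=True)
class SegregationReport:
    regions: list[RegionSegregation]

    @property
    def all_segregated(self) -> bool:
        return all(r.verdict == "segregated" for r in self.regions)


@dataclass(frozen=True)
class DegSummary:
    n_up: int
    n_down: int
    n_up_over_32fold: int
    mean_fpkm_a: float | None   # over the requested gene set
    mean_fpkm_b: float | None


# ---------------------------------------------------------------------------
# FPKM
# ---------------------------------------------------------------------------

def fpkm(counts: CountMatrix) -> pd.DataFrame:
    """Fragments per kilobase of gene per million mapped fragments.

    ``FPKM[g, s] = counts[g, s] * 1e9 / (length_bp[g] * total[s])`` where the
    per-sample total is the column sum over the genes in the matrix (i.e.
    gene-assigned fragments, not a separate mapped-read total).
    """
    totals = counts.counts.sum(axis=0, dtype=np.float64)
    if np.any(totals == 0):
        zero = [s for s, t in zip(counts.samples, totals) if t == 0]
        raise ValueError(f"sample(s) with zero total counts: {zero}")
    values = (
        counts.counts * 1e9 / (counts.gene_lengths_bp[:, None] * totals[None, :])
    )
    return pd.DataFrame(values, index=counts.gene_ids, columns=counts.samples)


# ---------------------------------------------------------------------------
# DEG calling
# ---------------------------------------------------------------------------

def call_degs(
    counts: CountMatrix,
    condition_a_samples: list[str],
    condition_b_samples: list[str],
    deleted_gene_ids: set[str] | None = None,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    pseudo_fpkm: float = 1.0,
    per_replicate: bool = False,
) -> list[DegRecord]:
    """Call differential expression of condition b relative to condition a.

    Thresholds are strict inequalities: a gene at exactly the fold-change
    threshold is not called. Genes in ``deleted_gene_ids`` are still tested
    but flagged ``excluded_deleted`` so summaries can leave them out of the
    downregulated counts (their loss is the edit, not a response to it).

    ``per_replicate`` is a robustness variant: instead of pooling replicates,
    the Fisher test runs on every (a-replicate, b-replicate) pairing and the
    per-gene p is the Bonferroni-adjusted minimum across pairings — more
    conservative to single-replicate artifacts, still not a count model.
    """
    deleted_gene_ids = deleted_gene_ids or set()
    a_idx = counts.sample_index(condition_a_samples)
    b_idx = counts.sample_index(condition_b_samples)
    if set(condition_a_samples) & set(condition_b_samples):
        raise ValueError("condition sample sets overlap")
    if len(a_idx) == 0 or len(b_idx) == 0:
        raise ValueError("each condition needs at least one sample")

    pooled_a = counts.counts[:, a_idx].sum(axis=1)
    pooled_b = counts.counts[:, b_idx].sum(axis=1)
    total_a = int(pooled_a.sum())
    total_b = int(pooled_b.sum())

    fpkm_all = fpkm(counts)
    mean_a = fpkm_all.iloc[:, a_idx].mean(axis=1).to_numpy()
    mean_b = fpkm_all.iloc[:, b_idx].mean(axis=1).to_numpy()

    pvals = np.empty(len(counts.gene_ids))
    if per_replicate:
        col_a = counts.counts[:, a_idx]
        col_b = counts.counts[:, b_idx]
        tot_a = col_a.sum(axis=0)
        tot_b = col_b.sum(axis=0)
        n_pairs = len(a_idx) * len(b_idx)
        for i in range(len(counts.gene_ids)):
            p_min = 1.0
            for ja in range(len(a_idx)):
                for jb in range(len(b_idx)):
                    ga, gb = int(col_a[i, ja]), int(col_b[i, jb])
                    table = [
                        [ga, int(tot_a[ja]) - ga],
                        [gb, int(tot_b[jb]) - gb],
                    ]
                    p_min = min(p_min, stats.fisher_exact(table)[1])
            pvals[i] = min(1.0, p_min * n_pairs)
    else:
        for i, (ga, gb) in enumerate(zip(pooled_a, pooled_b)):
            table = [[int(ga), total_a - int(ga)], [int(gb), total_b - int(gb)]]
            pvals[i] = stats.fisher_exact(table, alternative="two-sided")[1]
    qvals = multipletests(pvals, method="fdr_bh")[1]

    records = []
    for i, gene in enumerate(counts.gene_ids):
        fc = (mean_b[i] + pseudo_fpkm) / (mean_a[i] + pseudo_fpkm)
        if fc > fc_threshold and qvals[i] < alpha:
            direction = "up"
        elif fc < 1.0 / fc_threshold and qvals[i] < alpha:
            direction = "down"
        else:
            direction = "ns"
        records.append(
            DegRecord(
                gene_id=gene,
                mean_fpkm_a=float(mean_a[i]),
                mean_fpkm_b=float(mean_b[i]),
                fold_change=float(fc),
                log2_fc=float(np.log2(fc)),
                p_value=float(pvals[i]),
                q_value=float(qvals[i]),
                direction=direction,
                excluded_deleted=gene in deleted_gene_ids,
            )
        )
    return records


def deg_summary(
    degs: list[DegRecord],
    gene_set: list[str] | None = None,
    high_fold: float = 32.0,
) -> DegSummary:
    """Up/down counts, strong-upregulation count, and set-mean FPKMs.

    Deleted genes are omitted from the down count. The per-condition mean
    FPKM of ``gene_set`` is the unweighted arithmetic mean, over the genes of
    the set, of each gene's per-condition mean FPKM; an empty/None set
    reports null means.
    """
    n_up = sum(1 for d in degs if d.direction == "up")
    n_down = sum(
        1 for d in degs if d.direction == "down" and not d.excluded_deleted
    )
    n_high = sum(
        1 for d in degs if d.direction == "up" and d.fold_change > high_fold
    )
    mean_a = mean_b = None
    if gene_set:
        by_id = {d.gene_id: d for d in degs}
        missing = [g for g in gene_set if g not in by_id]
        if missing:
            raise KeyError(f"gene set members not in DEG results: {missing[:5]}")
        mean_a = float(np.mean([by_id[g].mean_fpkm_a for g in gene_set]))
        mean_b = float(np.mean([by_id[g].mean_fpkm_b for g in gene_set]))
    return DegSummary(
        n_up=n_up,
        n_down=n_down,
        n_up_over_32fold=n_high,
        mean_fpkm_a=mean_a,
        mean_fpkm_b=mean_b,
    )


# ---------------------------------------------------------------------------
# segregation
# ---------------------------------------------------------------------------

def segregation_check(
    fpkm_df: pd.DataFrame,
    regions: list[CandidateRegion],
    wt_sample_ids: list[str],
    mut_sample_ids: list[str],
    segregated_below: float = 0.05,
    failed_above: float = 0.5,
    flank_min_residual: float = 0.5,
) -> SegregationReport:
    """Per-region residual-expression verdicts for a set of deleted regions.

    For each region the per-gene FPKM is averaged across the samples of each
    condition; the report carries the heat-map-style mean log10(FPKM+1) per
    condition, while the verdict is based on the linear residual fraction
    (mutant mean FPKM over wild-type mean FPKM, pseudocounted):
    ``segregated`` below ``segregated_below``, ``failed`` above
    ``failed_above``, ``partial`` in between. The flanking genes are checked
    the other way around — they must *not* be depleted.
    """
    eps = 1e-9
    regs = []
    for region in regions:
        members = [t for t in region.member_locus_tags if t in fpkm_df.index]
        if not members:
            raise ValueError(f"region {region.name} has no quantified member genes")
        wt = fpkm_df.loc[members, wt_sample_ids].mean(axis=1)
        mut = fpkm_df.loc[members, mut_sample_ids].mean(axis=1)
        residual = float(mut.mean() / (wt.mean() + eps))
        if residual < segregated_below:
            verdict = "segregated"
        elif residual > failed_above:
            verdict = "failed"
        else:
            verdict = "partial"
        flank_ok = True
        for tag in (region.left_flank_tag, region.right_flank_tag):
            if tag in fpkm_df.index:
                fw = float(fpkm_df.loc[tag, wt_sample_ids].mean())
                fm = float(fpkm_df.loc[tag, mut_sample_ids].mean())
                if fw > 0 and fm / (fw + eps) < flank_min_residual:
                    flank_ok = False
        regs.append(
            RegionSegregation(
                region_name=region.name,
                n_genes=len(members),
                mean_log_fpkm_wt=float(np.log10(wt + 1.0).mean()),
                mean_log_fpkm_mut=float(np.log10(mut + 1.0).mean()),
                residual_fraction=residual,
                verdict=verdict,
                flank_ok=flank_ok,
            )
        )
    return SegregationReport(regions=regs)


__all__ = [
    "DegRecord",
    "DegSummary",
    "RegionSegregation",
    "SegregationReport",
    "call_degs",
    "deg_summary",
    "fpkm",
    "segregation_check",
]
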