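"""End-to-end pipeline: genome -> regions -> constructs -> plan -> verification.

Chains the individual stages the way a reduction campaign would run them:
enumerate and size-filter nonessential regions, design an editing construct
per region, assemble a stepwise plan with alternating markers, emit the
predicted edited genome, then verify the predicted final strain with
simulated RNA-seq counts (segregation verdicts per deleted region and a DEG
scan against the wild type).
"""

from __future__ import annotations

import json
import logging
import os
from pathlib import Path

from . import __version__, io
from .config import RunConfig
from .expression import call_degs, deg_summary, fpkm, segregation_check
from .model import AnnotatedGenome
from .plans import apply_plan, build_plan
from .regions import filter_regions, find_regions, region_stats
from .simulate import gen_counts, gen_genome

log = logging.getLogger("genomecut")


def write_guides_tsv(plan, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# genomecut {__version__} guides\n"
            "region\tstrand\tpam_start\tpam\tprotospacer\tgc\tgenome_hits\n"
        )
        for step in plan.steps:
            for g in step.construct.guides:
                fh.write(
                    f"{g.region_name}\t{g.strand}\t{g.pam_start}\t{g.pam_seq}\t"
                    f"{g.protospacer}\t{g.gc_fraction:.3f}\t{g.genome_hit_count}\n"
                )


def write_oligos_tsv(plan, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# genomecut {__version__} cloning oligos\nregion\ttop\tbottom\n")
        for step in plan.steps:
            for o in step.construct.oligos:
                fh.write(f"{o.guide.region_name}\t{o.top_oligo}\t{o.bottom_oligo}\n")


def run_pipeline(
    config: RunConfig,
    out_dir: str | os.PathLike,
    genome: AnnotatedGenome | None = None,
) -> dict:
    """Run every stage and write the artifact bundle into ``out_dir``.

    With no ``genome``, a synthetic one with planted over-threshold regions
    is generated from ``config`` (self-contained demo mode). Returns the
    report dictionary that is also written to ``report.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()

    if genome is None:
        log.info("generating synthetic genome (seed=%d)", config.seed)
        genome, truth = gen_genome(
            n_genes=config.n_genes,
            region_size_targets=config.region_size_targets,
            gc=config.gc,
            seed=config.seed,
        )
        io.write_genome(
            genome, out / "genome.fasta", out / "genome.gff3", out / "essentiality.tsv"
        )

    regions = find_regions(genome, breakers=config.breakers(), span=config.span)
    filtered = filter_regions(regions, config.min_region_bp, strict=config.strict_over)
    stats = region_stats(regions, filtered, len(genome))
    io.write_regions_bed(filtered, out / "regions.bed", chrom_id=genome.chrom_id)
    log.info(
        "%d regions, %d over %d bp (%.2f%% of genome)",
        stats.n_regions_total,
        stats.n_regions_over_threshold,
        config.min_region_bp,
        stats.percent_of_genome,
    )

    targets = filtered[: config.n_steps]
    plan = build_plan(
        genome,
        targets,
        order=config.order,
        start_marker=config.start_marker,
        cfg=config.construct_config(),
    )
    io.write_plan_json(plan, out / "plan.json")
    write_guides_tsv(plan, out / "guides.tsv")
    write_oligos_tsv(plan, out / "oligos.tsv")

    edited = apply_plan(genome, plan)
    io.write_genome(edited, out / "edited.fasta", out / "edited.gff3")

    # verification on simulated RNA-seq of the final strain
    deleted_tags = tuple(
        t for step in plan.steps for t in step.construct.region.member_locus_tags
    )
    counts, _ = gen_counts(
        genome,
        deleted_tags=deleted_tags,
        leak_rate=0.0,
        depth=config.depth,
        dispersion=config.dispersion,
        n_reps=config.n_reps,
        seed=config.seed,
    )
    io.write_counts_tsv(counts, out / "counts.tsv")
    wt = [s for s in counts.samples if counts.conditions[s] == "WT"]
    mut = [s for s in counts.samples if counts.conditions[s] == "MUT"]
    fpkm_df = fpkm(counts)
    seg = segregation_check(
        fpkm_df,
        [s.construct.region for s in plan.steps],
        wt,
        mut,
        segregated_below=config.segregated_below,
        failed_above=config.failed_above,
    )
    degs = call_degs(
        counts,
        wt,
        mut,
        deleted_gene_ids=set(deleted_tags),
        fc_threshold=config.fc_threshold,
        alpha=config.alpha,
        pseudo_fpkm=config.pseudo_fpkm,
    )
    summary = deg_summary(degs)

    report = {
        "tool": "genomecut",
        "version": __version__,
        "config_hash": cfg_hash,
        "config": config.to_dict(),
        "genome_bp": len(genome),
        "region_stats": {
            "n_regions_total": stats.n_regions_total,
            "n_regions_over_threshold": stats.n_regions_over_threshold,
            "total_bp_over_threshold": stats.total_bp_over_threshold,
            "percent_of_genome": stats.percent_of_genome,
        },
        "plan": {
            "n_steps": len(plan.steps),
            "markers": [s.marker for s in plan.steps],
            "final_genome_bp": len(edited),
            "final_reduction_percent": round(100 * plan.final_reduction_fraction, 2),
        },
        "segregation": [
            {
                "region": r.region_name,
                "residual_fraction": r.residual_fraction,
                "verdict": r.verdict,
                "flank_ok": r.flank_ok,
            }
            for r in seg.regions
        ],
        "deg_summary": {
            "n_up": summary.n_up,
            "n_down": summary.n_down,
            "n_up_over_32fold": summary.n_up_over_32fold,
        },
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return report


__all__ = ["run_pipeline", "write_guides_tsv", "write_oligos_tsv"]
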