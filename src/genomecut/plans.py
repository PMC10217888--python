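"""Multi-step deletion campaigns with alternating selection markers.

Because the editing plasmid must be cured before the next one is introduced,
successive steps alternate the kanamycin (Km) and spectinomycin (Sp)
resistance markers: each new plasmid can then be selected on a background
that has lost the previous one. A plan therefore records, per step, the
editing construct, the marker, and the predicted genome after the edit; the
predicted genome is recomputed from scratch at each step (annotation lifting
included) so stale coordinates are caught by string comparison of the arms
rather than silently propagated.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

from .constructs import (
    CloningOligoPair,
    ConstructConfig,
    EditingConstruct,
    FusionPrimer,
    HomologyArm,
    PayloadGene,
    PrimerConfig,
    PrimerPair,
    design_editing_construct,
)
from .guides import Guide
from .model import AnnotatedGenome, CandidateRegion, GeneRecord

MARKERS = ("Km", "Sp")


class ArmMismatchError(ValueError):
    """Construct arms do not match the current genome (stale plan)."""


class PlanError(ValueError):
    pass


@dataclass(frozen=True)
class DeletionStep:
    index: int
    construct: EditingConstruct
    marker: str
    predicted_genome_bp: int
    cumulative_reduction_fraction: float


@dataclass
class DeletionPlan:
    steps: list[DeletionStep] = field(default_factory=list)
    start_marker: str = "Km"
    wt_genome_bp: int = 0

    @property
    def final_reduction_fraction(self) -> float:
        if not self.steps:
            return 0.0
        return self.steps[-1].cumulative_reduction_fraction


def other_marker(marker: str) -> str:
    return "Sp" if marker == "Km" else "Km"


# ---------------------------------------------------------------------------
# applying a step
# ---------------------------------------------------------------------------

def apply_step(genome: AnnotatedGenome, construct: EditingConstruct) -> AnnotatedGenome:
    """Splice the construct's region out of the genome (payload back in).

    The homology arms are compared base-for-base against the current genome
    before anything is cut; a mismatch means the construct was designed
    against a different genome state (e.g. the step was already applied).
    Genes inside the deleted span are dropped, downstream genes are shifted,
    and retained payload genes are re-annotated at their new coordinates.
    """
    up, down = construct.arm_up, construct.arm_down
    n = len(genome)
    if up.start < 0 or down.end > n:
        raise PlanError("origin-spanning edits are not supported")
    if genome.sequence[up.start : up.end] != up.seq:
        raise ArmMismatchError(
            f"up arm of {construct.region.name} does not match the genome at "
            f"[{up.start}, {up.end}); the plan is stale"
        )
    if genome.sequence[down.start : down.end] != down.seq:
        raise ArmMismatchError(
            f"down arm of {construct.region.name} does not match the genome at "
            f"[{down.start}, {down.end}); the plan is stale"
        )
    rs, re = up.end, down.start
    payload_seq = construct.payload_seq
    if len(payload_seq) >= re - rs:
        raise PlanError(
            f"payload ({len(payload_seq)} bp) is not smaller than the deleted "
            f"span ({re - rs} bp)"
        )
    new_seq = genome.sequence[:rs] + payload_seq + genome.sequence[re:]
    shift = (re - rs) - len(payload_seq)

    new_genes: list[GeneRecord] = []
    for g in genome.genes:
        if g.end <= rs:
            new_genes.append(g)
        elif g.start >= re:
            new_genes.append(dataclasses.replace(g, start=g.start - shift, end=g.end - shift))
        # genes inside or straddling the deleted span are dropped

    offset = 0
    for p in construct.payload:
        src = genome.gene(p.locus_tag)
        new_start = rs + offset + (src.start - p.source_start)
        new_genes.append(
            dataclasses.replace(src, start=new_start, end=new_start + src.length_bp)
        )
        offset += len(p.seq)

    return AnnotatedGenome(
        chrom_id=genome.chrom_id,
        sequence=new_seq,
        genes=new_genes,
        circular=genome.circular,
    )


# ---------------------------------------------------------------------------
# building plans
# ---------------------------------------------------------------------------

def _locate_region(genome: AnnotatedGenome, region: CandidateRegion) -> CandidateRegion:
    """Re-derive a region's coordinates from its member genes in the current genome."""
    try:
        members = [genome.gene(tag) for tag in region.member_locus_tags]
    except KeyError as exc:
        raise PlanError(
            f"region {region.name} invalidated by an earlier deletion "
            f"(gene {exc.args[0]} no longer present)"
        ) from None
    return CandidateRegion(
        start=min(m.start for m in members),
        end=max(m.end for m in members),
        member_locus_tags=region.member_locus_tags,
        left_flank_tag=region.left_flank_tag,
        right_flank_tag=region.right_flank_tag,
    )


def build_plan(
    genome: AnnotatedGenome,
    regions: list[CandidateRegion],
    order: str = "input",
    start_marker: str = "Km",
    cfg: ConstructConfig = ConstructConfig(),
) -> DeletionPlan:
    """Assemble a stepwise campaign deleting ``regions`` one per step.

    ``order`` is ``input`` (default; the historical order) or ``size-desc``.
    Markers alternate starting from ``start_marker``. Constructs are designed
    against the predicted genome at each step, so all coordinates are live.
    """
    if start_marker not in MARKERS:
        raise PlanError(f"start_marker must be one of {MARKERS}")
    if order not in ("input", "size-desc"):
        raise PlanError("order must be 'input' or 'size-desc'")
    for i, a in enumerate(regions):
        for b in regions[i + 1 :]:
            if a.start < b.end and b.start < a.end:
                raise PlanError(f"regions {a.name} and {b.name} overlap")
    ordered = (
        sorted(regions, key=lambda r: (-r.length_bp, r.start))
        if order == "size-desc"
        else list(regions)
    )
    wt_bp = len(genome)
    current = genome
    steps: list[DeletionStep] = []
    marker = start_marker
    for idx, region in enumerate(ordered, start=1):
        live = _locate_region(current, region)
        construct = design_editing_construct(current, live, marker=marker, cfg=cfg)
        current = apply_step(current, construct)
        steps.append(
            DeletionStep(
                index=idx,
                construct=construct,
                marker=marker,
                predicted_genome_bp=len(current),
                cumulative_reduction_fraction=(wt_bp - len(current)) / wt_bp,
            )
        )
        marker = other_marker(marker)
    return DeletionPlan(steps=steps, start_marker=start_marker, wt_genome_bp=wt_bp)


def apply_plan(genome: AnnotatedGenome, plan: DeletionPlan, n_steps: int | None = None) -> AnnotatedGenome:
    """Apply the first ``n_steps`` of a plan (all by default)."""
    current = genome
    for step in plan.steps[: n_steps if n_steps is not None else len(plan.steps)]:
        current = apply_step(current, step.construct)
    return current


# ---------------------------------------------------------------------------
# deletion-replacement (interrupted regions)
# ---------------------------------------------------------------------------

def build_replacement_construct(
    genome: AnnotatedGenome,
    span_start: int,
    span_end: int,
    retain_tags: list[str],
    flank_bp: int = 200,
    marker: str = "Km",
    cfg: ConstructConfig = ConstructConfig(),
) -> EditingConstruct:
    """Delete a composite span while retaining its interior essential genes.

    The retained genes (each padded with ``flank_bp`` of native flanking DNA
    to keep their promoters — a declared biological risk, not a guarantee)
    are concatenated in genomic order between the homology arms, so the span
    is removed as a whole and the essential genes come back on the donor.
    Guides are placed outside the retained (padded) intervals so the edited
    chromosome is not re-cut.
    """
    members = [
        g for g in genome.genes if g.start >= span_start and g.end <= span_end
    ]
    if not members:
        raise PlanError("composite span contains no genes")
    retained = []
    for tag in retain_tags:
        g = genome.gene(tag)
        if g.start < span_start or g.end > span_end:
            raise PlanError(
                f"retained gene {tag} overlaps the outer boundary of the span"
            )
        retained.append(g)
    retained.sort(key=lambda g: g.start)
    payload = []
    forbidden = []
    for g in retained:
        ps = max(span_start, g.start - flank_bp)
        pe = min(span_end, g.end + flank_bp)
        payload.append(
            PayloadGene(
                locus_tag=g.locus_tag,
                seq=genome.slice(ps, pe),
                source_start=ps,
                source_end=pe,
            )
        )
        forbidden.append((ps, pe))
    region = CandidateRegion(
        start=span_start,
        end=span_end,
        member_locus_tags=tuple(m.locus_tag for m in members),
    )
    return design_editing_construct(
        genome,
        region,
        marker=marker,
        cfg=cfg,
        payload=payload,
        forbidden_intervals=forbidden,
    )


# ---------------------------------------------------------------------------
# (de)serialization — consumed by genomecut.io.write_plan_json/read_plan_json
# ---------------------------------------------------------------------------

def plan_to_dict(plan: DeletionPlan) -> dict:
    return {
        "start_marker": plan.start_marker,
        "wt_genome_bp": plan.wt_genome_bp,
        "final_reduction_fraction": plan.final_reduction_fraction,
        "steps": [
            {
                "index": s.index,
                "marker": s.marker,
                "predicted_genome_bp": s.predicted_genome_bp,
                "cumulative_reduction_fraction": s.cumulative_reduction_fraction,
                "construct": dataclasses.asdict(s.construct),
            }
            for s in plan.steps
        ],
    }


def _region_from_dict(d: dict) -> CandidateRegion:
    return CandidateRegion(
        start=d["start"],
        end=d["end"],
        member_locus_tags=tuple(d["member_locus_tags"]),
        left_flank_tag=d["left_flank_tag"],
        right_flank_tag=d["right_flank_tag"],
    )


def _construct_from_dict(d: dict) -> EditingConstruct:
    guides = [Guide(**g) for g in d["guides"]]
    oligos = [
        CloningOligoPair(
            guide=Guide(**o["guide"]),
            top_oligo=o["top_oligo"],
            bottom_oligo=o["bottom_oligo"],
            overhangs=tuple(o["overhangs"]),
        )
        for o in d["oligos"]
    ]
    return EditingConstruct(
        region=_region_from_dict(d["region"]),
        guides=guides,
        oligos=oligos,
        arm_up=HomologyArm(**d["arm_up"]),
        arm_down=HomologyArm(**d["arm_down"]),
        fusion_primers=[FusionPrimer(**p) for p in d["fusion_primers"]],
        genotype_primers={
            k: PrimerPair(**v) for k, v in d["genotype_primers"].items()
        },
        marker=d["marker"],
        payload=[PayloadGene(**p) for p in d["payload"]],
        cloning_site_hits=list(d["cloning_site_hits"]),
    )


def plan_from_dict(d: dict) -> DeletionPlan:
    steps = [
        DeletionStep(
            index=s["index"],
            construct=_construct_from_dict(s["construct"]),
            marker=s["marker"],
            predicted_genome_bp=s["predicted_genome_bp"],
            cumulative_reduction_fraction=s["cumulative_reduction_fraction"],
        )
        for s in d["steps"]
    ]
    return DeletionPlan(
        steps=steps,
        start_marker=d["start_marker"],
        wt_genome_bp=d["wt_genome_bp"],
    )


__all__ = [
    "MARKERS",
    "ArmMismatchError",
    "DeletionPlan",
    "DeletionStep",
    "PlanError",
    "apply_plan",
    "apply_step",
    "build_plan",
    "build_replacement_construct",
    "other_marker",
    "plan_from_dict",
    "plan_to_dict",
    "ConstructConfig",
    "PrimerConfig",
]
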