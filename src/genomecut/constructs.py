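"""Donor construct and primer design, plus in-silico PCR verification.

For each deletion region this module designs:

* two homology arms abutting the region (templates for homology-directed
  repair across the deletion),
* four fusion-PCR primers — outer primers at the distal arm ends and inner
  primers carrying reciprocal 5' tails so the two arm amplicons (and an
  optional retained-gene payload) overlap-extend into one donor fragment,
* two genotyping primer pairs implementing the classic knockout check:
  F/R anneal inside the deleted region (product on wild type only) and
  F'/R' flank the junction (a short product appears only once the region is
  gone; on the wild type the same pair would have to span the whole region,
  which exceeds the amplifiable size and yields nothing).

``insilico_pcr`` predicts amplicons by exact full-length primer matching,
which is deliberately strict: it is the verification tool the genotyping
logic is tested against, not a thermodynamic annealing model.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

from Bio.SeqUtils import MeltingTemp as mt

from .guides import (
    DEFAULT_OVERHANGS,
    CloningOligoPair,
    Guide,
    make_cloning_oligos,
    scan_pams,
    select_guides,
)
from .model import AnnotatedGenome, CandidateRegion, revcomp

BAMHI = "GGATCC"
BGLII = "AGATCT"


class InsufficientFlankError(ValueError):
    pass


class PrimerDesignError(ValueError):
    pass


@dataclass(frozen=True)
class PrimerConfig:
    """Constraints for primer picking.

    Melting temperatures come from Biopython's nearest-neighbor calculation
    (``MeltingTemp.Tm_NN`` with its default SantaLucia parameter set, 50 mM
    Na+, 25 nM strands). A 3'-terminal G/C is preferred, not required.
    """

    min_len: int = 18
    max_len: int = 28
    tm_min: float = 55.0
    tm_max: float = 65.0
    max_delta_tm: float = 3.0
    window: int = 60
    max_amplicon: int = 5000


@dataclass(frozen=True)
class ConstructConfig:
    arm_bp: int = 1000
    tail_len: int = 20
    pam: str = "TTN"
    spacer_len: int = 22
    guides_per_region: int = 2
    gc_range: tuple[float, float] = (0.3, 0.7)
    overhangs: tuple[str, str] = DEFAULT_OVERHANGS
    primers: PrimerConfig = field(default_factory=PrimerConfig)
    # genotyping geometry
    inner_offset: int = 300       # F anneals this far into the region
    internal_product: int = 800   # nominal F/R product size
    outer_offset: int = 1200      # F'/R' anchor distance from the junctions
    cloning_sites: tuple[str, ...] = (BAMHI, BGLII)

    def __post_init__(self) -> None:
        if not (100 <= self.arm_bp <= 3000):
            raise ValueError("arm_bp must be within 100..3000")
        if self.tail_len and self.tail_len < 10:
            raise ValueError("tail_len must be 0 or >= 10")


@dataclass(frozen=True)
class HomologyArm:
    side: str            # "up" or "down"
    start: int
    end: int
    seq: str

    @property
    def length_bp(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class FusionPrimer:
    """A PCR primer with an optional 5' tail; ``seq = tail + anneal_seq``."""

    name: str
    anneal_seq: str
    tail: str = ""
    tm: float = 0.0

    @property
    def seq(self) -> str:
        return self.tail + self.anneal_seq


@dataclass(frozen=True)
class PrimerPair:
    name: str
    fwd_seq: str
    rev_seq: str
    fwd_pos: int          # genomic start of the fwd annealing site on WT
    rev_pos: int          # genomic end of the rev annealing site on WT
    tm_fwd: float
    tm_rev: float
    expected_wt_bp: int | None
    expected_mut_bp: int | None


@dataclass(frozen=True)
class PayloadGene:
    """A retained essential gene carried between the arms (deletion-replacement)."""

    locus_tag: str
    seq: str
    source_start: int
    source_end: int


@dataclass(frozen=True)
class Amplicon:
    start: int
    end: int
    length: int
    seq: str


@dataclass
class EditingConstruct:
    """Everything needed for one deletion (or deletion-replacement) step."""

    region: CandidateRegion
    guides: list[Guide]
    oligos: list[CloningOligoPair]
    arm_up: HomologyArm
    arm_down: HomologyArm
    fusion_primers: list[FusionPrimer]
    genotype_primers: dict[str, PrimerPair]
    marker: str = "Km"
    payload: list[PayloadGene] = field(default_factory=list)
    cloning_site_hits: list[str] = field(default_factory=list)

    @property
    def payload_seq(self) -> str:
        return "".join(p.seq for p in self.payload)

    @property
    def net_deletion_bp(self) -> int:
        return self.region.length_bp - len(self.payload_seq)


# ---------------------------------------------------------------------------
# homology arms
# ---------------------------------------------------------------------------

def design_arms(
    genome: AnnotatedGenome, region: CandidateRegion, arm_bp: int = 1000
) -> tuple[HomologyArm, HomologyArm]:
    """Arms of ``arm_bp`` immediately flanking the region.

    The up arm ends exactly at ``region.start`` and the down arm begins
    exactly at ``region.end``. On a linear genome an arm running off the
    chromosome is an error; on a circular one it wraps the origin.
    """
    if arm_bp < 100:
        raise ValueError("arm_bp must be >= 100")
    n = len(genome)
    up_start, up_end = region.start - arm_bp, region.start
    dn_start, dn_end = region.end, region.end + arm_bp
    if not genome.circular and (up_start < 0 or dn_end > n):
        raise InsufficientFlankError(
            f"region {region.name} too close to a chromosome end for "
            f"{arm_bp} bp arms on a linear genome"
        )
    up = HomologyArm("up", up_start, up_end, genome.slice(up_start, up_end))
    down = HomologyArm("down", dn_start, dn_end, genome.slice(dn_start, dn_end))
    return up, down


def find_cloning_site_hits(
    arms: tuple[HomologyArm, HomologyArm],
    sites: tuple[str, ...] = (BAMHI, BGLII),
) -> list[str]:
    """Arms destined for the BamHI/BglII vector window must not carry the sites."""
    hits = []
    for arm in arms:
        for site in sites:
            if site in arm.seq or revcomp(site) in arm.seq:
                hits.append(f"{arm.side}:{site}")
    return hits


# ---------------------------------------------------------------------------
# primer picking
# ---------------------------------------------------------------------------

def primer_tm(seq: str) -> float:
    return float(mt.Tm_NN(seq))


def _candidates(
    template: str,
    anchor: int,
    direction: str,
    cfg: PrimerConfig,
    fixed_anchor: bool = False,
):
    """Feasible primer candidates near ``anchor`` on a local template string.

    ``direction`` "fwd": primer equals template[start:start+L], 5' end near
    the anchor. "rev": primer is the reverse complement of
    template[end-L:end], its 3' end near the anchor. Candidates are scored
    (3'-G/C preferred, then |Tm-60|, then |offset|, then length) and returned
    best-first; the scan order is fixed, so design is deterministic.
    """
    offsets = [0] if fixed_anchor else [
        o for k in range(cfg.window + 1) for o in ((k, -k) if k else (0,))
    ]
    out = []
    for off in offsets:
        for L in range(cfg.min_len, cfg.max_len + 1):
            if direction == "fwd":
                s = anchor + off
                e = s + L
            else:
                e = anchor + off
                s = e - L
            if s < 0 or e > len(template):
                continue
            sub = template[s:e]
            seq = sub if direction == "fwd" else revcomp(sub)
            tm = primer_tm(seq)
            if not (cfg.tm_min <= tm <= cfg.tm_max):
                continue
            score = (seq[-1] not in "GC", abs(tm - 60.0), abs(off), L)
            out.append({"seq": seq, "start": s, "end": e, "tm": tm, "score": score})
    out.sort(key=lambda c: c["score"])
    return out


def _pick_pair(fwd_cands, rev_cands, cfg: PrimerConfig, what: str):
    best = None
    for f in fwd_cands[:40]:
        for r in rev_cands[:40]:
            if abs(f["tm"] - r["tm"]) > cfg.max_delta_tm:
                continue
            key = (f["score"], r["score"])
            if best is None or key < best[0]:
                best = (key, f, r)
    if best is None:
        raise PrimerDesignError(
            f"no {what} primer pair satisfies length {cfg.min_len}-{cfg.max_len}, "
            f"Tm {cfg.tm_min}-{cfg.tm_max} C, dTm <= {cfg.max_delta_tm}; consider "
            f"widening the Tm window or the search window"
        )
    return best[1], best[2]


# ---------------------------------------------------------------------------
# fusion PCR
# ---------------------------------------------------------------------------

def design_fusion_primers(
    arms: tuple[HomologyArm, HomologyArm],
    cfg: ConstructConfig = ConstructConfig(),
    payload_seq: str = "",
) -> list[FusionPrimer]:
    """Outer + tailed inner primers for the two-step (overlap) PCR.

    The inner up-R primer carries a 5' tail equal to the reverse complement
    of the first ``tail_len`` nt of the next fragment (the down arm, or the
    payload when present), and the inner down-F symmetrically carries the
    last ``tail_len`` nt of the previous fragment, so both junctions overlap
    by at least ``tail_len`` nt during the second-step PCR.
    """
    up, down = arms
    t = cfg.tail_len
    nxt = payload_seq if payload_seq else down.seq
    prev = payload_seq if payload_seq else up.seq
    # fusion primers are anchored at the exact arm ends (so the fused product
    # reconstructs the arms base-for-base); with the anchor fixed, length is
    # the only freedom, so a wider length band is allowed than for the
    # position-free genotyping primers.
    pc = dataclasses.replace(cfg.primers, min_len=16, max_len=45)
    upF_c, upR_c = _pick_pair(
        _candidates(up.seq, 0, "fwd", pc, fixed_anchor=True),
        _candidates(up.seq, len(up.seq), "rev", pc, fixed_anchor=True),
        pc,
        "up-arm fusion",
    )
    dnF_c, dnR_c = _pick_pair(
        _candidates(down.seq, 0, "fwd", pc, fixed_anchor=True),
        _candidates(down.seq, len(down.seq), "rev", pc, fixed_anchor=True),
        pc,
        "down-arm fusion",
    )
    return [
        FusionPrimer("up-outer-F", upF_c["seq"], "", upF_c["tm"]),
        FusionPrimer("up-inner-R", upR_c["seq"], revcomp(nxt[:t]) if t else "", upR_c["tm"]),
        FusionPrimer("down-inner-F", dnF_c["seq"], prev[-t:] if t else "", dnF_c["tm"]),
        FusionPrimer("down-outer-R", dnR_c["seq"], "", dnR_c["tm"]),
    ]


def amplify(template: str, fwd: FusionPrimer, rev: FusionPrimer) -> str | None:
    """One PCR on a linear template; tails are appended, 3' ends must match."""
    i = template.find(fwd.anneal_seq)
    if i == -1:
        return None
    rc = revcomp(rev.anneal_seq)
    j = template.find(rc, i + len(fwd.anneal_seq))
    if j == -1:
        return None
    core = template[i : j + len(rc)]
    return fwd.tail + core + revcomp(rev.tail)


def overlap_extend(frag_a: str, frag_b: str, min_overlap: int = 15) -> str | None:
    """Merge two fragments sharing a terminal overlap (largest exact match)."""
    kmax = min(len(frag_a), len(frag_b))
    for k in range(kmax, min_overlap - 1, -1):
        if frag_a[-k:] == frag_b[:k]:
            return frag_a + frag_b[k:]
    return None


def simulate_fusion_pcr(
    template: str,
    fusion_primers: list[FusionPrimer],
    payload_seq: str = "",
    min_overlap: int = 15,
) -> str | None:
    """Run the two-step PCR in silico; returns the fused donor or None."""
    upF, upR, dnF, dnR = fusion_primers
    amp_up = amplify(template, upF, upR)
    amp_down = amplify(template, dnF, dnR)
    if amp_up is None or amp_down is None:
        return None
    fragments = [amp_up] + ([payload_seq] if payload_seq else []) + [amp_down]
    fused = fragments[0]
    for frag in fragments[1:]:
        fused = overlap_extend(fused, frag, min_overlap)
        if fused is None:
            return None
    return fused


# ---------------------------------------------------------------------------
# genotyping
# ---------------------------------------------------------------------------

def design_genotyping_primers(
    genome: AnnotatedGenome,
    region: CandidateRegion,
    cfg: ConstructConfig = ConstructConfig(),
    payload_bp: int = 0,
) -> dict[str, PrimerPair]:
    """The F/R (wild-type-only) and F'/R' (mutant-only) genotyping pairs.

    F/R anneal strictly inside the region, so the deleted template gives no
    product. F'/R' anneal outside the region at a distance such that the
    mutant junction product is <= ``max_amplicon`` while the wild-type
    product (which must span the whole region) exceeds it and is reported as
    absent.
    """
    seq = genome.sequence
    pc = cfg.primers
    min_span = cfg.inner_offset + cfg.internal_product + pc.window + pc.max_len
    if region.length_bp < min_span:
        raise PrimerDesignError(
            f"region {region.name} ({region.length_bp} bp) shorter than the "
            f"minimal internal F/R layout ({min_span} bp)"
        )
    f_anchor = region.start + cfg.inner_offset
    r_anchor = f_anchor + cfg.internal_product
    f_c, r_c = _pick_pair(
        _candidates(seq, f_anchor, "fwd", pc),
        _candidates(seq, r_anchor, "rev", pc),
        pc,
        "internal F/R",
    )
    fr = PrimerPair(
        name=f"Cr-{region.name.split('-')[0]}-F/R",
        fwd_seq=f_c["seq"],
        rev_seq=r_c["seq"],
        fwd_pos=f_c["start"],
        rev_pos=r_c["end"],
        tm_fwd=f_c["tm"],
        tm_rev=r_c["tm"],
        expected_wt_bp=r_c["end"] - f_c["start"],
        expected_mut_bp=None,
    )

    fp_anchor = region.start - cfg.outer_offset
    rp_anchor = region.end + cfg.outer_offset
    if not genome.circular and (
        fp_anchor - pc.window < 0 or rp_anchor + pc.window > len(seq)
    ):
        raise PrimerDesignError(
            f"region {region.name}: no room for junction primers on a linear genome"
        )
    fp_c, rp_c = _pick_pair(
        _candidates(seq, fp_anchor, "fwd", pc),
        _candidates(seq, rp_anchor, "rev", pc),
        pc,
        "junction F'/R'",
    )
    mut_bp = (
        (region.start - fp_c["start"]) + (rp_c["end"] - region.end) + payload_bp
    )
    wt_bp = rp_c["end"] - fp_c["start"]
    if mut_bp > pc.max_amplicon:
        raise PrimerDesignError(
            f"region {region.name}: mutant junction product ({mut_bp} bp) "
            f"exceeds max_amplicon ({pc.max_amplicon}); reduce outer_offset"
        )
    if wt_bp <= pc.max_amplicon:
        raise PrimerDesignError(
            f"region {region.name}: wild-type F'/R' product ({wt_bp} bp) would "
            f"also amplify (<= max_amplicon {pc.max_amplicon}); the region is "
            f"too small for the size-based mutant/WT split"
        )
    fprp = PrimerPair(
        name=f"Cr-{region.name.split('-')[0]}-F'/R'",
        fwd_seq=fp_c["seq"],
        rev_seq=rp_c["seq"],
        fwd_pos=fp_c["start"],
        rev_pos=rp_c["end"],
        tm_fwd=fp_c["tm"],
        tm_rev=rp_c["tm"],
        expected_wt_bp=None,  # spans the whole region: beyond max_amplicon
        expected_mut_bp=mut_bp,
    )
    return {"FR": fr, "FpRp": fprp}


def _primer_sites(template: str, primer: str, allow_5prime_mismatches: int) -> list[int]:
    """Binding sites of ``primer`` on the top strand (5'->3' left to right)."""
    if allow_5prime_mismatches <= 0:
        hits = []
        i = template.find(primer)
        while i != -1:
            hits.append(i)
            i = template.find(primer, i + 1)
        return hits
    # relaxed mode: the 3'-terminal 8 nt must match exactly; up to N
    # mismatches are tolerated 5' of them (mirrors real tailed primers)
    anchor = primer[-8:]
    head = primer[:-8]
    hits = []
    j = template.find(anchor)
    while j != -1:
        start = j - len(head)
        if start >= 0:
            mismatches = sum(a != b for a, b in zip(template[start:j], head))
            if mismatches <= allow_5prime_mismatches:
                hits.append(start)
        j = template.find(anchor, j + 1)
    return hits


def insilico_pcr(
    template_seq: str,
    fwd: str,
    rev: str,
    max_amplicon: int = 5000,
    allow_5prime_mismatches: int = 0,
) -> list[Amplicon]:
    """All products with exact full-length primer matches, length-capped.

    The forward primer must match the top strand and the reverse primer the
    bottom strand downstream of it. Multiple products are allowed and are
    returned sorted by position; no match means an empty list, not an error.
    ``allow_5prime_mismatches`` relaxes matching to tolerate that many
    mismatches outside the 3'-terminal 8 nt of each primer.
    """
    fwd, rev = fwd.upper(), rev.upper()
    if len(fwd) < 15 or len(rev) < 15:
        raise ValueError("primers must be >= 15 nt")
    fwd_hits = _primer_sites(template_seq, fwd, allow_5prime_mismatches)
    # the reverse primer binds the bottom strand: search the top strand for
    # its reverse complement, whose 3' anchor sits at the *left* end
    rc = revcomp(rev)
    if allow_5prime_mismatches <= 0:
        rev_hits = _primer_sites(template_seq, rc, 0)
    else:
        rev_hits = [
            len(template_seq) - (h + len(rc))
            for h in _primer_sites(revcomp(template_seq), rev, allow_5prime_mismatches)
        ]
        rev_hits.sort()
    products = []
    for i in fwd_hits:
        for j in rev_hits:
            if j < i + len(fwd):
                continue
            end = j + len(rev)
            length = end - i
            if length <= max_amplicon:
                products.append(
                    Amplicon(start=i, end=end, length=length, seq=template_seq[i:end])
                )
    products.sort(key=lambda a: (a.start, a.end))
    return products


# ---------------------------------------------------------------------------
# full construct
# ---------------------------------------------------------------------------

def design_editing_construct(
    genome: AnnotatedGenome,
    region: CandidateRegion,
    marker: str = "Km",
    cfg: ConstructConfig = ConstructConfig(),
    payload: list[PayloadGene] | None = None,
    forbidden_intervals: list[tuple[int, int]] | None = None,
) -> EditingConstruct:
    """Design guides, cloning oligos, arms and all primers for one region.

    ``forbidden_intervals`` (genomic) exclude guide placements — used for
    deletion-replacement, where guides must not target the retained genes
    that come back on the donor.
    """
    if marker not in ("Km", "Sp"):
        raise ValueError("marker must be 'Km' or 'Sp'")
    payload = payload or []
    candidates = scan_pams(genome, region, pam=cfg.pam, spacer_len=cfg.spacer_len)
    if forbidden_intervals:
        candidates = [
            g
            for g in candidates
            if not any(
                g.footprint_start < e and s < g.footprint_end
                for s, e in forbidden_intervals
            )
        ]
        if not candidates:
            raise ValueError(
                f"region {region.name}: no guide placements outside the "
                f"retained-gene intervals"
            )
    guides = select_guides(
        candidates, k=cfg.guides_per_region, gc_range=cfg.gc_range
    )
    oligos = [make_cloning_oligos(g, cfg.overhangs) for g in guides]
    arms = design_arms(genome, region, cfg.arm_bp)
    hits = find_cloning_site_hits(arms, cfg.cloning_sites)
    if hits:
        warnings.warn(
            f"region {region.name}: homology arms contain vector cloning "
            f"site(s) {hits}; consider shifting arm boundaries by up to 50 bp",
            stacklevel=2,
        )
    payload_seq = "".join(p.seq for p in payload)
    fusion = design_fusion_primers(arms, cfg, payload_seq)
    genotyping = design_genotyping_primers(
        genome, region, cfg, payload_bp=len(payload_seq)
    )
    return EditingConstruct(
        region=region,
        guides=guides,
        oligos=oligos,
        arm_up=arms[0],
        arm_down=arms[1],
        fusion_primers=fusion,
        genotype_primers=genotyping,
        marker=marker,
        payload=payload,
        cloning_site_hits=hits,
    )


__all__ = [
    "Amplicon",
    "BAMHI",
    "BGLII",
    "ConstructConfig",
    "EditingConstruct",
    "FusionPrimer",
    "HomologyArm",
    "InsufficientFlankError",
    "PayloadGene",
    "PrimerConfig",
    "PrimerDesignError",
    "PrimerPair",
    "amplify",
    "design_arms",
    "design_editing_construct",
    "design_fusion_primers",
    "design_genotyping_primers",
    "find_cloning_site_hits",
    "insilico_pcr",
    "overlap_extend",
    "primer_tm",
    "simulate_fusion_pcr",
]
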