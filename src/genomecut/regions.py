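"""Enumeration of contiguous nonessential gene regions and their statistics.

A candidate region is a maximal run of consecutive deletable genes. Which
fitness classes count as deletable is controlled by ``breakers``: genes in a
breaker class terminate runs. By default essential, beneficial and unlabeled
(unknown) genes all break runs, so only runs of genes explicitly classified
nonessential are returned. A deletable gene whose interval overlaps a breaker
gene is itself treated as non-deletable (the shared DNA cannot be removed
safely), which also poisons the run it would have joined.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import AnnotatedGenome, CandidateRegion

DEFAULT_BREAKERS = frozenset({"essential", "beneficial", "unknown"})
SPAN_MODES = ("gene-extent", "inter-breaker")


@dataclass(frozen=True)
class RegionStats:
    """Summary of a region set before/after the size filter."""

    n_regions_total: int
    n_regions_over_threshold: int
    total_bp_over_threshold: int
    genome_bp: int
    percent_of_genome: float


def deletable_flags(genome: AnnotatedGenome, breakers=DEFAULT_BREAKERS) -> list[bool]:
    """Per-gene deletability, including overlap poisoning by breaker genes."""
    breakers = frozenset(breakers)
    bad = breakers - {"essential", "beneficial", "unknown"}
    if bad:
        raise ValueError(
            f"breakers must be a subset of {{essential, beneficial, unknown}}; "
            f"got extra {sorted(bad)}"
        )
    genes = genome.genes
    breaker_ivals = [
        (g.start, g.end) for g in genes if g.essentiality in breakers
    ]
    flags = []
    for g in genes:
        if g.essentiality in breakers:
            flags.append(False)
            continue
        overlaps_breaker = any(
            s < g.end and g.start < e for s, e in breaker_ivals
        )
        flags.append(not overlaps_breaker)
    return flags


def find_regions(
    genome: AnnotatedGenome,
    breakers=DEFAULT_BREAKERS,
    span: str = "gene-extent",
) -> list[CandidateRegion]:
    """All maximal runs of consecutive deletable genes, sorted by start.

    No size filter is applied here; see :func:`filter_regions`. ``span``
    selects how a run is turned into genomic coordinates:

    * ``gene-extent`` (default) — start of the first member gene to the end
      of the last member gene; conservative and unambiguous.
    * ``inter-breaker`` — end of the nearest breaker gene on the left to the
      start of the nearest breaker gene on the right, i.e. including the
      flanking intergenic DNA.

    The origin is never wrapped, even for circular genomes.
    """
    if span not in SPAN_MODES:
        raise ValueError(f"span must be one of {SPAN_MODES}")
    genes = genome.genes
    flags = deletable_flags(genome, breakers)
    regions: list[CandidateRegion] = []
    n = len(genes)
    i = 0
    while i < n:
        if not flags[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and flags[j + 1]:
            j += 1
        members = genes[i : j + 1]
        left = genes[i - 1] if i > 0 else None
        right = genes[j + 1] if j + 1 < n else None
        if span == "gene-extent":
            start = members[0].start
            end = max(m.end for m in members)
        else:
            start = left.end if left is not None else 0
            end = right.start if right is not None else len(genome)
        regions.append(
            CandidateRegion(
                start=start,
                end=end,
                member_locus_tags=tuple(m.locus_tag for m in members),
                left_flank_tag=left.locus_tag if left is not None else "chrom_start",
                right_flank_tag=(
                    right.locus_tag if right is not None else "chrom_end"
                ),
            )
        )
        i = j + 1
    return regions


def filter_regions(
    regions: list[CandidateRegion], min_bp: int = 10_000, strict: bool = True
) -> list[CandidateRegion]:
    """Keep regions over ``min_bp``.

    ``strict`` (default) keeps regions with length strictly greater than
    ``min_bp`` — an "over 10 kb" reading under which a region of exactly
    10,000 bp is excluded. With ``strict=False`` the comparison is >=.
    """
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    if strict:
        return [r for r in regions if r.length_bp > min_bp]
    return [r for r in regions if r.length_bp >= min_bp]


def region_stats(
    regions: list[CandidateRegion],
    filtered: list[CandidateRegion],
    genome_bp: int,
) -> RegionStats:
    """Count / total-bp / percent-of-chromosome summary of a filtered subset."""
    if genome_bp <= 0:
        raise ValueError("genome_bp must be positive")
    if not set(id(r) for r in filtered) <= set(id(r) for r in regions):
        # allow value-equal subsets too (e.g. re-read from disk)
        if not all(f in regions for f in filtered):
            raise ValueError("filtered must be a subset of regions")
    total = sum(r.length_bp for r in filtered)
    return RegionStats(
        n_regions_total=len(regions),
        n_regions_over_threshold=len(filtered),
        total_bp_over_threshold=total,
        genome_bp=genome_bp,
        percent_of_genome=round(100.0 * total / genome_bp, 2),
    )


__all__ = [
    "DEFAULT_BREAKERS",
    "RegionStats",
    "deletable_flags",
    "filter_regions",
    "find_regions",
    "region_stats",
]
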