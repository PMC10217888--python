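"""Cpf1 (Cas12a) guide design inside candidate deletion regions.

Cpf1 recognises a T-rich PAM 5' of the protospacer. Here the PAM pattern is
``TTN`` and the protospacer is the 22 nt immediately 3' of the PAM on the PAM
strand; both are configurable. Because the editing plasmid keeps expressing
the crRNA while chromosome copies segregate, every guide footprint must lie
entirely inside the region being deleted: once the deletion is in place the
repaired chromosome no longer contains the target and stops being cleaved.
"""

from __future__ import annotations

import functools
import warnings
from collections import Counter
from dataclasses import dataclass, replace

from .model import AnnotatedGenome, CandidateRegion, gc_fraction, revcomp

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: Placeholder 4-nt sticky ends for the AarI-digested vector. AarI cuts
#: outside its recognition site and the overhang it leaves is defined by the
#: vector sequence, which is a property of the plasmid stock in use — set
#: these to match your vector.
DEFAULT_OVERHANGS = ("AGAT", "AAAC")


@dataclass(frozen=True)
class Guide:
    """One Cpf1 target site: PAM + protospacer, with placement metadata.

    ``pam_start`` is the genomic coordinate of the first PAM base as read on
    the PAM strand; ``footprint_start``/``footprint_end`` bound the full
    PAM+protospacer site in genome coordinates regardless of strand.
    """

    region_name: str
    strand: str
    pam_start: int
    pam_seq: str
    protospacer: str
    gc_fraction: float
    genome_hit_count: int
    footprint_start: int
    footprint_end: int

    @property
    def site_seq(self) -> str:
        """PAM + protospacer as read on the PAM strand."""
        return self.pam_seq + self.protospacer


@dataclass(frozen=True)
class CloningOligoPair:
    """Annealing oligo pair that rebuilds the guide cassette with sticky ends.

    ``top_oligo`` = left overhang + core; ``bottom_oligo`` = right overhang +
    reverse complement of the core, so the annealed duplex carries the core
    double-stranded with the two configured 4-nt 5' overhangs, ready for
    ligation into the AarI-digested vector.
    """

    guide: Guide
    top_oligo: str
    bottom_oligo: str
    overhangs: tuple[str, str]

    @property
    def core(self) -> str:
        return self.top_oligo[len(self.overhangs[0]):]


def pam_matches(seq: str, pattern: str) -> bool:
    if len(seq) != len(pattern):
        return False
    return all(base in IUPAC[p] for base, p in zip(seq, pattern.upper()))


def count_occurrences(haystack: str, needle: str) -> int:
    """Overlapping occurrence count of ``needle`` in ``haystack``."""
    count = 0
    i = haystack.find(needle)
    while i != -1:
        count += 1
        i = haystack.find(needle, i + 1)
    return count


@functools.lru_cache(maxsize=4)
def _site_counter(genome_seq: str, k: int) -> Counter:
    """Counts of every k-mer on both strands of the genome (small genomes)."""
    counts: Counter = Counter()
    rc = revcomp(genome_seq)
    for s in (genome_seq, rc):
        for i in range(len(s) - k + 1):
            counts[s[i : i + k]] += 1
    return counts


def genome_hit_count(genome_seq: str, site: str) -> int:
    """Occurrences of ``site`` in the genome, counting both strands."""
    if len(genome_seq) <= 500_000:
        return _site_counter(genome_seq, len(site))[site]
    return count_occurrences(genome_seq, site) + count_occurrences(
        genome_seq, revcomp(site)
    )


def scan_pams(
    genome: AnnotatedGenome,
    region: CandidateRegion,
    pam: str = "TTN",
    spacer_len: int = 22,
) -> list[Guide]:
    """Every PAM site (both strands) whose protospacer stays inside the region.

    Returns guides sorted by genomic footprint position. A region too short
    to hold PAM + spacer yields an empty list with a warning.
    """
    pam = pam.upper()
    plen = len(pam)
    site_len = plen + spacer_len
    if region.length_bp < site_len:
        warnings.warn(
            f"region {region.name} ({region.length_bp} bp) shorter than "
            f"PAM+spacer ({site_len} bp); no guides possible",
            stacklevel=2,
        )
        return []
    seq = genome.sequence
    guides: list[Guide] = []
    # plus strand: PAM at [i, i+plen), spacer at [i+plen, i+plen+spacer_len)
    for i in range(region.start, region.end - site_len + 1):
        pam_seq = seq[i : i + plen]
        if pam_matches(pam_seq, pam):
            spacer = seq[i + plen : i + site_len]
            guides.append(
                Guide(
                    region_name=region.name,
                    strand="+",
                    pam_start=i,
                    pam_seq=pam_seq,
                    protospacer=spacer,
                    gc_fraction=gc_fraction(spacer),
                    genome_hit_count=genome_hit_count(seq, pam_seq + spacer),
                    footprint_start=i,
                    footprint_end=i + site_len,
                )
            )
    # minus strand: PAM occupies genomic [j, j+plen) read 3'->5' on top, i.e.
    # its reverse complement matches the pattern; spacer is genomic
    # [j-spacer_len, j) read on the minus strand.
    for j in range(region.start + spacer_len, region.end - plen + 1):
        window = seq[j : j + plen]
        pam_seq = revcomp(window)
        if pam_matches(pam_seq, pam):
            spacer = revcomp(seq[j - spacer_len : j])
            guides.append(
                Guide(
                    region_name=region.name,
                    strand="-",
                    pam_start=j + plen - 1,
                    pam_seq=pam_seq,
                    protospacer=spacer,
                    gc_fraction=gc_fraction(spacer),
                    genome_hit_count=genome_hit_count(seq, pam_seq + spacer),
                    footprint_start=j - spacer_len,
                    footprint_end=j + plen,
                )
            )
    guides.sort(key=lambda g: (g.footprint_start, g.strand))
    return guides


class GuideSelectionError(ValueError):
    pass


def select_guides(
    candidates: list[Guide],
    k: int = 2,
    gc_range: tuple[float, float] = (0.3, 0.7),
    require_unique: bool = True,
    seed_check: int | None = None,
    genome_seq: str | None = None,
) -> list[Guide]:
    """Pick ``k`` guides, one near each end of the region.

    Policy: guides with a unique full-length genome match are mandatory
    (relaxable via ``require_unique``); GC within ``gc_range`` is preferred
    but not mandatory; the k picks target k evenly spaced anchor points from
    the region start to the region end, ties broken by proximity to the
    anchor then by lower coordinate. Deterministic for identical input.

    ``seed_check`` additionally requires the PAM plus the PAM-proximal
    ``seed_check``-mer of the protospacer to be unique in the genome (both
    strands) — a stricter off-target stance than full-length uniqueness;
    needs ``genome_seq``.
    """
    if not candidates:
        raise GuideSelectionError("no candidate guides to select from")
    pool = [g for g in candidates if g.genome_hit_count == 1] if require_unique else list(candidates)
    if seed_check is not None:
        if genome_seq is None:
            raise ValueError("seed_check requires genome_seq")
        pool = [
            g
            for g in pool
            if genome_hit_count(genome_seq, g.pam_seq + g.protospacer[:seed_check]) == 1
        ]
    if len(pool) < k:
        raise GuideSelectionError(
            f"only {len(pool)} candidate guides pass the mandatory filters "
            f"(need {k}); relaxable filters: require_unique, seed_check"
        )
    lo = min(g.footprint_start for g in candidates)
    hi = max(g.footprint_end for g in candidates)
    anchors = (
        [lo]
        if k == 1
        else [lo + round(t * (hi - lo) / (k - 1)) for t in range(k)]
    )
    chosen: list[Guide] = []
    remaining = list(pool)
    for anchor in anchors:
        def key(g: Guide):
            gc_ok = gc_range[0] <= g.gc_fraction <= gc_range[1]
            center = (g.footprint_start + g.footprint_end) // 2
            return (not gc_ok, abs(center - anchor), g.footprint_start, g.strand)

        best = min(remaining, key=key)
        chosen.append(best)
        remaining.remove(best)
    chosen.sort(key=lambda g: g.footprint_start)
    return chosen


def make_cloning_oligos(
    guide: Guide, overhangs: tuple[str, str] = DEFAULT_OVERHANGS
) -> CloningOligoPair:
    """Annealing oligo pair carrying PAM + spacer between AarI sticky ends."""
    left, right = (o.upper() for o in overhangs)
    for o in (left, right):
        if len(o) != 4 or set(o) - set("ACGT"):
            raise ValueError(f"overhangs must be 4-nt DNA strings, got {o!r}")
    core = guide.site_seq
    return CloningOligoPair(
        guide=guide,
        top_oligo=left + core,
        bottom_oligo=right + revcomp(core),
        overhangs=(left, right),
    )


def annealed_core_mismatches(pair: CloningOligoPair) -> int:
    """Mismatch count between the two core strands after annealing (0 = perfect)."""
    top_core = pair.top_oligo[len(pair.overhangs[0]):]
    bottom_core = pair.bottom_oligo[len(pair.overhangs[1]):]
    paired = revcomp(bottom_core)
    if len(paired) != len(top_core):
        return max(len(paired), len(top_core))
    return sum(a != b for a, b in zip(top_core, paired))


__all__ = [
    "DEFAULT_OVERHANGS",
    "CloningOligoPair",
    "Guide",
    "GuideSelectionError",
    "annealed_core_mismatches",
    "count_occurrences",
    "genome_hit_count",
    "make_cloning_oligos",
    "pam_matches",
    "scan_pams",
    "select_guides",
    "replace",
]
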