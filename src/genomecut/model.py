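"""Core data model: annotated genomes, candidate deletion regions, count matrices.

All coordinates inside the package are 0-based half-open. Conversion to and
from 1-based inclusive (GFF3) or 0-based half-open (BED) happens only at the
I/O boundary (:mod:`genomecut.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

ESSENTIALITY_CATEGORIES = ("essential", "beneficial", "nonessential", "unknown")

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement of a plain DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def abbreviate_tag(locus_tag: str) -> str:
    """Short form of a locus tag: the part after the last underscore.

    ``Synpcc7942_0051`` -> ``0051``; tags without an underscore are returned
    unchanged.
    """
    return locus_tag.rsplit("_", 1)[-1] if "_" in locus_tag else locus_tag


@dataclass(frozen=True)
class GeneRecord:
    """One gene with its fitness classification.

    ``start``/``end`` are 0-based half-open genomic coordinates; essentiality
    is one of essential / beneficial / nonessential (from transposon-based
    essentiality mapping) or unknown when no label was provided.
    """

    locus_tag: str
    start: int
    end: int
    strand: str = "+"
    essentiality: str = "unknown"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.locus_tag}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.locus_tag}: strand must be + or -")
        if self.essentiality not in ESSENTIALITY_CATEGORIES:
            raise ValueError(
                f"gene {self.locus_tag}: unknown essentiality category "
                f"{self.essentiality!r}; expected one of {ESSENTIALITY_CATEGORIES}"
            )

    @property
    def length_bp(self) -> int:
        return self.end - self.start


@dataclass
class AnnotatedGenome:
    """A single circular (or linear) chromosome plus its ordered gene models."""

    chrom_id: str
    sequence: str
    genes: list[GeneRecord] = field(default_factory=list)
    circular: bool = True

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if len(seq) < 1:
            raise ValueError("genome sequence must be non-empty")
        bad = set(seq) - set("ACGT")
        if bad:
            raise ValueError(
                f"genome sequence contains non-ACGT characters: {sorted(bad)}"
            )
        self.sequence = seq
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end, g.locus_tag))
        n = len(seq)
        for g in self.genes:
            if g.end > n:
                raise ValueError(
                    f"gene {g.locus_tag} interval [{g.start}, {g.end}) outside "
                    f"sequence of length {n}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def gene(self, locus_tag: str) -> GeneRecord:
        for g in self.genes:
            if g.locus_tag == locus_tag:
                return g
        raise KeyError(locus_tag)

    def slice(self, start: int, end: int) -> str:
        """Sequence of [start, end); wraps the origin only for circular genomes."""
        n = len(self.sequence)
        if 0 <= start <= end <= n:
            return self.sequence[start:end]
        if not self.circular:
            raise ValueError(
                f"slice [{start}, {end}) outside linear genome of length {n}"
            )
        # modular wrap for circular chromosomes
        start %= n
        end %= n
        if start < end:
            return self.sequence[start:end]
        return self.sequence[start:] + self.sequence[:end]

    def overlapping_pairs(self) -> list[tuple[str, str]]:
        """Locus-tag pairs of overlapping gene models (allowed, but flagged)."""
        out = []
        for a, b in zip(self.genes, self.genes[1:]):
            if b.start < a.end:
                out.append((a.locus_tag, b.locus_tag))
        return out

    def with_genes(self, genes: list[GeneRecord]) -> "AnnotatedGenome":
        return AnnotatedGenome(
            chrom_id=self.chrom_id,
            sequence=self.sequence,
            genes=genes,
            circular=self.circular,
        )


@dataclass(frozen=True)
class CandidateRegion:
    """A maximal run of consecutive deletable (nonessential) genes.

    ``start``/``end`` span the gene extent (first member start to last member
    end) by default. ``left_flank_tag``/``right_flank_tag`` name the nearest
    non-deletable gene on each side, or the sentinels ``chrom_start`` /
    ``chrom_end``.
    """

    start: int
    end: int
    member_locus_tags: tuple[str, ...]
    left_flank_tag: str = "chrom_start"
    right_flank_tag: str = "chrom_end"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("region must have positive length")
        if not self.member_locus_tags:
            raise ValueError("region must have at least one member gene")

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    @property
    def name(self) -> str:
        first = abbreviate_tag(self.member_locus_tags[0])
        last = abbreviate_tag(self.member_locus_tags[-1])
        return f"{first}-{last}"


@dataclass
class CountMatrix:
    """Gene-level fragment counts (genes x samples) with gene lengths in bp."""

    gene_ids: list[str]
    gene_lengths_bp: np.ndarray
    samples: list[str]
    counts: np.ndarray
    conditions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_lengths_bp = np.asarray(self.gene_lengths_bp, dtype=np.int64)
        self.counts = np.asarray(self.counts)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")
        if np.any(self.gene_lengths_bp < 1):
            raise ValueError("gene lengths must be >= 1 bp")
        if self.counts.shape != (len(self.gene_ids), len(self.samples)):
            raise ValueError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.samples)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                raise ValueError("counts must be integers")
            self.counts = as_int
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.gene_ids, columns=self.samples)
        df.insert(0, "length_bp", self.gene_lengths_bp)
        df.index.name = "gene_id"
        return df

    def sample_index(self, sample_ids: list[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([pos[s] for s in sample_ids], dtype=np.intp)
        except KeyError as exc:  # pragma: no cover - message formatting
            raise KeyError(f"unknown sample id {exc.args[0]!r}") from None

    def gene_index(self, gene_ids: list[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in pos]
        if missing:
            raise KeyError(f"gene ids not in count matrix: {missing[:5]}")
        return np.array([pos[g] for g in gene_ids], dtype=np.intp)


__all__ = [
    "ESSENTIALITY_CATEGORIES",
    "AnnotatedGenome",
    "CandidateRegion",
    "CountMatrix",
    "GeneRecord",
    "abbreviate_tag",
    "gc_fraction",
    "revcomp",
    "replace",
]
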