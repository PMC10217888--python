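"""Readers and writers for the external file formats.

Conventions enforced here, once, so the rest of the package never converts:

* FASTA — genome sequence, exactly one record.
* GFF3  — gene models, 1-based inclusive coordinates on disk.
* TSV   — essentiality labels (``locus_tag<TAB>essentiality``) and count
  matrices (``gene_id``, ``length_bp``, one column per sample).
* BED6  — candidate regions, 0-based half-open on disk.
* JSON  — deletion plans (schema-versioned, lossless).
"""

from __future__ import annotations

import json
import os
from urllib.parse import quote, unquote

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    ESSENTIALITY_CATEGORIES,
    AnnotatedGenome,
    CandidateRegion,
    CountMatrix,
    GeneRecord,
)

PLAN_SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# genome: FASTA + GFF3 + essentiality TSV
# ---------------------------------------------------------------------------

def read_essentiality_tsv(path: str | os.PathLike) -> dict[str, str]:
    """Read the two-column essentiality table into ``{locus_tag: category}``.

    Categories are matched case-insensitively against the three fitness
    classes; anything else is an error rather than being coerced, so typos in
    the input surface immediately. Duplicate locus tags are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.shape[1] < 2 or df.columns[0] != "locus_tag":
        raise ValueError(
            f"{path}: expected header 'locus_tag<TAB>essentiality', "
            f"got columns {list(df.columns)}"
        )
    valid = {"essential", "beneficial", "nonessential"}
    labels: dict[str, str] = {}
    for tag, cat in zip(df.iloc[:, 0], df.iloc[:, 1]):
        if tag in labels:
            raise ValueError(f"{path}: duplicate locus_tag {tag!r}")
        cat_l = str(cat).strip().lower()
        if cat_l not in valid:
            raise ValueError(
                f"{path}: unknown essentiality category {cat!r} for {tag!r}; "
                f"expected one of {sorted(valid)}"
            )
        labels[tag] = cat_l
    return labels


def _parse_gff_attributes(attr_field: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in attr_field.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key.strip()] = unquote(value.strip())
    return out


def read_gff_genes(
    path: str | os.PathLike,
    feature_type: str = "gene",
    chrom_id: str | None = None,
) -> list[GeneRecord]:
    """Read gene intervals from GFF3 (1-based inclusive -> 0-based half-open).

    The locus tag is taken from the ``locus_tag`` attribute, falling back to
    ``ID``. Only rows of ``feature_type`` (default ``gene``; ``CDS`` is the
    usual alternative) are kept.
    """
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype != feature_type:
                continue
            if chrom_id is not None and seqid != chrom_id:
                raise ValueError(
                    f"{path}:{lineno}: feature on {seqid!r} but genome is {chrom_id!r}"
                )
            attr = _parse_gff_attributes(attrs)
            tag = attr.get("locus_tag") or attr.get("ID")
            if not tag:
                raise ValueError(f"{path}:{lineno}: feature lacks locus_tag/ID")
            s1, e1 = int(start), int(end)
            if s1 < 1 or e1 < s1:
                raise ValueError(f"{path}:{lineno}: bad 1-based interval {s1}..{e1}")
            genes.append(
                GeneRecord(
                    locus_tag=tag,
                    start=s1 - 1,  # 1-based inclusive -> 0-based half-open
                    end=e1,
                    strand=strand if strand in "+-" else "+",
                )
            )
    return genes


def read_genome(
    fasta_path: str | os.PathLike,
    gff_path: str | os.PathLike,
    essentiality_tsv_path: str | os.PathLike | None = None,
    feature_type: str = "gene",
    circular: bool = True,
) -> AnnotatedGenome:
    """Load a genome with annotations and (optionally) essentiality labels.

    Genes present in the GFF but absent from the essentiality table default
    to ``unknown`` and will by default break candidate regions downstream.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ValueError(
            f"{fasta_path}: expected exactly one FASTA record, found {len(records)}"
        )
    rec = records[0]
    genes = read_gff_genes(gff_path, feature_type=feature_type, chrom_id=rec.id)
    labels = (
        read_essentiality_tsv(essentiality_tsv_path)
        if essentiality_tsv_path is not None
        else {}
    )
    genes = [
        GeneRecord(
            locus_tag=g.locus_tag,
            start=g.start,
            end=g.end,
            strand=g.strand,
            essentiality=labels.get(g.locus_tag, "unknown"),
        )
        for g in genes
    ]
    return AnnotatedGenome(
        chrom_id=rec.id, sequence=str(rec.seq), genes=genes, circular=circular
    )


def read_genome_sequence_only(fasta_path: str | os.PathLike) -> str:
    """Just the (single) uppercased sequence of a FASTA file."""
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ValueError(
            f"{fasta_path}: expected exactly one FASTA record, found {len(records)}"
        )
    return str(records[0].seq).upper()


def write_genome(
    genome: AnnotatedGenome,
    fasta_path: str | os.PathLike,
    gff_path: str | os.PathLike,
    essentiality_tsv_path: str | os.PathLike | None = None,
) -> None:
    """Write FASTA + GFF3 (+ essentiality TSV) for a genome object."""
    rec = SeqRecord(Seq(genome.sequence), id=genome.chrom_id, description="")
    SeqIO.write([rec], str(fasta_path), "fasta")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.chrom_id} 1 {len(genome)}\n")
        for g in genome.genes:
            attrs = f"ID={quote(g.locus_tag)};locus_tag={quote(g.locus_tag)}"
            fh.write(
                "\t".join(
                    [
                        genome.chrom_id,
                        "genomecut",
                        "gene",
                        str(g.start + 1),  # back to 1-based inclusive
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
    if essentiality_tsv_path is not None:
        with open(essentiality_tsv_path, "w") as fh:
            fh.write("locus_tag\tessentiality\n")
            for g in genome.genes:
                if g.essentiality != "unknown":
                    fh.write(f"{g.locus_tag}\t{g.essentiality}\n")


# ---------------------------------------------------------------------------
# regions: BED6
# ---------------------------------------------------------------------------

def write_regions_bed(
    regions: list[CandidateRegion], path: str | os.PathLike, chrom_id: str = "chrom"
) -> None:
    """Write candidate regions as BED6 (0-based half-open; score = length)."""
    with open(path, "w") as fh:
        fh.write(
            "# genomecut candidate regions; BED6, name=first-last member tag, "
            "score=length_bp\n"
        )
        for r in regions:
            members = ",".join(r.member_locus_tags)
            fh.write(
                f"{chrom_id}\t{r.start}\t{r.end}\t{r.name}\t{r.length_bp}\t+"
                f"\t{members}\t{r.left_flank_tag}\t{r.right_flank_tag}\n"
            )


def read_regions_bed(path: str | os.PathLike) -> list[CandidateRegion]:
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}: expected >= 6 BED columns")
            start, end = int(fields[1]), int(fields[2])
            members = tuple(fields[6].split(",")) if len(fields) > 6 else (fields[3],)
            left = fields[7] if len(fields) > 7 else "chrom_start"
            right = fields[8] if len(fields) > 8 else "chrom_end"
            regions.append(
                CandidateRegion(
                    start=start,
                    end=end,
                    member_locus_tags=members,
                    left_flank_tag=left,
                    right_flank_tag=right,
                )
            )
    return regions


# ---------------------------------------------------------------------------
# count matrices: TSV
# ---------------------------------------------------------------------------

def write_counts_tsv(counts: CountMatrix, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        if counts.conditions:
            cond = ",".join(f"{s}={counts.conditions[s]}" for s in counts.samples)
            fh.write(f"# conditions: {cond}\n")
        counts.to_dataframe().to_csv(fh, sep="\t")


def read_counts_tsv(path: str | os.PathLike) -> CountMatrix:
    conditions: dict[str, str] = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# conditions:"):
            for item in first.partition(":")[2].strip().split(","):
                s, _, c = item.partition("=")
                conditions[s] = c
        else:
            fh.seek(0)
        df = pd.read_csv(fh, sep="\t", index_col=0)
    if df.columns[0] != "length_bp":
        raise ValueError(f"{path}: second column must be 'length_bp'")
    samples = [str(c) for c in df.columns[1:]]
    return CountMatrix(
        gene_ids=[str(g) for g in df.index],
        gene_lengths_bp=df["length_bp"].to_numpy(),
        samples=samples,
        counts=df[samples].to_numpy(),
        conditions=conditions,
    )


# ---------------------------------------------------------------------------
# deletion plans: JSON
# ---------------------------------------------------------------------------

def write_plan_json(plan, path: str | os.PathLike) -> None:
    from .plans import plan_to_dict

    payload = plan_to_dict(plan)
    payload["schema_version"] = PLAN_SCHEMA_VERSION
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_plan_json(path: str | os.PathLike):
    from .plans import plan_from_dict

    with open(path) as fh:
        payload = json.load(fh)
    version = payload.get("schema_version")
    if version != PLAN_SCHEMA_VERSION:
        raise ValueError(
            f"{path}: unsupported plan schema version {version!r} "
            f"(this build reads version {PLAN_SCHEMA_VERSION})"
        )
    return plan_from_dict(payload)


__all__ = [
    "PLAN_SCHEMA_VERSION",
    "read_counts_tsv",
    "read_essentiality_tsv",
    "read_genome",
    "read_genome_sequence_only",
    "read_gff_genes",
    "read_plan_json",
    "read_regions_bed",
    "write_counts_tsv",
    "write_genome",
    "write_plan_json",
    "write_regions_bed",
]
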