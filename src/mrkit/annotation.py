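"""Offline mapping of instrument variants to overlapping protein-coding
genes from a user-supplied gene-interval file (BED or GFF3).

A variant maps to every gene whose closed interval [start, end] contains its
position on the same chromosome; variants overlapping no gene are retained
with an empty gene list (rendered "-" in reports). BED intervals (0-based,
half-open) are converted to 1-based closed; GFF3 is 1-based closed as-is.
Strand is carried through but does not affect overlap.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .summary_io import normalize_chrom

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneInterval:
    """One gene's genomic span (1-based, closed)."""

    chrom: int
    start: int
    end: int
    strand: str
    gene_id: str
    gene_name: str

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start exceeds end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -")


@dataclass(frozen=True)
class VariantAnnotation:
    rsid: str
    chrom: int | None
    pos: int | None
    genes: tuple[tuple[str, str], ...]  # (gene_id, gene_name) pairs


def read_bed(path) -> list[GeneInterval]:
    """Read gene intervals from BED (3+ columns, 0-based half-open).

    The optional 4th (name) column is parsed as ``gene_id|gene_name``; a
    bare name fills both fields. The optional 6th column supplies strand.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    genes = []
    for row in df.itertuples(index=False):
        fields = list(row)
        chrom = normalize_chrom(fields[0])
        start, end = int(fields[1]), int(fields[2])
        name = fields[3] if len(fields) > 3 and pd.notna(fields[3]) else f"{chrom}:{start}"
        gene_id, _, gene_name = name.partition("|")
        strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "+"
        genes.append(
            GeneInterval(chrom, start + 1, end, strand, gene_id, gene_name or gene_id)
        )
    return genes


def read_gff3(path) -> list[GeneInterval]:
    """Read gene features from GFF3 (1-based closed; ID/Name attributes)."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9 or fields[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID", "").removeprefix("gene:") or f"{fields[0]}:{fields[3]}"
            genes.append(
                GeneInterval(
                    chrom=normalize_chrom(fields[0]),
                    start=int(fields[3]),
                    end=int(fields[4]),
                    strand=fields[6] if fields[6] in ("+", "-") else "+",
                    gene_id=gene_id,
                    gene_name=attrs.get("Name", gene_id),
                )
            )
    return genes


def read_gene_intervals(path) -> list[GeneInterval]:
    """Dispatch on file extension: .bed -> BED, .gff/.gff3 -> GFF3."""
    p = str(path).lower()
    if p.endswith(".bed"):
        return read_bed(path)
    if p.endswith((".gff", ".gff3")):
        return read_gff3(path)
    raise ValueError(f"unrecognized gene-interval format: {path}")


def annotate(
    variants: Sequence[tuple[str, object, object]],
    genes: Iterable[GeneInterval],
) -> list[VariantAnnotation]:
    """Map each (rsid, chrom, pos) to all overlapping gene intervals.

    Output order and length match the input; variants with an unknown
    chromosome code or no overlapping gene get an empty gene list.
    """
    trees: dict[int, IntervalTree] = {}
    for g in genes:
        # interval trees are half-open; +1 makes [start, end] inclusive
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g)
    out = []
    for rsid, chrom, pos in variants:
        try:
            c = normalize_chrom(chrom)
            p = int(pos)
            if p < 1:
                raise ValueError
        except (ValueError, TypeError):
            log.warning("variant %s: unresolvable coordinates (%r, %r)", rsid, chrom, pos)
            out.append(VariantAnnotation(rsid, None, None, ()))
            continue
        hits = sorted(
            (iv.data for iv in trees.get(c, IntervalTree()).at(p)),
            key=lambda g: (g.start, g.gene_id),
        )
        out.append(
            VariantAnnotation(rsid, c, p, tuple((g.gene_id, g.gene_name) for g in hits))
        )
    return out


def annotation_frame(annotations: Sequence[VariantAnnotation]) -> pd.DataFrame:
    """Tab-ready report: one row per variant, "-" where nothing mapped."""
    rows = []
    for a in annotations:
        rows.append(
            {
                "rsid": a.rsid,
                "chrom": a.chrom if a.chrom is not None else "-",
                "pos": a.pos if a.pos is not None else "-",
                "gene_ids": ",".join(g[0] for g in a.genes) or "-",
                "gene_names": ",".join(g[1] for g in a.genes) or "-",
            }
        )
    return pd.DataFrame(rows, columns=["rsid", "chrom", "pos", "gene_ids", "gene_names"])
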