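"""Genomic-feature annotation of DMRs.

Feature classes follow HOMER-style definitions: *promoter* is the
strand-aware window from 1 kb upstream to 100 bp downstream of the TSS;
*intragenic* is the gene body (exons, UTRs, introns) extended 1 kb past the
TES; everything else is *intergenic*.  A DMR overlapping both a promoter and
a gene body reports promoter.  Overlap means at least 1 bp of intersection.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import DmrCall, GeneModel

__all__ = [
    "GeneIndex",
    "classify_feature",
    "distance_to_tss",
    "assign_genes",
    "annotate_dmrs",
]

PROMOTER_UP = 1000
PROMOTER_DOWN = 100
TES_EXTENSION = 1000


def promoter_interval(gene: GeneModel) -> tuple[int, int]:
    """Strand-aware [TSS-1kb, TSS+100bp) promoter window, clipped at 0."""
    if gene.strand == "+":
        lo, hi = gene.tss - PROMOTER_UP, gene.tss + PROMOTER_DOWN
    else:
        lo, hi = gene.tss - PROMOTER_DOWN, gene.tss + PROMOTER_UP
    return max(lo, 0), hi


def extended_body(gene: GeneModel) -> tuple[int, int]:
    """Gene extent extended 1 kb past the TES (strand-aware), clipped at 0."""
    if gene.strand == "+":
        return gene.start, gene.end + TES_EXTENSION
    return max(gene.start - TES_EXTENSION, 0), gene.end


class GeneIndex:
    """Interval index over promoters, extended gene bodies, and TSSs."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.genes = list(genes)
        self._promoters: dict[str, IntervalTree] = {}
        self._bodies: dict[str, IntervalTree] = {}
        tss_by_chrom: dict[str, list] = {}
        for g in self.genes:
            lo, hi = promoter_interval(g)
            if hi > lo:
                self._promoters.setdefault(g.chrom, IntervalTree()).addi(lo, hi, g)
            lo, hi = extended_body(g)
            if hi > lo:
                self._bodies.setdefault(g.chrom, IntervalTree()).addi(lo, hi, g)
            tss_by_chrom.setdefault(g.chrom, []).append((g.tss, g.gene_id, g.strand))
        # sorted TSS arrays; gene_id order breaks distance ties
        self._tss: dict[str, tuple[np.ndarray, list]] = {}
        for chrom, entries in tss_by_chrom.items():
            entries.sort(key=lambda e: (e[0], e[1]))
            self._tss[chrom] = (
                np.array([e[0] for e in entries], dtype=np.int64),
                entries,
            )

    def promoter_hits(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        tree = self._promoters.get(chrom)
        return [iv.data for iv in tree.overlap(start, end)] if tree else []

    def body_hits(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        tree = self._bodies.get(chrom)
        return [iv.data for iv in tree.overlap(start, end)] if tree else []


def _as_index(genes) -> GeneIndex:
    return genes if isinstance(genes, GeneIndex) else GeneIndex(genes)


def classify_feature(interval: tuple[str, int, int], genes) -> str:
    """Classify a DMR interval as promoter, intragenic, or intergenic."""
    chrom, start, end = interval
    index = _as_index(genes)
    if index.promoter_hits(chrom, start, end):
        return "promoter"
    if index.body_hits(chrom, start, end):
        return "intragenic"
    return "intergenic"


def distance_to_tss(interval: tuple[str, int, int], genes) -> tuple[float, str | None]:
    """Signed distance from the DMR centre to the nearest TSS.

    Positive means downstream of the TSS in the gene's orientation, negative
    upstream; ties in absolute distance are broken by the lexicographically
    smaller gene_id.  Returns (nan, None) when the chromosome has no genes.
    """
    chrom, start, end = interval
    index = _as_index(genes)
    if chrom not in index._tss:
        return float("nan"), None
    center = (start + end) // 2
    positions, entries = index._tss[chrom]
    j = int(np.searchsorted(positions, center))
    best = None
    for i in range(max(0, j - 1), min(len(entries), j + 2)):
        tss, gid, strand = entries[i]
        d_abs = abs(center - tss)
        key = (d_abs, gid)
        if best is None or key < best[0]:
            signed = center - tss if strand == "+" else tss - center
            best = (key, signed, gid)
    # candidates beyond the immediate neighbours can never be closer because
    # positions are sorted, except under gene_id tie-breaks at equal distance;
    # scan outward while |distance| ties are possible
    d0 = best[0][0]
    lo, hi = j - 2, j + 2
    while lo >= 0 and abs(center - positions[lo]) == d0:
        tss, gid, strand = entries[lo]
        key = (d0, gid)
        if key < best[0]:
            best = (key, center - tss if strand == "+" else tss - center, gid)
        lo -= 1
    while hi < len(entries) and abs(center - positions[hi]) == d0:
        tss, gid, strand = entries[hi]
        key = (d0, gid)
        if key < best[0]:
            best = (key, center - tss if strand == "+" else tss - center, gid)
        hi += 1
    return float(best[1]), best[2]


def assign_genes(
    dmrs: Sequence[DmrCall],
    genes,
    mode: str = "intragenic_plus_promoter",
    window_bp: int = 50_000,
) -> list[set[str]]:
    """Gene sets assigned to each DMR (parallel to the input order).

    Default mode assigns every gene for which the DMR is promoter or
    intragenic; window mode assigns genes whose TSS lies within
    ``window_bp`` of the DMR centre.  A DMR may map to several genes; an
    empty set means intergenic for association purposes.
    """
    index = _as_index(genes)
    out: list[set[str]] = []
    if mode == "intragenic_plus_promoter":
        for d in dmrs:
            hits = index.promoter_hits(d.chrom, d.start, d.end)
            hits += index.body_hits(d.chrom, d.start, d.end)
            out.append({g.gene_id for g in hits})
    elif mode == "window":
        for d in dmrs:
            if d.chrom not in index._tss:
                out.append(set())
                continue
            center = (d.start + d.end) // 2
            positions, entries = index._tss[d.chrom]
            lo = int(np.searchsorted(positions, center - window_bp, side="left"))
            hi = int(np.searchsorted(positions, center + window_bp, side="right"))
            out.append({entries[i][1] for i in range(lo, hi)})
    else:
        raise ValueError(f"unknown assignment mode {mode!r}")
    return out


def annotate_dmrs(dmrs: Sequence[DmrCall], genes, mode: str = "intragenic_plus_promoter",
                  window_bp: int = 50_000) -> pd.DataFrame:
    """Annotated DMR table: feature class, nearest-TSS distance, gene sets."""
    index = _as_index(genes)
    gene_sets = assign_genes(dmrs, index, mode=mode, window_bp=window_bp)
    rows = []
    for d, gs in zip(dmrs, gene_sets):
        dist, gid = distance_to_tss((d.chrom, d.start, d.end), index)
        rows.append(
            {
                "chrom": d.chrom,
                "start": d.start,
                "end": d.end,
                "category": d.category,
                "timing": d.timing,
                "feature_class": classify_feature((d.chrom, d.start, d.end), index),
                "tss_distance": dist,
                "nearest_gene": gid,
                "assigned_genes": ",".join(sorted(gs)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "category", "timing", "feature_class",
            "tss_distance", "nearest_gene", "assigned_genes",
        ],
    )
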