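"""DMR-to-expression association against a random-segment background.

The question: are DMRs located in genes that are postnatally upregulated
more often than random, length-matched DNA segments would be?  Foreground
and background pass through byte-identical gene-assignment logic; the two
proportions are compared with a pooled-variance two-proportion z-test

    z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2)),   p = (k1+k2)/(n1+n2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .annotation import GeneIndex, assign_genes
from .io import DmrCall, SampleInfo

__all__ = [
    "AssociationResult",
    "upregulated_genes",
    "random_segments",
    "proportion_ztest",
    "dmr_gene_enrichment",
]


@dataclass
class AssociationResult:
    k_dmr: int
    n_dmr: int
    k_bg: int
    n_bg: int
    z_stat: float
    p_value: float

    @property
    def prop_dmr(self) -> float:
        return self.k_dmr / self.n_dmr if self.n_dmr else float("nan")

    @property
    def prop_bg(self) -> float:
        return self.k_bg / self.n_bg if self.n_bg else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k_dmr": [self.k_dmr], "n_dmr": [self.n_dmr],
                "k_bg": [self.k_bg], "n_bg": [self.n_bg],
                "prop_dmr": [self.prop_dmr], "prop_bg": [self.prop_bg],
                "z_stat": [self.z_stat], "p_value": [self.p_value],
            }
        )


def upregulated_genes(
    expr: pd.DataFrame,
    sheet: Sequence[SampleInfo],
    age_from: float = 1.0,
    age_to: float = 15.0,
    min_fold: float = 1.5,
    alpha: float = 0.05,
    de_table: pd.DataFrame | None = None,
) -> set[str]:
    """Genes significantly upregulated between two ages.

    When ``de_table`` (columns ``gene_id log2fc p significant``) is given it
    takes precedence: genes flagged significant with positive log2fc.
    Otherwise a two-sample Welch t-test on log2(x+1) replicate values is
    applied together with a mean fold-change filter (mean at ``age_to`` at
    least ``min_fold`` times the mean at ``age_from``).
    """
    if de_table is not None:
        sig = de_table["significant"].astype(bool) & (de_table["log2fc"] > 0)
        return set(de_table.loc[sig, "gene_id"].astype(str))
    by_id = {s.sample_id: s for s in sheet}
    cols_from = [c for c in expr.columns if by_id[c].age_weeks == age_from]
    cols_to = [c for c in expr.columns if by_id[c].age_weeks == age_to]
    if not cols_from or not cols_to:
        raise ValueError(f"expression table lacks samples at age {age_from} or {age_to}")
    if len(cols_from) < 2 or len(cols_to) < 2:
        raise ValueError("internal DE test needs >=2 replicates per age group")
    a = np.log2(expr[cols_from].to_numpy(float) + 1.0)
    b = np.log2(expr[cols_to].to_numpy(float) + 1.0)
    p = stats.ttest_ind(b, a, axis=1, equal_var=False).pvalue
    mean_from = expr[cols_from].mean(axis=1).to_numpy(float)
    mean_to = expr[cols_to].mean(axis=1).to_numpy(float)
    up = (mean_to >= min_fold * mean_from) & (p < alpha)
    return set(expr.index[up].astype(str))


def random_segments(
    chrom_sizes: Mapping[str, int],
    n: int,
    length_bp,
    rng_seed: int | np.random.Generator = 0,
    exclude: Sequence[tuple[str, int, int]] | None = None,
    max_tries: int = 1000,
) -> list[tuple[str, int, int]]:
    """Uniform random genomic segments, chromosomes weighted by length.

    ``length_bp`` is a scalar or a per-segment array (length-matched
    sampling).  Segments overlapping ``exclude`` intervals are redrawn up to
    ``max_tries`` times each before an error is raised.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    lengths = np.broadcast_to(np.asarray(length_bp, dtype=np.int64), (n,))
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=np.float64)
    if (lengths > sizes.min()).any():
        raise ValueError("segment length exceeds a chromosome length")
    weights = sizes / sizes.sum()
    trees: dict[str, IntervalTree] = {}
    if exclude:
        for c, s, e in exclude:
            trees.setdefault(c, IntervalTree()).addi(s, e)
    out: list[tuple[str, int, int]] = []
    for L in lengths:
        L = int(L)
        for _ in range(max_tries):
            ci = int(rng.choice(len(chroms), p=weights))
            chrom = chroms[ci]
            start = int(rng.integers(0, chrom_sizes[chrom] - L + 1))
            if chrom in trees and trees[chrom].overlap(start, start + L):
                continue
            out.append((chrom, start, start + L))
            break
        else:
            raise ValueError("could not place a segment outside the excluded set")
    return out


def proportion_ztest(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pooled-variance two-proportion z-test (two-sided normal p)."""
    if n1 < 1 or n2 < 1:
        raise ValueError("both sample sizes must be >= 1")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        if p1 == p2:
            return 0.0, 1.0
        return (math.inf if p1 > p2 else -math.inf), 0.0
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (p1 - p2) / se
    return z, float(2.0 * stats.norm.sf(abs(z)))


def _hit_stats(
    intervals: Sequence[tuple[str, int, int]],
    index: GeneIndex,
    up_genes: set[str],
    mode: str,
    window_bp: int,
) -> tuple[int, int]:
    """(k, n): gene-assigned intervals hitting an upregulated gene / total
    gene-assigned intervals.  The same routine serves foreground and
    background so both follow the identical assignment path."""
    shims = [DmrCall(c, s, e, "segment", 0) for c, s, e in intervals]
    gene_sets = assign_genes(shims, index, mode=mode, window_bp=window_bp)
    assigned = [gs for gs in gene_sets if gs]
    k = sum(1 for gs in assigned if gs & up_genes)
    return k, len(assigned)


def dmr_gene_enrichment(
    dmrs: Sequence[DmrCall],
    genes,
    up_genes: set[str],
    chrom_sizes: Mapping[str, int],
    rng_seed: int = 0,
    mode: str = "intragenic_plus_promoter",
    window_bp: int = 50_000,
    bg_multiplier: int = 1,
    fixed_bg_length: int | None = None,
) -> AssociationResult:
    """Enrichment of DMRs in upregulated genes vs random segments.

    Foreground: the fraction of gene-assigned DMRs whose gene set intersects
    ``up_genes``.  Background: random segments, length-matched to the DMRs
    (or all ``fixed_bg_length`` bp), pushed through the identical assignment
    and intersection logic; ``bg_multiplier`` scales the number of segments
    drawn.  The two proportions are compared with the pooled z-test.
    """
    if not dmrs:
        raise ValueError("empty DMR set")
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    fg = [(d.chrom, d.start, d.end) for d in dmrs]
    k1, n1 = _hit_stats(fg, index, up_genes, mode, window_bp)
    if fixed_bg_length is not None:
        lengths = fixed_bg_length
    else:
        lengths = np.tile(
            np.array([d.end - d.start for d in dmrs], dtype=np.int64), bg_multiplier
        )
    bg = random_segments(
        chrom_sizes, len(dmrs) * bg_multiplier, lengths, rng_seed
    )
    k2, n2 = _hit_stats(bg, index, up_genes, mode, window_bp)
    if n1 == 0 or n2 == 0:
        raise ValueError("no gene-assigned intervals in foreground or background")
    z, p = proportion_ztest(k1, n1, k2, n2)
    return AssociationResult(k1, n1, k2, n2, z, p)
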