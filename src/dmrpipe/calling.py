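"""Tissue-specific and postnatal DMR calling.

The caller implements three rules in sequence:

1. *Tissue specificity*: a tile is a hypo (de novo) DMR for a target tissue
   when its mean methylation is at least ``delta_specific`` percentage
   points lower (higher) than in at least ``min_discriminating_tissues`` of
   the other tissues.  Differences are absolute percentage points by
   default; a relative-ratio mode is available.
2. *Postnatal timing*: a tissue-specific tile is postnatally demethylated
   when the newborn mean exceeds the adult mean by ``delta_postnatal``
   points with a per-tile test p below ``alpha_tile``.  It is *late* when
   demethylation has not yet happened at the boundary age (default 3 weeks),
   *early* otherwise, and *prenatal* when the newborn level is already below
   ``prenatal_max_newborn_pct``.  De novo tiles mirror all signs.
3. The per-tile test is Fisher's exact test on the replicate-pooled 2x2
   count table (methylated/unmethylated x newborn/adult); a replicate-level
   t-test on percent values is available as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .io import DmrCall
from .tiling import TileMatrix

__all__ = [
    "DmrParams",
    "CallResult",
    "tissue_means",
    "call_tissue_specific",
    "count_specific_calls",
    "tile_test",
    "call_postnatal",
]


@dataclass(frozen=True)
class DmrParams:
    """Thresholds of the DMR definitions (percent-methylation points)."""

    delta_specific: float = 50.0
    min_discriminating_tissues: int = 5
    n_comparison_tissues: int = 9  # panel size including the target
    delta_postnatal: float = 35.0
    alpha_tile: float = 0.05
    prenatal_max_newborn_pct: float = 5.0
    late_age_boundary_weeks: float = 3.0
    relative_delta: bool = False  # delta_specific as ratio of the higher level
    tile_test_method: Literal["fisher", "ttest"] = "fisher"
    fdr: bool = False  # Benjamini-Hochberg on per-tile p-values

    def __post_init__(self):
        if not 0 < self.delta_specific <= 100:
            raise ValueError("delta_specific must be in (0, 100]")
        if not 0 < self.delta_postnatal <= 100:
            raise ValueError("delta_postnatal must be in (0, 100]")
        if not 0 < self.alpha_tile < 1:
            raise ValueError("alpha_tile must be in (0, 1)")


@dataclass
class CallResult:
    """Tissue-specific calls plus the audit trail of untestable tiles."""

    calls: list[DmrCall]
    called_index: np.ndarray  # row indices into the matrix tiles
    untestable_index: np.ndarray  # tiles with data in <= half the panel
    n_discriminating: np.ndarray  # per called tile


def tissue_means(
    matrix: TileMatrix,
    age_filter: float | None = None,
    genotype_filter: str | None = None,
) -> pd.DataFrame:
    """Tiles x tissues table of replicate-mean percent methylation.

    Replicates of a tissue (restricted to ``age_filter``/``genotype_filter``
    when given) are averaged over non-missing cells; a (tile, tissue) cell
    with no data is NaN.
    """
    tissues = list(dict.fromkeys(s.tissue for s in matrix.samples))
    out = {}
    for t in tissues:
        cols = matrix.columns_for(tissue=t, age_weeks=age_filter, genotype=genotype_filter)
        if cols.size == 0:
            continue
        out[t] = _nanmean(matrix.pct[:, cols])
    return pd.DataFrame(out, index=np.arange(matrix.n_tiles))


def _nanmean(a: np.ndarray) -> np.ndarray:
    """Row-wise nanmean that is silent on all-NaN rows (returns NaN)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(a, axis=1)


def _specific_mask(
    means: np.ndarray,
    target: np.ndarray,
    direction: str,
    params: DmrParams,
):
    """Boolean call mask + per-tile discriminating-tissue counts.

    ``means``: tiles x comparison-tissues (NaN allowed); ``target``: tiles.
    Shared by the public caller and the permutation engine so both run the
    identical rule.
    """
    if direction not in ("hypo", "denovo"):
        raise ValueError(f"direction must be hypo or denovo, got {direction!r}")
    with np.errstate(invalid="ignore"):
        if params.relative_delta:
            frac = params.delta_specific / 100.0
            if direction == "hypo":
                hit = (means - target[:, None]) >= frac * means
            else:
                hit = (target[:, None] - means) >= frac * target[:, None]
        else:
            diff = means - target[:, None]
            if direction == "denovo":
                diff = -diff
            hit = diff >= params.delta_specific
    hit &= ~np.isnan(means)
    n_disc = hit.sum(axis=1)
    called = (n_disc >= params.min_discriminating_tissues) & ~np.isnan(target)
    return called, n_disc


def count_specific_calls(
    means: np.ndarray, target: np.ndarray, direction: str, params: DmrParams
) -> int:
    called, _ = _specific_mask(means, target, direction, params)
    return int(called.sum())


def call_tissue_specific(
    means: pd.DataFrame,
    target_tissue: str,
    direction: Literal["hypo", "denovo"],
    params: DmrParams,
    tiles: pd.DataFrame | None = None,
) -> CallResult:
    """Call tiles hypo- or de-novo-methylated specifically in one tissue.

    ``means`` is the tiles x tissues table from :func:`tissue_means`;
    ``tiles`` supplies intervals for the emitted :class:`DmrCall` records
    (synthetic ``tile_<row>`` intervals are used when omitted).  Tiles with
    data in no more than half of the comparison tissues are reported as
    untestable, separately from the negatives.
    """
    if target_tissue not in means.columns:
        raise ValueError(f"target tissue {target_tissue!r} not in means table")
    target = means[target_tissue].to_numpy(float)
    comparison = means.drop(columns=[target_tissue])
    comp = comparison.to_numpy(float)
    called, n_disc = _specific_mask(comp, target, direction, params)
    n_data = (~np.isnan(comp)).sum(axis=1)
    untestable = np.flatnonzero(np.isnan(target) | (n_data <= comp.shape[1] / 2))
    idx = np.flatnonzero(called)
    category = "tissue_hypo" if direction == "hypo" else "tissue_denovo"
    calls = []
    for i in idx:
        if tiles is not None:
            chrom, start, end = (
                str(tiles["chrom"].iat[i]),
                int(tiles["start"].iat[i]),
                int(tiles["end"].iat[i]),
            )
        else:
            chrom, start, end = f"tile_{i}", 0, 0
        calls.append(DmrCall(chrom, start, end, category, int(n_disc[i])))
    return CallResult(calls, idx, untestable, n_disc[idx])


def tile_test(
    newborn_counts: tuple[int, int],
    adult_counts: tuple[int, int],
) -> float:
    """Two-sided Fisher exact test on pooled (meth, total) pairs.

    The 2x2 table is methylated/unmethylated x newborn/adult.
    """
    (m1, t1), (m2, t2) = newborn_counts, adult_counts
    if t1 <= 0 or t2 <= 0:
        raise ValueError("tile_test requires positive total counts")
    if not (0 <= m1 <= t1 and 0 <= m2 <= t2):
        raise ValueError("methylated count outside [0, total]")
    table = [[m1, t1 - m1], [m2, t2 - m2]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def _age_stats(matrix: TileMatrix, rows: np.ndarray, cols: np.ndarray):
    """(replicate-mean pct, pooled meth, pooled total) for matrix rows."""
    mean_pct = _nanmean(matrix.pct[np.ix_(rows, cols)])
    meth = matrix.meth[np.ix_(rows, cols)].sum(axis=1)
    total = matrix.total[np.ix_(rows, cols)].sum(axis=1)
    return mean_pct, meth, total


def call_postnatal(
    matrix: TileMatrix,
    specific: CallResult,
    target_tissue: str,
    newborn_age: float = 1.0,
    adult_age: float = 15.0,
    params: DmrParams = DmrParams(),
    genotype_filter: str | None = None,
) -> list[DmrCall]:
    """Attach postnatal-timing labels to tissue-specific DMR calls.

    For hypo DMRs the timing is *prenatal* when the newborn level is already
    below ``prenatal_max_newborn_pct``; otherwise *early/late postnatal*
    when newborn - adult >= ``delta_postnatal`` with per-tile p <
    ``alpha_tile`` (late when the drop has not yet occurred at the boundary
    age, early otherwise, ``early_or_late_unknown`` when the boundary age is
    absent); *none* otherwise.  De novo DMRs mirror all signs (prenatal
    means already above 100 - ``prenatal_max_newborn_pct`` at 1 week).

    The delta rule is applied to replicate means; the significance test to
    replicate-pooled counts.
    """
    nb_cols = matrix.columns_for(tissue=target_tissue, age_weeks=newborn_age,
                                 genotype=genotype_filter)
    ad_cols = matrix.columns_for(tissue=target_tissue, age_weeks=adult_age,
                                 genotype=genotype_filter)
    if nb_cols.size == 0 or ad_cols.size == 0:
        raise ValueError(
            f"matrix lacks {target_tissue!r} samples at age "
            f"{newborn_age if nb_cols.size == 0 else adult_age}"
        )
    bd_cols = matrix.columns_for(tissue=target_tissue,
                                 age_weeks=params.late_age_boundary_weeks,
                                 genotype=genotype_filter)
    rows = specific.called_index
    nb_pct, nb_meth, nb_total = _age_stats(matrix, rows, nb_cols)
    ad_pct, ad_meth, ad_total = _age_stats(matrix, rows, ad_cols)
    if bd_cols.size:
        bd_pct, _, _ = _age_stats(matrix, rows, bd_cols)
    else:
        bd_pct = np.full(rows.size, np.nan)

    out: list[DmrCall] = []
    pvals = np.full(rows.size, np.nan)
    for k in range(rows.size):
        if nb_total[k] > 0 and ad_total[k] > 0:
            if params.tile_test_method == "ttest":
                a = matrix.pct[rows[k], nb_cols]
                b = matrix.pct[rows[k], ad_cols]
                a, b = a[~np.isnan(a)], b[~np.isnan(b)]
                if a.size >= 2 and b.size >= 2:
                    pvals[k] = stats.ttest_ind(a, b, equal_var=False).pvalue
            else:
                pvals[k] = tile_test(
                    (int(nb_meth[k]), int(nb_total[k])),
                    (int(ad_meth[k]), int(ad_total[k])),
                )
    if params.fdr:
        ok = ~np.isnan(pvals)
        if ok.any():
            pvals[ok] = _bh_adjust(pvals[ok])

    for k, call in enumerate(specific.calls):
        hypo = call.category == "tissue_hypo"
        delta = (nb_pct[k] - ad_pct[k]) if hypo else (ad_pct[k] - nb_pct[k])
        nb_level = nb_pct[k] if hypo else 100.0 - nb_pct[k]
        bd_delta = (nb_pct[k] - bd_pct[k]) if hypo else (bd_pct[k] - nb_pct[k])
        timing = "none"
        if not np.isnan(nb_level) and nb_level < params.prenatal_max_newborn_pct:
            timing = "prenatal"
        elif (
            not np.isnan(delta)
            and delta >= params.delta_postnatal
            and not np.isnan(pvals[k])
            and pvals[k] < params.alpha_tile
        ):
            if np.isnan(bd_pct[k]):
                timing = "early_or_late_unknown"
            elif bd_delta < params.delta_postnatal:
                timing = "late_postnatal"
            else:
                timing = "early_postnatal"
        out.append(
            call._replace(
                timing=timing,
                delta_newborn_adult=float(delta),
                p_tile=float(pvals[k]),
            )
        )
    return out


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(ranked, 1.0)
    return out
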