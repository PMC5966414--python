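"""Label-replacement permutation test for the size of a DMR set.

The null is built by replacing the target tissue's sample columns with the
same number of columns drawn at random (without replacement) from the other
tissues, removing the drawn columns from the comparison panel, and re-running
the identical tissue-specific caller.  The p-value is the add-one quantile of
the observed DMR count among the permuted counts,

    p = (1 + #{permuted >= observed}) / (n_perm + 1),

which never returns zero; when no permutation reaches the observed count the
result is the upper bound 1/(n_perm+1) and ``p_is_upper_bound`` is set.

The true target columns are excluded entirely from permuted datasets, so a
permuted dataset has the same shape as the original and never leaks target
signal into the null.  Re-evaluation is vectorised: per-tissue mean columns
are maintained as running sums/counts and only the drawn columns'
contributions change between permutations — no re-tiling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calling import DmrParams, _specific_mask
from .io import SampleInfo
from .tiling import TileMatrix

__all__ = ["PermutationResult", "permute_target", "permutation_test"]


@dataclass
class PermutationResult:
    observed_count: int
    permuted_counts: np.ndarray
    p_value: float
    p_is_upper_bound: bool
    seed: int
    n_perm: int

    def to_frame(self) -> pd.DataFrame:
        pc = self.permuted_counts
        return pd.DataFrame(
            {
                "observed_count": [self.observed_count],
                "n_perm": [self.n_perm],
                "max_permuted": [int(pc.max()) if pc.size else 0],
                "mean_permuted": [float(pc.mean()) if pc.size else 0.0],
                "p_value": [self.p_value],
                "p_is_upper_bound": [self.p_is_upper_bound],
                "seed": [self.seed],
            }
        )


def permute_target(
    sheet: list[SampleInfo],
    target_tissue: str,
    rng: np.random.Generator | int,
) -> list[SampleInfo]:
    """One permuted sample sheet: pseudo-target columns drawn from the pool.

    The k target-tissue samples are dropped and k non-target samples,
    drawn uniformly without replacement, are relabelled as target; drawn
    samples thereby leave the comparison panel.  All other labels are
    unchanged.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    target = [s for s in sheet if s.tissue == target_tissue]
    pool = [s for s in sheet if s.tissue != target_tissue]
    k = len(target)
    if len(pool) < k:
        raise ValueError(
            f"non-target pool ({len(pool)}) smaller than target set ({k})"
        )
    drawn = set(rng.choice(len(pool), size=k, replace=False).tolist())
    out = []
    for i, s in enumerate(pool):
        if i in drawn:
            out.append(s._replace(tissue=target_tissue))
        else:
            out.append(s)
    return out


def permutation_test(
    matrix: TileMatrix,
    target_tissue: str,
    dmr_params: DmrParams = DmrParams(),
    direction: str = "hypo",
    age_filter: float | None = 15.0,
    n_perm: int = 10_000,
    rng_seed: int = 0,
) -> PermutationResult:
    """Significance of the tissue-specific DMR count by label replacement.

    The observed count is the number of tissue-specific calls on the true
    labels (samples restricted to ``age_filter`` when given, matching how the
    caller is normally configured); each permutation reruns the identical
    rule on a permuted sheet.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(rng_seed)

    cols = (
        matrix.columns_for(age_weeks=age_filter)
        if age_filter is not None
        else np.arange(len(matrix.samples), dtype=np.intp)
    )
    samples = [matrix.samples[j] for j in cols]
    pct = matrix.pct[:, cols]
    tissues = [s.tissue for s in samples]
    target_cols = np.flatnonzero(np.asarray(tissues) == target_tissue)
    if target_cols.size == 0:
        raise ValueError(f"no {target_tissue!r} samples after age filter")
    pool_cols = np.flatnonzero(np.asarray(tissues) != target_tissue)
    k = target_cols.size
    if pool_cols.size < k:
        raise ValueError("non-target pool smaller than the target sample set")

    obs = np.isfinite(pct)
    vals = np.where(obs, pct, 0.0)

    # observed count on true labels
    comp_tissues = sorted({tissues[j] for j in pool_cols})
    t_index = {t: i for i, t in enumerate(comp_tissues)}
    T = pct.shape[0]
    base_sum = np.zeros((T, len(comp_tissues)))
    base_cnt = np.zeros((T, len(comp_tissues)))
    for j in pool_cols:
        i = t_index[tissues[j]]
        base_sum[:, i] += vals[:, j]
        base_cnt[:, i] += obs[:, j]
    with np.errstate(invalid="ignore", divide="ignore"):
        base_means = np.where(base_cnt > 0, base_sum / base_cnt, np.nan)
        tgt_cnt = obs[:, target_cols].sum(axis=1)
        tgt_mean = np.where(tgt_cnt > 0, vals[:, target_cols].sum(axis=1) / tgt_cnt, np.nan)
    called, _ = _specific_mask(base_means, tgt_mean, direction, dmr_params)
    observed = int(called.sum())

    pool_tissue_idx = np.array([t_index[tissues[j]] for j in pool_cols])
    pool_vals = vals[:, pool_cols]
    pool_obs = obs[:, pool_cols].astype(float)

    permuted = np.empty(n_perm, dtype=np.int64)
    for p in range(n_perm):
        draw = rng.choice(pool_cols.size, size=k, replace=False)
        ps = pool_vals[:, draw].sum(axis=1)
        pc = pool_obs[:, draw].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            pseudo = np.where(pc > 0, ps / pc, np.nan)
        # only the drawn columns' tissues change; adjust those columns in a
        # copy of the precomputed per-tissue means
        means = base_means.copy()
        for i in np.unique(pool_tissue_idx[draw]):
            dcols = draw[pool_tissue_idx[draw] == i]
            s = base_sum[:, i] - pool_vals[:, dcols].sum(axis=1)
            c = base_cnt[:, i] - pool_obs[:, dcols].sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                means[:, i] = np.where(c > 0, s / c, np.nan)
        c, _ = _specific_mask(means, pseudo, direction, dmr_params)
        permuted[p] = int(c.sum())

    n_ge = int((permuted >= observed).sum())
    p_value = (1 + n_ge) / (n_perm + 1)
    return PermutationResult(
        observed_count=observed,
        permuted_counts=permuted,
        p_value=float(p_value),
        p_is_upper_bound=(n_ge == 0),
        seed=int(rng_seed),
        n_perm=int(n_perm),
    )
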