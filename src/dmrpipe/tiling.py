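"""Fixed-width tile aggregation of CpG calls and the cross-sample matrix.

A *tile* is a genome-anchored window of ``tile_size`` bp (starts are
multiples of ``tile_size``).  CpG read counts are pooled within a tile and
percent methylation is the pooled ratio ``100 * meth / total`` — the
read-weighted mean, not the mean of per-CpG ratios — so that downstream
count-based tests see the same primitive data.

The minimum-coverage filter has two interpretations, both provided:

* pooled mode (default): a tile is emitted when the pooled number of CpG
  read observations (sum of ``total_reads``) reaches ``min_cpg_obs``;
* strict-sites mode: a tile is emitted when it contains at least
  ``min_cpg_obs`` distinct CpG sites each covered by >=1 read.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .io import CPG_COLUMNS, SampleInfo, calls_to_frame

__all__ = [
    "TilingParams",
    "TileMethylation",
    "TileMatrix",
    "merge_strands",
    "aggregate_tiles",
    "aggregate_tiles_frame",
    "build_matrix",
]

TILE_COLUMNS = ["chrom", "start", "end", "n_cpg_sites", "meth_reads", "total_reads", "pct_meth"]


@dataclass(frozen=True)
class TilingParams:
    """Tile width and coverage filter.

    Defaults are the RRBS settings (100 bp tiles, >=10 pooled CpG read
    observations); WGBS-style analyses use 200 bp and 15.
    """

    tile_size: int = 100
    min_cpg_obs: int = 10
    strict_sites: bool = False

    def __post_init__(self):
        if self.tile_size <= 0:
            raise ValueError("tile_size must be positive")
        if self.min_cpg_obs < 1:
            raise ValueError("min_cpg_obs must be >= 1")

    @classmethod
    def rrbs(cls) -> "TilingParams":
        return cls(tile_size=100, min_cpg_obs=10)

    @classmethod
    def wgbs(cls) -> "TilingParams":
        return cls(tile_size=200, min_cpg_obs=15)


class TileMethylation(NamedTuple):
    chrom: str
    start: int
    end: int
    n_cpg_sites: int
    meth_reads: int
    total_reads: int
    pct_meth: float


def _as_frame(calls) -> pd.DataFrame:
    if isinstance(calls, pd.DataFrame):
        return calls
    return calls_to_frame(calls)


def merge_strands(calls) -> pd.DataFrame:
    """Pool symmetric CpG observations onto the + strand position.

    A ``-`` strand call at position p belongs to the CpG whose C on the +
    strand sits at p-1; counts of the two strands are added.  Lone calls on
    either strand are kept (minus-strand ones shifted to the + position).
    """
    frame = _as_frame(calls)
    if frame.empty:
        return pd.DataFrame(columns=CPG_COLUMNS)
    pos = frame["pos"].to_numpy(np.int64).copy()
    minus = frame["strand"].to_numpy() == "-"
    pos[minus] -= 1
    merged = (
        pd.DataFrame(
            {
                "chrom": frame["chrom"].to_numpy(),
                "pos": pos,
                "meth_reads": frame["meth_reads"].to_numpy(np.int64),
                "total_reads": frame["total_reads"].to_numpy(np.int64),
            }
        )
        .groupby(["chrom", "pos"], sort=True, as_index=False)
        .sum()
    )
    merged.insert(2, "strand", "+")
    return merged[CPG_COLUMNS]


def aggregate_tiles_frame(
    calls, params: TilingParams, keep_suppressed: bool = False
) -> pd.DataFrame:
    """Pool strand-merged CpG calls into tiles (vectorised, frame in/out).

    Returns a DataFrame with :data:`TILE_COLUMNS`; tiles failing the
    coverage filter are dropped unless ``keep_suppressed``, in which case a
    boolean ``suppressed`` column is added.
    """
    frame = _as_frame(calls)
    if frame.empty:
        cols = TILE_COLUMNS + (["suppressed"] if keep_suppressed else [])
        return pd.DataFrame(columns=cols)
    tile_start = (frame["pos"].to_numpy(np.int64) // params.tile_size) * params.tile_size
    g = (
        pd.DataFrame(
            {
                "chrom": frame["chrom"].to_numpy(),
                "start": tile_start,
                "pos": frame["pos"].to_numpy(np.int64),
                "meth_reads": frame["meth_reads"].to_numpy(np.int64),
                "total_reads": frame["total_reads"].to_numpy(np.int64),
            }
        )
        .groupby(["chrom", "start"], sort=True)
        .agg(
            n_cpg_sites=("pos", "nunique"),
            meth_reads=("meth_reads", "sum"),
            total_reads=("total_reads", "sum"),
        )
        .reset_index()
    )
    g["end"] = g["start"] + params.tile_size
    g["pct_meth"] = 100.0 * g["meth_reads"] / g["total_reads"]
    if params.strict_sites:
        ok = g["n_cpg_sites"] >= params.min_cpg_obs
    else:
        ok = g["total_reads"] >= params.min_cpg_obs
    if keep_suppressed:
        g["suppressed"] = ~ok
        return g[TILE_COLUMNS + ["suppressed"]]
    return g.loc[ok, TILE_COLUMNS].reset_index(drop=True)


def aggregate_tiles(calls, params: TilingParams) -> list[TileMethylation]:
    """Row-object variant of :func:`aggregate_tiles_frame`."""
    g = aggregate_tiles_frame(calls, params)
    return [
        TileMethylation(str(r.chrom), int(r.start), int(r.end), int(r.n_cpg_sites),
                        int(r.meth_reads), int(r.total_reads), float(r.pct_meth))
        for r in g.itertuples(index=False)
    ]


@dataclass
class TileMatrix:
    """Tiles x samples percent-methylation matrix with pooled counts.

    ``pct`` holds NaN where a tile failed the coverage filter in a sample;
    ``meth``/``total`` are zero there.  Column order follows the sample
    sheet.
    """

    tiles: pd.DataFrame  # columns chrom, start, end
    samples: list[SampleInfo]
    pct: np.ndarray  # (T, S) float, NaN = missing
    meth: np.ndarray  # (T, S) int64
    total: np.ndarray  # (T, S) int64

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def mask(self) -> np.ndarray:
        """True where a cell is observed."""
        return ~np.isnan(self.pct)

    @property
    def n_tiles(self) -> int:
        return len(self.tiles)

    def tile_labels(self) -> pd.Index:
        t = self.tiles
        return pd.Index(
            t["chrom"].astype(str) + ":" + t["start"].astype(str) + "-" + t["end"].astype(str)
        )

    def columns_for(
        self,
        tissue: str | None = None,
        age_weeks: float | None = None,
        genotype: str | None = None,
    ) -> np.ndarray:
        """Indices of sample columns matching the given design filters."""
        idx = [
            j
            for j, s in enumerate(self.samples)
            if (tissue is None or s.tissue == tissue)
            and (age_weeks is None or s.age_weeks == age_weeks)
            and (genotype is None or s.genotype == genotype)
        ]
        return np.asarray(idx, dtype=np.intp)

    def to_tsv(self, pct_path, counts_path=None) -> None:
        labels = self.tile_labels()
        pd.DataFrame(self.pct, index=labels, columns=self.sample_ids).to_csv(
            pct_path, sep="\t", index_label="tile", na_rep="NA", float_format="%.6g"
        )
        if counts_path is not None:
            txt = np.char.add(
                np.char.add(self.meth.astype(str), "|"), self.total.astype(str)
            )
            pd.DataFrame(txt, index=labels, columns=self.sample_ids).to_csv(
                counts_path, sep="\t", index_label="tile"
            )

    @classmethod
    def from_tsv(cls, pct_path, counts_path, sheet: Sequence[SampleInfo]) -> "TileMatrix":
        pct_df = pd.read_csv(pct_path, sep="\t", index_col=0, na_values="NA")
        cnt_df = pd.read_csv(counts_path, sep="\t", index_col=0, dtype=str)
        order = [s.sample_id for s in sheet]
        pct_df = pct_df[order]
        cnt_df = cnt_df[order]
        parts = pct_df.index.str.extract(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")
        tiles = pd.DataFrame(
            {
                "chrom": parts["chrom"].to_numpy(),
                "start": parts["start"].astype(np.int64).to_numpy(),
                "end": parts["end"].astype(np.int64).to_numpy(),
            }
        )
        split = cnt_df.apply(lambda col: col.str.split("|", expand=False))
        meth = np.array(
            [[int(v[0]) for v in row] for row in split.to_numpy()], dtype=np.int64
        )
        total = np.array(
            [[int(v[1]) for v in row] for row in split.to_numpy()], dtype=np.int64
        )
        return cls(tiles, list(sheet), pct_df.to_numpy(float), meth, total)


def build_matrix(
    per_sample_tiles: Mapping[str, pd.DataFrame | Sequence[TileMethylation]],
    sheet: Sequence[SampleInfo],
) -> TileMatrix:
    """Assemble per-sample tile sets into a tiles x samples matrix.

    The tile universe is the union of tiles emitted in any sample; cells
    absent in a sample (tile suppressed or never covered there) are masked
    missing.  Every sample in the sheet must have a tile set.
    """
    missing = [s.sample_id for s in sheet if s.sample_id not in per_sample_tiles]
    if missing:
        raise ValueError(f"sheet samples without tile data: {missing}")
    frames = {}
    for s in sheet:
        t = per_sample_tiles[s.sample_id]
        frames[s.sample_id] = t if isinstance(t, pd.DataFrame) else pd.DataFrame(
            t, columns=TILE_COLUMNS
        )
    keys = sorted(
        set().union(
            *(
                zip(f["chrom"], f["start"], f["end"])
                for f in frames.values()
                if not f.empty
            )
        )
    )
    tiles = pd.DataFrame(keys, columns=["chrom", "start", "end"])
    index = {k: i for i, k in enumerate(keys)}
    T, S = len(keys), len(sheet)
    pct = np.full((T, S), np.nan)
    meth = np.zeros((T, S), dtype=np.int64)
    total = np.zeros((T, S), dtype=np.int64)
    for j, s in enumerate(sheet):
        f = frames[s.sample_id]
        if f.empty:
            continue
        rows = np.fromiter(
            (index[k] for k in zip(f["chrom"], f["start"], f["end"])),
            dtype=np.intp,
            count=len(f),
        )
        pct[rows, j] = f["pct_meth"].to_numpy(float)
        meth[rows, j] = f["meth_reads"].to_numpy(np.int64)
        total[rows, j] = f["total_reads"].to_numpy(np.int64)
    return TileMatrix(tiles, list(sheet), pct, meth, total)
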