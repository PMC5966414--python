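"""Synthetic multi-tissue bisulfite datasets with known ground truth.

The generator emulates the statistical structure the DMR analysis assumes:
nine tissues sampled at 1, 3, and 15 weeks with a few replicates each;
RRBS-like sparse CpG coverage (5-15 CpGs per covered tile, tile-level
dropout); beta-binomial read counts around per-tile true methylation means;
and planted tiles following four trajectory classes in the target tissue:

* ``prenatal`` — already unmethylated (<5%) at 1 week, at all ages;
* ``early``    — methylated at 1 week, demethylated from 3 weeks on;
* ``late``     — methylated at 1 and 3 weeks, demethylated by 15 weeks;
* ``denovo``   — unmethylated everywhere, gaining methylation with age in
  the target tissue only.

Non-target tissues hold the background level on hypo tiles (and the low
level on de novo tiles) at every age.  ``dko_mode`` freezes the target
tissue at its 1-week state at all ages (no postnatal transition at all);
``insr_mode`` freezes only the late-class tiles.  A linked expression table
upregulates a configurable fraction of the genes that contain postnatal DMR
tiles, from the tile's demethylation onset age onward.

All distributions and effect sizes here are generator choices exposed on
:class:`SimConfig`; real RRBS data have correlated coverage, CpG-density
structure, and batch effects that this model does not attempt.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from .io import GeneModel, SampleInfo, write_bismark_cov, write_sample_sheet

__all__ = ["SimConfig", "TruthTable", "SimResult", "simulate_methylomes", "simulate_expression"]

DEFAULT_TISSUES = (
    "liver", "lung", "heart", "brain", "fat",
    "neutrophils", "hippocampus", "kidney", "spleen",
)

TILE_CLASSES = ("background", "island", "prenatal", "early", "late", "denovo")


@dataclass(frozen=True)
class SimConfig:
    """Study design and generative parameters of the synthetic dataset."""

    # design
    n_tissues: int = 9
    target_tissue: str = "liver"
    ages_weeks: tuple[float, ...] = (1.0, 3.0, 15.0)
    n_replicates: int = 3
    # genome / tiling
    n_tiles: int = 20_000
    tile_size: int = 100
    tile_spacing: int = 1_000  # distance between consecutive covered tiles
    n_chroms: int = 2
    cpg_per_tile: tuple[int, int] = (5, 15)
    # coverage
    mean_depth: float = 30.0
    dropout: float = 0.1  # per (tile, sample) probability of no coverage
    # planted truth
    n_prenatal: int = 100
    n_early: int = 40
    n_late: int = 60
    n_denovo: int = 50
    effect_delta: float = 60.0  # percentage points
    bg_mean: float = 0.85
    island_fraction: float = 0.1
    island_mean: float = 0.05
    prenatal_level: float = 0.03
    # per-CpG beta-binomial dispersion; modest, so pooled tile estimates sit
    # within binomial sampling error of the planted means
    beta_concentration: float = 100.0
    tile_mean_concentration: float = 200.0  # per-tile baseline jitter
    # gene layout / expression
    gene_stride_tiles: int = 10
    gene_span_tiles: int = 5
    linked_fraction: float = 0.6  # planted tiles placed inside gene bodies
    upregulated_fraction: float = 0.7  # linked postnatal genes induced
    fold_change: float = 3.0
    expr_baseline_log_mean: float = 3.5  # natural log of baseline FPKM-like
    expr_baseline_log_sd: float = 1.0
    expr_noise_log_sd: float = 0.1
    dko_attenuation: float = 0.5  # induced fold shrinks toward 1 by this factor
    # perturbation modes
    dko_mode: bool = False  # freeze every postnatal transition at the 1-week state
    insr_mode: bool = False  # freeze only late-class transitions
    seed: int = 0

    def __post_init__(self):
        n_planted = self.n_prenatal + self.n_early + self.n_late + self.n_denovo
        if n_planted > self.n_tiles:
            raise ValueError("planted tile counts exceed n_tiles")
        if not 0 < self.effect_delta <= 100:
            raise ValueError("effect_delta must be in (0, 100]")
        if self.n_tissues < 2:
            raise ValueError("need at least two tissues")
        if self.n_tissues > len(DEFAULT_TISSUES):
            raise ValueError(f"at most {len(DEFAULT_TISSUES)} tissue names available")

    @property
    def tissues(self) -> tuple[str, ...]:
        names = [self.target_tissue] + [
            t for t in DEFAULT_TISSUES if t != self.target_tissue
        ]
        return tuple(names[: self.n_tissues])

    @classmethod
    def preset(cls, name: str, seed: int = 0) -> "SimConfig":
        """Named configurations: rrbs (default), wgbs, null, dko, insr."""
        if name == "rrbs":
            return cls(seed=seed)
        if name == "wgbs":
            return cls(tile_size=200, seed=seed)
        if name == "null":
            return cls(n_prenatal=0, n_early=0, n_late=0, n_denovo=0, seed=seed)
        if name == "dko":
            return cls(dko_mode=True, seed=seed)
        if name == "insr":
            return cls(insr_mode=True, seed=seed)
        raise ValueError(f"unknown preset {name!r}")


@dataclass
class TruthTable:
    """Planted ground truth: per-tile class and per-gene expression effect."""

    tiles: pd.DataFrame  # tile_id, chrom, start, end, cls
    target_means: pd.DataFrame  # tile_id x age columns: true target-tissue mean (%)
    genes: pd.DataFrame  # gene_id, linked_tiles, fold_change, onset_age

    def tiles_of_class(self, cls: str) -> pd.DataFrame:
        return self.tiles[self.tiles["cls"] == cls]

    def write(self, path) -> None:
        merged = self.tiles.merge(self.target_means, on="tile_id")
        merged.to_csv(path, sep="\t", index=False)


@dataclass
class SimResult:
    config: SimConfig
    sheet: list[SampleInfo]
    calls: dict[str, pd.DataFrame]  # sample_id -> CpG call frame
    truth: TruthTable
    genes: list[GeneModel]
    chrom_sizes: dict[str, int]

    def write(self, out_dir) -> None:
        """Write sample sheet, Bismark coverage files, BED12, truth TSV."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        sheet = []
        for s in self.sheet:
            p = out / f"{s.sample_id}.cov"
            write_bismark_cov(self.calls[s.sample_id], p)
            sheet.append(s._replace(path=str(p)))
        write_sample_sheet(sheet, out / "samples.tsv")
        with open(out / "genes.bed", "w") as fh:
            for g in self.genes:
                n_bl = 1
                fh.write(
                    f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                    f"{g.start}\t{g.end}\t0\t{n_bl}\t{g.end - g.start},\t0,\n"
                )
        self.truth.write(out / "truth.tsv")


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------


def _tile_layout(config: SimConfig):
    """Genome coordinates of the covered-tile slots and the gene grid."""
    per_chrom = int(np.ceil(config.n_tiles / config.n_chroms))
    chrom = np.array(
        [f"chr{i // per_chrom + 1}" for i in range(config.n_tiles)], dtype=object
    )
    within = np.arange(config.n_tiles) % per_chrom
    start = within * config.tile_spacing
    chrom_sizes = {
        f"chr{c + 1}": per_chrom * config.tile_spacing + 10 * config.tile_spacing
        for c in range(config.n_chroms)
    }
    return chrom, start.astype(np.int64), chrom_sizes, per_chrom


def _gene_grid(config: SimConfig, chrom, start, per_chrom) -> list[GeneModel]:
    """One gene per ``gene_stride_tiles`` block, spanning slots 2..6 of it."""
    genes = []
    stride, span = config.gene_stride_tiles, config.gene_span_tiles
    gid = 0
    for slot0 in range(0, config.n_tiles - stride + 1, stride):
        # skip blocks straddling a chromosome boundary
        if slot0 // per_chrom != (slot0 + stride - 1) // per_chrom:
            continue
        body_first, body_last = slot0 + 2, slot0 + 2 + span - 1
        g_start = int(start[body_first])
        g_end = int(start[body_last]) + config.tile_size
        strand = "+" if gid % 2 == 0 else "-"
        tss, tes = (g_start, g_end) if strand == "+" else (g_end, g_start)
        genes.append(
            GeneModel(f"gene_{gid:05d}", str(chrom[body_first]), strand,
                      tss, tes, g_start, g_end)
        )
        gid += 1
    return genes


def _plant_classes(config: SimConfig, rng: np.random.Generator, per_chrom: int):
    """Assign a trajectory class to every tile slot.

    Planted DMR tiles go partly into gene-body slots (block offsets 2..6)
    and partly into intergenic slots (offsets 8..9, clear of promoters and
    the 1 kb TES extension on either strand).
    """
    stride = config.gene_stride_tiles
    idx = np.arange(config.n_tiles)
    offs = idx % stride
    blk = idx - offs
    # block fully on one chromosome -> a gene exists for it
    in_block = (blk // per_chrom) == ((blk + stride - 1) // per_chrom)
    genic = np.flatnonzero((offs >= 3) & (offs <= 5) & in_block)
    intergenic = np.flatnonzero((offs == 8) | (offs == 9))
    cls = np.full(config.n_tiles, "background", dtype=object)
    genic = rng.permutation(genic)
    intergenic = rng.permutation(intergenic)
    gi, ii = 0, 0
    for name, count in (
        ("prenatal", config.n_prenatal),
        ("early", config.n_early),
        ("late", config.n_late),
        ("denovo", config.n_denovo),
    ):
        n_genic = int(round(count * config.linked_fraction))
        take_g, gi = genic[gi : gi + n_genic], gi + n_genic
        take_i, ii = intergenic[ii : ii + count - n_genic], ii + count - n_genic
        if take_g.size + take_i.size < count:
            raise ValueError("not enough free tile slots to plant all classes")
        cls[take_g] = name
        cls[take_i] = name
    free = np.flatnonzero(cls == "background")
    n_island = int(round(config.island_fraction * config.n_tiles))
    cls[rng.choice(free, size=min(n_island, free.size), replace=False)] = "island"
    return cls


# ---------------------------------------------------------------------------
# true means
# ---------------------------------------------------------------------------


def _true_means(
    config: SimConfig, cls: np.ndarray, baseline: np.ndarray,
    tissue: str, age: float,
) -> np.ndarray:
    """Per-tile true methylation fraction for one (tissue, age) condition."""
    high = baseline  # per-tile jittered background level, shared across tissues
    low = np.clip(baseline - config.effect_delta / 100.0, 0.02, 1.0)
    denovo_base = low
    mu = high.copy()
    mu[cls == "island"] = config.island_mean
    target = tissue == config.target_tissue

    def stage(a: float) -> float:
        # effective age seen by the target tissue under perturbation modes
        return config.ages_weeks[0] if config.dko_mode else a

    if not target:
        mu[cls == "prenatal"] = high[cls == "prenatal"]
        mu[cls == "early"] = high[cls == "early"]
        mu[cls == "late"] = high[cls == "late"]
        mu[cls == "denovo"] = denovo_base[cls == "denovo"]
        return mu

    age_eff = stage(age)
    mu[cls == "prenatal"] = config.prenatal_level
    m = cls == "early"
    mu[m] = np.where(age_eff < 3.0, high[m], low[m])
    m = cls == "late"
    late_age = config.ages_weeks[0] if (config.dko_mode or config.insr_mode) else age
    mu[m] = np.where(late_age < 15.0, high[m], low[m])
    m = cls == "denovo"
    mu[m] = np.where(age_eff < 3.0, denovo_base[m], high[m])
    return mu


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def simulate_methylomes(config: SimConfig) -> SimResult:
    """Generate per-sample CpG calls plus the ground-truth table.

    Per CpG site the methylation probability is Beta-distributed around the
    tile's true mean for that (tissue, age); read depth is 1 + Poisson;
    methylated reads are Binomial(depth, p).  Fixed seed gives identical
    output.
    """
    rng = np.random.default_rng(config.seed)
    chrom, start, chrom_sizes, per_chrom = _tile_layout(config)
    cls = _plant_classes(config, rng, per_chrom)
    genes = _gene_grid(config, chrom, start, per_chrom)

    # per-tile baseline with mild jitter, shared across tissues (exchangeable
    # under the null)
    c0 = config.tile_mean_concentration
    baseline = rng.beta(config.bg_mean * c0, (1 - config.bg_mean) * c0,
                        size=config.n_tiles)

    # CpG catalog: positions fixed across samples (RRBS fragments are shared)
    lo, hi = config.cpg_per_tile
    n_cpg = rng.integers(lo, hi + 1, size=config.n_tiles)
    offsets = []
    half = config.tile_size // 2
    for n in n_cpg:
        offsets.append(np.sort(rng.choice(half, size=n, replace=False)) * 2)
    cpg_tile = np.repeat(np.arange(config.n_tiles), n_cpg)
    cpg_pos = start[cpg_tile] + np.concatenate(offsets)
    cpg_chrom = chrom[cpg_tile]

    genotype = "DKO" if config.dko_mode else ("InsR-KO" if config.insr_mode else "WT")
    sheet: list[SampleInfo] = []
    calls: dict[str, pd.DataFrame] = {}
    conc = config.beta_concentration
    for tissue in config.tissues:
        for age in config.ages_weeks:
            mu_tile = np.clip(
                _true_means(config, cls, baseline, tissue, age), 0.01, 0.99
            )
            mu_cpg = mu_tile[cpg_tile]
            for r in range(config.n_replicates):
                sid = f"{tissue}_{age:g}wk_r{r + 1}"
                gt = genotype if tissue == config.target_tissue else "WT"
                sheet.append(SampleInfo(sid, tissue, float(age), gt, f"r{r + 1}"))
                keep_tile = rng.random(config.n_tiles) >= config.dropout
                keep = keep_tile[cpg_tile]
                p = rng.beta(conc * mu_cpg[keep], conc * (1 - mu_cpg[keep]))
                depth = 1 + rng.poisson(config.mean_depth - 1, size=p.size)
                meth = rng.binomial(depth, p)
                calls[sid] = pd.DataFrame(
                    {
                        "chrom": cpg_chrom[keep],
                        "pos": cpg_pos[keep],
                        "strand": "+",
                        "meth_reads": meth.astype(np.int64),
                        "total_reads": depth.astype(np.int64),
                    }
                )

    tiles = pd.DataFrame(
        {
            "tile_id": np.arange(config.n_tiles),
            "chrom": chrom,
            "start": start,
            "end": start + config.tile_size,
            "cls": cls,
        }
    )
    tmeans = {"tile_id": np.arange(config.n_tiles)}
    for age in config.ages_weeks:
        tmeans[f"target_mean_pct_{age:g}wk"] = 100.0 * np.clip(
            _true_means(config, cls, baseline, config.target_tissue, age), 0.01, 0.99
        )
    truth_genes = _link_genes(config, rng, tiles, genes)
    truth = TruthTable(tiles, pd.DataFrame(tmeans), truth_genes)
    return SimResult(config, sheet, calls, truth, genes, chrom_sizes)


def _link_genes(
    config: SimConfig, rng: np.random.Generator,
    tiles: pd.DataFrame, genes: list[GeneModel],
) -> pd.DataFrame:
    """Per-gene truth: linked planted tiles, induced fold change, onset age."""
    rows = []
    planted = tiles[tiles["cls"].isin(["prenatal", "early", "late", "denovo"])]
    by_chrom: dict[str, pd.DataFrame] = dict(tuple(planted.groupby("chrom")))
    for g in genes:
        sub = by_chrom.get(g.chrom)
        linked: list[int] = []
        onset = np.nan
        if sub is not None:
            inside = sub[(sub["start"] >= g.start) & (sub["end"] <= g.end)]
            linked = inside["tile_id"].tolist()
            classes = set(inside["cls"])
            if "early" in classes:
                onset = 3.0
            elif "late" in classes:
                onset = 15.0
        fold = 1.0
        if not np.isnan(onset) and rng.random() < config.upregulated_fraction:
            fold = config.fold_change
        rows.append(
            {
                "gene_id": g.gene_id,
                "linked_tiles": ",".join(map(str, linked)),
                "fold_change": fold,
                "onset_age": onset,
            }
        )
    return pd.DataFrame(rows)


def simulate_expression(
    truth: TruthTable, config: SimConfig, rng_seed: int | None = None
) -> tuple[pd.DataFrame, list[SampleInfo]]:
    """Expression table (genes x target-tissue samples) linked to the truth.

    Baseline expression is log-normal; genes flagged in the truth table are
    multiplied by their fold change from the onset age onward.  In
    ``dko_mode`` the induced fold is attenuated toward 1 by
    ``dko_attenuation``, emulating the loss of demethylation-driven
    induction.
    """
    rng = np.random.default_rng(config.seed + 1 if rng_seed is None else rng_seed)
    genes = truth.genes
    n = len(genes)
    baseline = rng.lognormal(config.expr_baseline_log_mean,
                             config.expr_baseline_log_sd, size=n)
    fold = genes["fold_change"].to_numpy(float)
    onset = genes["onset_age"].to_numpy(float)
    if config.dko_mode:
        fold = 1.0 + (fold - 1.0) * config.dko_attenuation
    genotype = "DKO" if config.dko_mode else ("InsR-KO" if config.insr_mode else "WT")
    cols, data = [], []
    sheet: list[SampleInfo] = []
    for age in config.ages_weeks:
        induced = np.where(~np.isnan(onset) & (age >= onset), fold, 1.0)
        for r in range(config.n_replicates):
            sid = f"expr_{config.target_tissue}_{age:g}wk_r{r + 1}"
            sheet.append(
                SampleInfo(sid, config.target_tissue, float(age), genotype, f"r{r + 1}")
            )
            noise = rng.lognormal(0.0, config.expr_noise_log_sd, size=n)
            cols.append(sid)
            data.append(baseline * induced * noise)
    expr = pd.DataFrame(
        np.column_stack(data), index=genes["gene_id"].astype(str), columns=cols
    )
    expr.index.name = "gene_id"
    return expr, sheet
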