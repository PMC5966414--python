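"""Readers and writers for the file dialects the pipeline touches.

All internal coordinates are 0-based half-open (BED convention).  The two
bisulfite input dialects (Bismark coverage, BSMAP-methratio) are 1-based and
are converted on read, so a given cytosine has the same ``pos`` regardless of
the dialect it arrived in.

Bulk data travel as :class:`pandas.DataFrame` objects with the column layout
of :data:`CPG_COLUMNS`; the row-level named tuples (:class:`CpGCall`,
:class:`SampleInfo`, :class:`GeneModel`, :class:`DmrCall`) are the validated
scalar contract used at API edges and in tests.
"""

from __future__ import annotations

import logging
import math
import re
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("dmrpipe")

CPG_COLUMNS = ["chrom", "pos", "strand", "meth_reads", "total_reads"]

__all__ = [
    "CpGCall",
    "SampleInfo",
    "GeneModel",
    "DmrCall",
    "MethylationParseError",
    "read_cpg_calls",
    "read_cpg_frame",
    "calls_to_frame",
    "frame_to_calls",
    "read_gene_models",
    "read_sample_sheet",
    "write_sample_sheet",
    "write_dmr_bed",
    "read_dmr_bed",
    "write_bismark_cov",
    "read_expression_table",
    "write_expression_table",
]


class MethylationParseError(ValueError):
    """Raised when an input file violates its dialect; names the line."""


class CpGCall(NamedTuple):
    """One strand-resolved cytosine observation."""

    chrom: str
    pos: int  # 0-based position of the C
    strand: str  # '+' or '-'
    meth_reads: int
    total_reads: int

    def validate(self) -> "CpGCall":
        if self.pos < 0:
            raise ValueError(f"negative position {self.pos}")
        if self.total_reads <= 0:
            raise ValueError(f"non-positive total_reads {self.total_reads}")
        if not 0 <= self.meth_reads <= self.total_reads:
            raise ValueError(
                f"meth_reads {self.meth_reads} outside [0, {self.total_reads}]"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        return self


class SampleInfo(NamedTuple):
    """One sample column of the design: tissue, age, genotype, replicate."""

    sample_id: str
    tissue: str
    age_weeks: float
    genotype: str = "WT"  # WT, DKO, InsR-KO, other
    replicate: str = "r1"
    path: str | None = None


class GeneModel(NamedTuple):
    """Gene span with strand-aware TSS/TES.

    ``tss``/``tes`` are 0-based coordinates; for a ``-`` strand gene the TSS
    is the higher genomic coordinate.  ``start``/``end`` are the half-open
    gene extent.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    start: int
    end: int


class DmrCall(NamedTuple):
    """A tile flagged as tissue-specific, with postnatal timing."""

    chrom: str
    start: int
    end: int
    category: str  # tissue_hypo | tissue_denovo
    n_discriminating: int
    timing: str = "none"  # prenatal | early_postnatal | late_postnatal |
    #                        early_or_late_unknown | none
    delta_newborn_adult: float = float("nan")
    p_tile: float = float("nan")


# ---------------------------------------------------------------------------
# CpG call input
# ---------------------------------------------------------------------------


def _fail_rows(frame: pd.DataFrame, bad: pd.Series, path, why: str) -> None:
    if bad.any():
        lines = ", ".join(str(i) for i in frame.index[bad][:5] + 1)
        raise MethylationParseError(f"{path}: {why} at line(s) {lines}")


def read_cpg_frame(path, dialect: str = "bismark_cov") -> pd.DataFrame:
    """Read per-cytosine methylation calls into a DataFrame.

    Parameters
    ----------
    path
        TSV file in one of the supported dialects.
    dialect
        ``bismark_cov`` — ``chrom start(1-based) end %meth n_meth n_unmeth``;
        ``methratio`` — headered BSMAP-methratio output, of which only
        ``chr pos strand context C_count CT_count`` are consumed.  When a
        ``context`` column is present only CpG-context rows are kept.

    Returns
    -------
    DataFrame with columns ``chrom pos strand meth_reads total_reads``,
    positions 0-based, sorted by (chrom, pos).  Rows with zero total reads
    are dropped with a logged warning.
    """
    path = Path(path)
    if dialect == "bismark_cov":
        try:
            df = pd.read_csv(
                path,
                sep="\t",
                header=None,
                comment="#",
                names=["chrom", "start", "end", "pct", "n_meth", "n_unmeth"],
                dtype={"chrom": str},
            )
        except (ValueError, pd.errors.ParserError) as exc:
            raise MethylationParseError(f"{path}: {exc}") from exc
        if df.empty:
            return pd.DataFrame(columns=CPG_COLUMNS)
        for col in ("start", "n_meth", "n_unmeth"):
            bad = pd.to_numeric(df[col], errors="coerce").isna()
            _fail_rows(df, bad, path, f"non-numeric {col}")
            df[col] = df[col].astype(np.int64)
        _fail_rows(df, df["start"] < 1, path, "position < 1")
        _fail_rows(df, (df["n_meth"] < 0) | (df["n_unmeth"] < 0), path, "negative count")
        out = pd.DataFrame(
            {
                "chrom": df["chrom"],
                "pos": df["start"] - 1,
                "strand": "+",
                "meth_reads": df["n_meth"],
                "total_reads": df["n_meth"] + df["n_unmeth"],
            }
        )
    elif dialect == "methratio":
        try:
            df = pd.read_csv(path, sep="\t", dtype={0: str})
        except (ValueError, pd.errors.ParserError) as exc:
            raise MethylationParseError(f"{path}: {exc}") from exc
        if df.empty:
            return pd.DataFrame(columns=CPG_COLUMNS)
        cols = {c.lower(): c for c in df.columns}
        required = ["chr", "pos", "strand", "c_count", "ct_count"]
        missing = [c for c in required if c not in cols]
        if missing:
            raise MethylationParseError(f"{path}: missing column(s) {missing}")
        if "context" in cols:
            ctx = df[cols["context"]].astype(str).str.upper()
            df = df[ctx.str.contains("CG")].reset_index(drop=True)
        for key in ("pos", "c_count", "ct_count"):
            bad = pd.to_numeric(df[cols[key]], errors="coerce").isna()
            _fail_rows(df, bad, path, f"non-numeric {key}")
        meth = df[cols["c_count"]].astype(np.int64)
        total = df[cols["ct_count"]].astype(np.int64)
        _fail_rows(df, meth > total, path, "C_count > CT_count")
        _fail_rows(df, df[cols["pos"]].astype(np.int64) < 1, path, "position < 1")
        out = pd.DataFrame(
            {
                "chrom": df[cols["chr"]].astype(str),
                "pos": df[cols["pos"]].astype(np.int64) - 1,
                "strand": df[cols["strand"]].astype(str),
                "meth_reads": meth,
                "total_reads": total,
            }
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    n_zero = int((out["total_reads"] == 0).sum())
    if n_zero:
        logger.warning("%s: dropped %d rows with zero coverage", path, n_zero)
        out = out[out["total_reads"] > 0].reset_index(drop=True)
    bad = out["meth_reads"] > out["total_reads"]
    _fail_rows(out, bad, path, "meth_reads > total_reads")
    return out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def read_cpg_calls(path, dialect: str = "bismark_cov") -> list[CpGCall]:
    """Row-object variant of :func:`read_cpg_frame`."""
    return frame_to_calls(read_cpg_frame(path, dialect))


def calls_to_frame(calls: Iterable[CpGCall]) -> pd.DataFrame:
    calls = list(calls)
    if not calls:
        return pd.DataFrame(columns=CPG_COLUMNS)
    return pd.DataFrame(calls, columns=CPG_COLUMNS)


def frame_to_calls(frame: pd.DataFrame) -> list[CpGCall]:
    return [
        CpGCall(str(c), int(p), str(s), int(m), int(t)).validate()
        for c, p, s, m, t in frame[CPG_COLUMNS].itertuples(index=False)
    ]


def write_bismark_cov(frame: pd.DataFrame, path) -> None:
    """Write CpG calls (internal 0-based frame) as a Bismark coverage file."""
    pos1 = frame["pos"].to_numpy() + 1
    meth = frame["meth_reads"].to_numpy()
    total = frame["total_reads"].to_numpy()
    out = pd.DataFrame(
        {
            "chrom": frame["chrom"],
            "start": pos1,
            "end": pos1,
            "pct": np.round(100.0 * meth / total, 6),
            "n_meth": meth,
            "n_unmeth": total - meth,
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

_GTF_GENE_ID = re.compile(r'gene_id "([^"]+)"')


def _make_gene(gene_id: str, chrom: str, strand: str, start: int, end: int) -> GeneModel:
    if strand == "+":
        tss, tes = start, end
    elif strand == "-":
        tss, tes = end, start
    else:
        raise MethylationParseError(
            f"gene {gene_id}: strand {strand!r} (strand is required)"
        )
    return GeneModel(gene_id, chrom, strand, tss, tes, start, end)


def read_gene_models(path, dialect: str = "bed12") -> list[GeneModel]:
    """Read gene models from BED12 or GTF.

    One :class:`GeneModel` per gene; a GTF gene with several transcripts
    yields a single model spanning their union.  For ``-`` strand genes the
    TSS is the higher genomic coordinate.
    """
    path = Path(path)
    genes: list[GeneModel] = []
    if dialect == "bed12":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 6:
                    raise MethylationParseError(
                        f"{path}: line {lineno}: BED needs >=6 columns (strand required)"
                    )
                chrom, start, end, name, _score, strand = fields[:6]
                genes.append(_make_gene(name, chrom, strand, int(start), int(end)))
    elif dialect == "gtf":
        spans: dict[str, list] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 9:
                    raise MethylationParseError(f"{path}: line {lineno}: not GTF")
                chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields[:9]
                if feature not in ("gene", "transcript", "exon"):
                    continue
                m = _GTF_GENE_ID.search(attrs)
                if not m:
                    raise MethylationParseError(f"{path}: line {lineno}: no gene_id")
                gid = m.group(1)
                s0, e0 = int(start) - 1, int(end)  # GTF is 1-based inclusive
                rec = spans.setdefault(gid, [chrom, strand, s0, e0])
                rec[2] = min(rec[2], s0)
                rec[3] = max(rec[3], e0)
                if rec[1] != strand or rec[0] != chrom:
                    raise MethylationParseError(
                        f"{path}: gene {gid}: inconsistent chrom/strand"
                    )
        for gid, (chrom, strand, s0, e0) in spans.items():
            genes.append(_make_gene(gid, chrom, strand, s0, e0))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return genes


# ---------------------------------------------------------------------------
# Sample sheets
# ---------------------------------------------------------------------------

SHEET_COLUMNS = ["sample_id", "tissue", "age_weeks", "genotype", "replicate", "path"]


def read_sample_sheet(path) -> list[SampleInfo]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in SHEET_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise MethylationParseError(f"{path}: sample sheet missing {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise MethylationParseError(f"{path}: duplicate sample_id {dup!r}")
    if "path" not in df.columns:
        df["path"] = None
    return [
        SampleInfo(
            str(r.sample_id),
            str(r.tissue),
            float(r.age_weeks),
            str(r.genotype),
            str(r.replicate),
            None if pd.isna(r.path) else str(r.path),
        )
        for r in df.itertuples(index=False)
    ]


def write_sample_sheet(sheet: Sequence[SampleInfo], path) -> None:
    pd.DataFrame(sheet, columns=SHEET_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# DMR BED6+4
# ---------------------------------------------------------------------------

_DMR_HEADER = (
    "#chrom\tstart\tend\tname\tn_discriminating\tstrand\t"
    "category\ttiming\tdelta_newborn_adult\tp_tile\n"
)


def _fmt_float(x: float) -> str:
    return "NA" if (x is None or (isinstance(x, float) and math.isnan(x))) else repr(float(x))


def write_dmr_bed(dmrs: Sequence[DmrCall], path) -> None:
    """Write DMR calls as BED6+4 (0-based half-open); lossless round-trip."""
    dmrs = sorted(dmrs, key=lambda d: (d.chrom, d.start))
    with open(path, "w") as fh:
        fh.write(_DMR_HEADER)
        for i, d in enumerate(dmrs):
            fh.write(
                f"{d.chrom}\t{d.start}\t{d.end}\tdmr_{i:06d}\t{d.n_discriminating}\t.\t"
                f"{d.category}\t{d.timing}\t{_fmt_float(d.delta_newborn_adult)}\t"
                f"{_fmt_float(d.p_tile)}\n"
            )


def read_dmr_bed(path) -> list[DmrCall]:
    out: list[DmrCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 10:
                raise MethylationParseError(f"{path}: line {lineno}: expected 10 columns")
            out.append(
                DmrCall(
                    chrom=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    category=f[6],
                    n_discriminating=int(f[4]),
                    timing=f[7],
                    delta_newborn_adult=float("nan") if f[8] == "NA" else float(f[8]),
                    p_tile=float("nan") if f[9] == "NA" else float(f[9]),
                )
            )
    return out


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------


def read_expression_table(path) -> pd.DataFrame:
    """Genes x samples table of normalized expression (first column gene_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise MethylationParseError(f"{path}: negative expression values")
    return df


def write_expression_table(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id")
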