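"""Per-CpG methylation call tables: reading, strand merging, summarising.

The unit record is a CpG dinucleotide identified by the 0-based position of
its plus-strand cytosine, with methylated/unmethylated read counts. Input
cytosine reports (chrom, 1-based pos, strand, meth, unmeth, context) carry
one call per strand; `merge_strand_calls` sums the (+, p) and (-, p+1) calls
into the single per-CpG record used everywhere downstream.

%mCG at a covered position is 100*meth/(meth+unmeth); at zero coverage it is
missing, never 0 or 100, so weighted averages are not biased by uncovered
sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeLayout

log = logging.getLogger(__name__)

WILDTYPE = "wildtype"
MUTANT = "mutant"

_CALL_COLUMNS = ["chrom", "pos", "meth", "unmeth"]


class CytosineReportError(ValueError):
    """Malformed or invalid cytosine-report input."""


def _validate_calls(df: pd.DataFrame, layout: GenomeLayout | None) -> None:
    if (df["meth"] < 0).any() or (df["unmeth"] < 0).any():
        raise ValueError("negative read counts")
    if layout is not None:
        unknown = set(df["chrom"].unique()) - set(layout.names)
        if unknown:
            raise ValueError(f"unknown chroms: {sorted(unknown)}")
    for chrom, sub in df.groupby("chrom", sort=False, observed=True):
        pos = sub["pos"].to_numpy()
        if len(pos) > 1 and not (np.diff(pos) > 0).all():
            raise ValueError(f"positions not strictly increasing on {chrom}")


@dataclass
class CpGCallTable:
    """One sample's merged per-CpG calls.

    df columns: chrom (str), pos (0-based int, plus-strand C), meth, unmeth.
    Sorted by (chrom, pos); positions strictly increasing within a chrom.
    """

    sample_id: str
    group: str
    df: pd.DataFrame
    layout: GenomeLayout | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.df = (
            self.df[_CALL_COLUMNS]
            .sort_values(["chrom", "pos"], kind="mergesort")
            .reset_index(drop=True)
        )
        _validate_calls(self.df, self.layout)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def coverage(self) -> np.ndarray:
        return (self.df["meth"] + self.df["unmeth"]).to_numpy()

    def pct_mcg(self) -> np.ndarray:
        """Per-CpG %mCG; NaN where coverage is zero."""
        cov = self.coverage.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(cov > 0, 100.0 * self.df["meth"].to_numpy() / cov, np.nan)

    def restrict(self, chrom: str, start: int | None = None, end: int | None = None) -> pd.DataFrame:
        sub = self.df[self.df["chrom"] == chrom]
        if start is not None:
            sub = sub[sub["pos"] >= start]
        if end is not None:
            sub = sub[sub["pos"] < end]
        return sub


@dataclass
class StrandedCallTable:
    """Per-strand calls prior to CpG merging; minus-strand pos is the C on
    the minus strand (plus-strand C position + 1)."""

    sample_id: str
    group: str
    df: pd.DataFrame  # chrom, pos, strand, meth, unmeth
    layout: GenomeLayout | None = None


def read_cytosine_report(
    path: str | Path,
    layout: GenomeLayout,
    sample_id: str = "",
    group: str = WILDTYPE,
) -> StrandedCallTable:
    """Parse a cytosine-report TSV into a stranded call table.

    Input columns: chrom, 1-based position, strand (+/-), methylated count,
    unmethylated count, context. Only CG-context rows are kept; positions are
    converted to the 0-based internal convention; rows are sorted.
    """
    path = Path(path)
    records: list[tuple[str, int, str, int, int]] = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise CytosineReportError(f"{path}:{lineno}: expected 6 tab-separated fields, got {len(parts)}")
            chrom, pos_s, strand, meth_s, unmeth_s, context = parts[:6]
            try:
                pos1 = int(pos_s)
                meth = int(meth_s)
                unmeth = int(unmeth_s)
            except ValueError as exc:
                raise CytosineReportError(f"{path}:{lineno}: non-integer field ({exc})") from exc
            if strand not in ("+", "-"):
                raise CytosineReportError(f"{path}:{lineno}: bad strand {strand!r}")
            if context.upper() not in ("CG", "CPG"):
                dropped += 1
                continue
            if chrom not in layout:
                raise ValueError(f"{path}:{lineno}: unknown chrom {chrom!r}")
            if meth < 0 or unmeth < 0:
                raise ValueError(f"{path}:{lineno}: negative count")
            records.append((chrom, pos1 - 1, strand, meth, unmeth))
    if dropped:
        log.info("%s: dropped %d non-CpG-context rows", path, dropped)
    df = pd.DataFrame(records, columns=["chrom", "pos", "strand", "meth", "unmeth"])
    df = df.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)
    return StrandedCallTable(sample_id=sample_id or path.stem, group=group, df=df, layout=layout)


def merge_strand_calls(stranded: StrandedCallTable) -> CpGCallTable:
    """Merge (+, p) and (-, p+1) calls of the same CpG into one record at p.

    Unpaired records are retained at their plus-strand-equivalent position
    (a lone minus-strand call at p maps to p-1). Total meth and unmeth read
    counts are conserved exactly.
    """
    df = stranded.df
    out_frames = []
    for chrom, sub in df.groupby("chrom", sort=True):
        plus = sub[sub["strand"] == "+"]
        minus = sub[sub["strand"] == "-"]
        # minus-strand C at p belongs to the CpG whose plus-strand C is p-1
        minus_eq = minus.assign(pos=minus["pos"] - 1)
        merged = (
            pd.concat([plus[_CALL_COLUMNS], minus_eq[_CALL_COLUMNS]])
            .groupby("pos", as_index=False)[["meth", "unmeth"]]
            .sum()
        )
        merged.insert(0, "chrom", chrom)
        pos = merged["pos"].to_numpy()
        if len(pos) > 1 and (np.diff(pos) < 2).any():
            raise ValueError(f"overlapping plus-strand CpGs at distance < 2 on {chrom}")
        out_frames.append(merged)
    out = (
        pd.concat(out_frames, ignore_index=True)
        if out_frames
        else pd.DataFrame(columns=_CALL_COLUMNS)
    )
    return CpGCallTable(
        sample_id=stranded.sample_id, group=stranded.group, df=out, layout=stranded.layout
    )


def conversion_rate(calls: CpGCallTable) -> float:
    """Bisulphite conversion rate (%) pooled over the spike-in contig.

    Every cytosine of the spike-in is unmethylated truth, so the conversion
    rate is 100*unmeth/(meth+unmeth) pooled across its covered positions.
    """
    if calls.layout is None or calls.layout.spike_in is None:
        raise ValueError("layout with a spike-in contig required")
    sub = calls.df[calls.df["chrom"] == calls.layout.spike_in.name]
    meth = int(sub["meth"].sum())
    unmeth = int(sub["unmeth"].sum())
    if meth + unmeth == 0:
        raise ValueError("no covered spike-in positions")
    return 100.0 * unmeth / (meth + unmeth)


def coverage_profile(table: CpGCallTable, thresholds: list[int]) -> list[float]:
    """Fraction of CpGs covered by more than each threshold (strict >)."""
    if len(table) == 0:
        raise ValueError("empty call table")
    if any(t < 0 for t in thresholds):
        raise ValueError("thresholds must be >= 0")
    cov = table.coverage
    return [float((cov > t).mean()) for t in thresholds]


def subsample_calls(table: CpGCallTable, fraction: float, seed: int) -> CpGCallTable:
    """Binomially thin each CpG's meth and unmeth counts to the given fraction.

    Each read is retained independently with probability `fraction`;
    deterministic for a fixed seed. Used to equalise sequencing depth across
    libraries before cross-tissue comparisons.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0,1], got {fraction}")
    rng = np.random.default_rng(seed)
    df = table.df.copy()
    df["meth"] = rng.binomial(df["meth"].to_numpy(), fraction)
    df["unmeth"] = rng.binomial(df["unmeth"].to_numpy(), fraction)
    meta = dict(table.meta, subsample_fraction=fraction, subsample_seed=seed)
    return CpGCallTable(table.sample_id, table.group, df, table.layout, meta)


def binned_methylation(table: CpGCallTable, bin_size: int = 10_000) -> pd.DataFrame:
    """Weighted %mCG per non-overlapping genomic bin.

    Bin value is 100*sum(meth)/sum(meth+unmeth) over the bin's covered CpGs;
    bins with no covered CpG are absent from the output (missing, not zero).
    Columns: chrom, bin_start, pct_mcg, n_cpgs.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    df = table.df
    covered = df[(df["meth"] + df["unmeth"]) > 0].copy()
    if covered.empty:
        return pd.DataFrame(columns=["chrom", "bin_start", "pct_mcg", "n_cpgs"])
    covered["bin_start"] = (covered["pos"] // bin_size) * bin_size
    g = covered.groupby(["chrom", "bin_start"], as_index=False).agg(
        meth=("meth", "sum"), unmeth=("unmeth", "sum"), n_cpgs=("pos", "size")
    )
    g["pct_mcg"] = 100.0 * g["meth"] / (g["meth"] + g["unmeth"])
    return g[["chrom", "bin_start", "pct_mcg", "n_cpgs"]]


def region_weighted_methylation(
    table: CpGCallTable, chrom: str, start: int, end: int
) -> float:
    """Coverage-weighted %mCG over a half-open interval; NaN if uncovered."""
    sub = table.restrict(chrom, start, end)
    meth = sub["meth"].sum()
    cov = meth + sub["unmeth"].sum()
    if cov == 0:
        return float("nan")
    return 100.0 * float(meth) / float(cov)


def write_bedgraph(table: CpGCallTable, path: str | Path, what: str = "pct_mcg") -> None:
    """Write per-CpG %mCG or coverage as a 0-based half-open bedGraph."""
    df = table.df
    if what == "pct_mcg":
        values = table.pct_mcg()
        keep = ~np.isnan(values)
    elif what == "coverage":
        values = table.coverage.astype(float)
        keep = np.ones(len(df), dtype=bool)
    else:
        raise ValueError(f"unknown track {what!r}")
    with open(path, "w") as fh:
        for (chrom, pos), v in zip(
            df.loc[keep, ["chrom", "pos"]].itertuples(index=False), values[keep]
        ):
            fh.write(f"{chrom}\t{pos}\t{pos + 2}\t{v:.6g}\n")


def summarize_sample(table: CpGCallTable) -> dict:
    """TSV-ready summary: conversion %, coverage fractions, CpG count."""
    out = {
        "sample": table.sample_id,
        "group": table.group,
        "n_cpgs": len(table),
    }
    if table.layout is not None and table.layout.spike_in is not None:
        try:
            out["conversion_pct"] = conversion_rate(table)
        except ValueError:
            out["conversion_pct"] = float("nan")
    frac5, frac20 = coverage_profile(table, [5, 20])
    out["frac_gt5x"] = frac5
    out["frac_gt20x"] = frac20
    return out
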