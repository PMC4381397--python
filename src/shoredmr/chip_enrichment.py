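"""ChIP-seq coverage, RPKM enrichment and peak fold-change analysis.

Aligned reads are extended strand-aware to the 200-bp ChIP fragment length,
fragment density is summarised in fixed 32-nt genome bins, and per-interval
RPKM (fragments per kb of interval per million library fragments) supports:

* enrichment calls over input (> min_fold in every ChIP replicate),
* peak-level mutant/wild-type fold changes with a 50% cut-off,
* DMR-proximity flags for changed peaks,
* active/poised regulatory-state classification from H3K4me1/H3K27ac flags.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeLayout
from .intervals import Interval, gap_distance, merge_union


@dataclass
class FragmentSet:
    """Aligned reads as (chrom, 5' position, strand) with the library size;
    each read stands for a fragment extended to fragment_length from its 5'
    end toward 3'."""

    df: pd.DataFrame  # columns chrom, pos, strand
    fragment_length: int = 200

    @property
    def library_size(self) -> int:
        return len(self.df)

    def fragment_intervals(self, layout: GenomeLayout | None = None) -> pd.DataFrame:
        """Half-open fragment intervals, clipped at chromosome ends."""
        pos = self.df["pos"].to_numpy()
        plus = (self.df["strand"] == "+").to_numpy()
        start = np.where(plus, pos, pos - (self.fragment_length - 1))
        end = start + self.fragment_length
        out = pd.DataFrame({"chrom": self.df["chrom"], "start": start, "end": end})
        out["start"] = out["start"].clip(lower=0)
        if layout is not None:
            lengths = out["chrom"].map({c.name: c.length for c in layout.contigs})
            out["end"] = np.minimum(out["end"], lengths)
        return out[out["end"] > out["start"]].reset_index(drop=True)


@dataclass
class BinnedCoverage:
    """Per-chromosome fragment counts in fixed-width bins.

    Bin counts record the number of fragments overlapping each bin, so a
    200-bp fragment spans several 32-nt bins and the bin-count total exceeds
    the library size. Sorted fragment starts/ends are retained so interval
    fragment counts (for RPKM) are exact rather than bin-approximated.
    """

    bin_width: int
    counts: dict[str, np.ndarray]
    library_size: int
    frag_starts: dict[str, np.ndarray] = field(default_factory=dict)
    frag_ends: dict[str, np.ndarray] = field(default_factory=dict)

    def fragments_overlapping(self, chrom: str, start: int, end: int) -> int:
        starts = self.frag_starts.get(chrom)
        if starts is None:
            return 0
        ends = self.frag_ends[chrom]
        # overlapping = total - (start >= end of query) - (end <= start of query)
        n = len(starts)
        return int(n - (n - np.searchsorted(starts, end, side="left"))
                   - np.searchsorted(ends, start, side="right"))


def extend_and_bin(
    reads: FragmentSet, layout: GenomeLayout, bin_width: int = 32
) -> BinnedCoverage:
    """Extend reads to fragments and count fragments overlapping each bin."""
    frags = reads.fragment_intervals(layout)
    counts: dict[str, np.ndarray] = {}
    frag_starts: dict[str, np.ndarray] = {}
    frag_ends: dict[str, np.ndarray] = {}
    for contig in layout.contigs:
        n_bins = -(-contig.length // bin_width)
        counts[contig.name] = np.zeros(n_bins, dtype=np.int64)
    for chrom, sub in frags.groupby("chrom", sort=True):
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        frag_starts[chrom] = np.sort(s)
        frag_ends[chrom] = np.sort(e)
        if chrom not in counts:
            continue
        n_bins = len(counts[chrom])
        b0 = np.clip(s // bin_width, 0, n_bins - 1)
        b1 = np.clip((e - 1) // bin_width, 0, n_bins - 1)
        # +1 at b0, -1 after b1, cumulative sum = overlap count per bin
        diff = np.zeros(n_bins + 1, dtype=np.int64)
        np.add.at(diff, b0, 1)
        np.add.at(diff, b1 + 1, -1)
        counts[chrom] = np.cumsum(diff[:-1])
    return BinnedCoverage(
        bin_width=bin_width,
        counts=counts,
        library_size=reads.library_size,
        frag_starts=frag_starts,
        frag_ends=frag_ends,
    )


def rpkm(coverage: BinnedCoverage, chrom: str, start: int, end: int) -> float:
    """Fragments overlapping the interval x 1e9 / (interval bp x library)."""
    if end <= start:
        raise ValueError("interval length must be positive")
    if coverage.library_size <= 0:
        raise ValueError("zero library size")
    n = coverage.fragments_overlapping(chrom, start, end)
    return n * 1e9 / ((end - start) * coverage.library_size)


@dataclass(frozen=True)
class EnrichmentParams:
    min_fold_over_input: float = 2.0
    fold_change_cut: float = 0.5  # 50% change, i.e. fold >1.5 or <1/1.5
    proximity_window: int = 2_000

    def __post_init__(self) -> None:
        if min(self.min_fold_over_input, self.fold_change_cut, self.proximity_window) <= 0:
            raise ValueError("enrichment parameters must be positive")


def call_enrichment(
    chrom: str,
    start: int,
    end: int,
    chip_reps: list[BinnedCoverage],
    input_cov: BinnedCoverage,
    params: EnrichmentParams = EnrichmentParams(),
) -> tuple[bool, list[float]]:
    """Enriched iff ChIP RPKM / input RPKM strictly exceeds min_fold in
    every replicate; zero input with nonzero ChIP counts as infinite ratio."""
    if len(chip_reps) < 2:
        raise ValueError("need >=2 ChIP replicates")
    r_input = rpkm(input_cov, chrom, start, end)
    ratios = []
    for rep in chip_reps:
        r = rpkm(rep, chrom, start, end)
        if r_input > 0:
            ratios.append(r / r_input)
        else:
            ratios.append(math.inf if r > 0 else math.nan)
    enriched = all(r > params.min_fold_over_input for r in ratios if not math.isnan(r)) and not any(
        math.isnan(r) for r in ratios
    )
    return enriched, ratios


def union_peaks(peak_sets: list[list[tuple[str, int, int]]]) -> list[tuple[str, int, int]]:
    """Merge >=1 peak sets into a disjoint sorted union; abutting intervals
    (shared half-open boundary) are coalesced."""
    by_chrom: dict[str, list[Interval]] = {}
    for peaks in peak_sets:
        for chrom, s, e in peaks:
            by_chrom.setdefault(chrom, []).append((s, e))
    out = []
    for chrom in sorted(by_chrom):
        out.extend((chrom, s, e) for s, e in merge_union(by_chrom[chrom], merge_abutting=True))
    return out


def peak_fold_change(
    peaks: list[tuple[str, int, int]],
    wt_reps: list[BinnedCoverage],
    mut_reps: list[BinnedCoverage],
    params: EnrichmentParams = EnrichmentParams(),
) -> pd.DataFrame:
    """Per-peak mutant/wild-type RPKM fold change with labels.

    fold = mean mutant RPKM / mean wild-type RPKM; 'increased' iff
    fold > 1 + cut, 'decreased' iff fold < 1/(1 + cut) (both strict);
    both-zero peaks are 'unchanged'.
    """
    if not wt_reps or not mut_reps:
        raise ValueError("need >=1 replicate per group")
    hi = 1.0 + params.fold_change_cut
    lo = 1.0 / hi
    rows = []
    for chrom, s, e in peaks:
        wt = float(np.mean([rpkm(c, chrom, s, e) for c in wt_reps]))
        mut = float(np.mean([rpkm(c, chrom, s, e) for c in mut_reps]))
        if wt == 0 and mut == 0:
            fold, label = math.nan, "unchanged"
        elif wt == 0:
            fold, label = math.inf, "increased"
        else:
            fold = mut / wt
            label = "increased" if fold > hi else "decreased" if fold < lo else "unchanged"
        rows.append({"chrom": chrom, "start": s, "end": e, "wt_rpkm": wt,
                     "mut_rpkm": mut, "fold": fold, "label": label})
    return pd.DataFrame(rows)


def peaks_near_dmrs(
    peaks: list[tuple[str, int, int]],
    dmrs: list[tuple[str, int, int]],
    proximity_window: int = 2_000,
) -> pd.DataFrame:
    """Nearest-DMR edge distance per peak (0 when overlapping) and a flag
    for distance <= proximity_window; peaks on DMR-free chromosomes get a
    missing distance and False flag."""
    dmr_by_chrom: dict[str, list[Interval]] = {}
    for chrom, s, e in dmrs:
        dmr_by_chrom.setdefault(chrom, []).append((s, e))
    rows = []
    for chrom, s, e in peaks:
        cands = dmr_by_chrom.get(chrom)
        if not cands:
            dist: float = math.nan
            flag = False
        else:
            dist = min(gap_distance((s, e), iv) for iv in cands)
            flag = dist <= proximity_window
        rows.append({"chrom": chrom, "start": s, "end": e,
                     "nearest_dmr_distance": dist, "within_window": flag})
    return pd.DataFrame(rows)


def classify_regulatory_state(k4me1_enriched: bool, k27ac_enriched: bool) -> str:
    """Active = H3K4me1 and H3K27ac; poised = H3K4me1 only; otherwise none
    (H3K27ac alone does not define a state here)."""
    if k4me1_enriched and k27ac_enriched:
        return "active"
    if k4me1_enriched:
        return "poised"
    return "none"


def _mann_whitney_u(a: np.ndarray, b: np.ndarray) -> float:
    """U for sample a: number of (a_i, b_j) pairs with a_i > b_j (+0.5 ties)."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def mann_whitney(a, b) -> tuple[float, float]:
    """Mann-Whitney U with a two-sided p-value.

    Exact path (enumeration of all group assignments of the pooled values)
    when n_a + n_b <= 16 and there are no ties; otherwise the normal
    approximation with tie and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    u_obs = _mann_whitney_u(a, b)
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    if len(pooled) <= 16 and no_ties:
        na = len(a)
        mn = na * len(b)
        centre = mn / 2.0
        obs_dev = abs(u_obs - centre)
        total = 0
        extreme = 0
        for combo in itertools.combinations(range(len(pooled)), na):
            mask = np.zeros(len(pooled), dtype=bool)
            mask[list(combo)] = True
            u = _mann_whitney_u(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - centre) >= obs_dev - 1e-12:
                extreme += 1
        return u_obs, extreme / total
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def read_fragment_bed(path: str | Path, fragment_length: int = 200) -> FragmentSet:
    """Read reads from BED6 (chrom, start, end, name, score, strand); the 5'
    position is start on + and end-1 on -."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, s, e = f[0], int(f[1]), int(f[2])
            strand = f[5] if len(f) > 5 else "+"
            rows.append((chrom, s if strand == "+" else e - 1, strand))
    return FragmentSet(pd.DataFrame(rows, columns=["chrom", "pos", "strand"]),
                       fragment_length=fragment_length)


def write_fragment_bed(frags: FragmentSet, path: str | Path, read_length: int = 50) -> None:
    with open(path, "w") as fh:
        for chrom, pos, strand in frags.df.itertuples(index=False):
            if strand == "+":
                s, e = pos, pos + read_length
            else:
                s, e = pos - read_length + 1, pos + 1
            fh.write(f"{chrom}\t{max(0, s)}\t{e}\tread\t0\t{strand}\n")


def write_bedgraph_bins(cov: BinnedCoverage, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(cov.counts):
            arr = cov.counts[chrom]
            for i, v in enumerate(arr):
                if v:
                    fh.write(f"{chrom}\t{i * cov.bin_width}\t{(i + 1) * cov.bin_width}\t{v}\n")
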