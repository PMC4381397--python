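"""Differentially methylated region (DMR) calling between two genotype groups.

The procedure follows the local-likelihood smoothing approach for low-pass
bisulphite data: per-sample methylation proportions are smoothed with a
coverage- and kernel-weighted local quadratic fit, a per-CpG signal-to-noise
t-statistic contrasts the groups, CpGs beyond empirical quantile cut-offs of
the statistic are chained into candidate regions, and candidates are filtered
on CpG count and raw (count-based) mean methylation change.

Two named parameterisations are provided:

* full-depth  — smoothing ns=20, h=250 bp, maxGap=1e8; CpGs kept when
  coverage >=8 in at least one replicate of each group; t quantiles
  0.01/0.99; >10 CpGs per region (strict); mean change >15 points; no
  intra-region gap limit.
* cross-tissue — smoothing ns=50, h=500 bp, maxGap=1e7; coverage >=6 in
  both replicates; max 1,500 bp between consecutive region CpGs; >=8 CpGs;
  mean change >15 points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .methylome_io import MUTANT, WILDTYPE, CpGCallTable

log = logging.getLogger(__name__)

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


class Direction(str, Enum):
    HYPER = "hyper_in_mutant"
    HYPO = "hypo_in_mutant"


@dataclass(frozen=True)
class SmoothingParams:
    """Local smoothing controls: ns = minimum CpGs per window, h = minimum
    window half-width (bp), max_gap = bp gap splitting CpG clusters."""

    ns: int = 20
    h: float = 250.0
    max_gap: int = 100_000_000

    def __post_init__(self) -> None:
        if self.ns < 1 or self.h <= 0 or self.max_gap <= 0:
            raise ValueError("invalid smoothing parameters")


@dataclass(frozen=True)
class DmrCallParams:
    min_coverage: int = 8
    coverage_mode: str = "at_least_one_replicate_per_group"  # or "both_replicates"
    q_low: float = 0.01
    q_high: float = 0.99
    min_cpgs: int = 10
    min_cpgs_strict: bool = True  # strict > vs inclusive >=
    min_mean_delta: float = 15.0  # percentage points, strict >
    max_intra_gap: int | None = None  # bp between consecutive DMR CpGs

    def __post_init__(self) -> None:
        if not 0 < self.q_low < self.q_high < 1:
            raise ValueError("require 0 < q_low < q_high < 1")
        if self.min_mean_delta <= 0:
            raise ValueError("min_mean_delta must be positive")
        if self.coverage_mode not in ("at_least_one_replicate_per_group", "both_replicates"):
            raise ValueError(f"unknown coverage_mode {self.coverage_mode!r}")


FULL_DEPTH_SMOOTHING = SmoothingParams(ns=20, h=250.0, max_gap=100_000_000)
CROSS_TISSUE_SMOOTHING = SmoothingParams(ns=50, h=500.0, max_gap=10_000_000)
FULL_DEPTH_CALLING = DmrCallParams(
    min_coverage=8,
    coverage_mode="at_least_one_replicate_per_group",
    min_cpgs=10,
    min_cpgs_strict=True,
    max_intra_gap=None,
)
CROSS_TISSUE_CALLING = DmrCallParams(
    min_coverage=6,
    coverage_mode="both_replicates",
    min_cpgs=8,
    min_cpgs_strict=False,
    max_intra_gap=1_500,
)


@dataclass
class Dmr:
    chrom: str
    start: int
    end: int  # half-open; last CpG position + 2
    n_cpgs: int
    mean_wt: float
    mean_mut: float
    delta: float  # mean_mut - mean_wt, percentage points
    direction: Direction
    area_stat: float  # sum of per-CpG t over the region

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def cluster_cpgs(positions: np.ndarray, max_gap: int) -> list[np.ndarray]:
    """Split sorted positions into clusters at gaps greater than max_gap."""
    positions = np.asarray(positions)
    if len(positions) == 0:
        return []
    if len(positions) > 1 and (np.diff(positions) <= 0).any():
        raise ValueError("positions must be sorted strictly increasing")
    breaks = np.flatnonzero(np.diff(positions) > max_gap) + 1
    return np.split(positions, breaks)


@njit(cache=True)
def _smooth_cluster_kernel(pos, y, cov, ns, h, out):  # pragma: no cover - jitted
    n = pos.shape[0]
    for j in range(n):
        pj = pos[j]
        # half-width: max(h, smallest half-width containing ns CpGs)
        if n <= ns:
            w = max(h, max(pj - pos[0], pos[n - 1] - pj))
        else:
            lo = j
            hi = j
            cnt = 1
            while cnt < ns:
                dl = pj - pos[lo - 1] if lo > 0 else -1.0
                dr = pos[hi + 1] - pj if hi < n - 1 else -1.0
                if dr < 0 or (dl >= 0 and dl <= dr):
                    lo -= 1
                else:
                    hi += 1
                cnt += 1
            w = max(pj - pos[lo], pos[hi] - pj)
            if w < h:
                w = h
        # window members
        lo = j
        while lo > 0 and pj - pos[lo - 1] <= w:
            lo -= 1
        hi = j
        while hi < n - 1 and pos[hi + 1] - pj <= w:
            hi += 1
        # weighted sums for the quadratic normal equations
        s0 = s1 = s2 = s3 = s4 = 0.0
        t0 = t1 = t2 = 0.0
        wsum = 0.0
        ysum = 0.0
        ndist = 0
        prev = -1.0e30
        for k in range(lo, hi + 1):
            if cov[k] <= 0:
                continue
            x = pos[k] - pj
            u = abs(x) / (w + 1.0)
            tri = (1.0 - u * u * u) ** 3
            wk = tri * cov[k]
            if wk <= 0.0:
                continue
            if pos[k] != prev:
                ndist += 1
                prev = pos[k]
            wsum += wk
            ysum += wk * y[k]
            x2 = x * x
            s0 += wk
            s1 += wk * x
            s2 += wk * x2
            s3 += wk * x2 * x
            s4 += wk * x2 * x2
            t0 += wk * y[k]
            t1 += wk * x * y[k]
            t2 += wk * x2 * y[k]
        if wsum <= 0.0:
            out[j] = np.nan
            continue
        mean = ysum / wsum
        if ndist < 3:
            out[j] = mean
            continue
        # solve the 3x3 system [s0 s1 s2; s1 s2 s3; s2 s3 s4] b = [t0 t1 t2]
        det = (
            s0 * (s2 * s4 - s3 * s3)
            - s1 * (s1 * s4 - s3 * s2)
            + s2 * (s1 * s3 - s2 * s2)
        )
        scale = s0 * s2 * s4
        if scale <= 0.0 or abs(det) < 1e-12 * scale:
            out[j] = mean
            continue
        b0 = (
            t0 * (s2 * s4 - s3 * s3)
            - s1 * (t1 * s4 - s3 * t2)
            + s2 * (t1 * s3 - s2 * t2)
        ) / det
        out[j] = b0
    # clip to the proportion scale
    for j in range(n):
        if out[j] < 0.0:
            out[j] = 0.0
        elif out[j] > 1.0:
            out[j] = 1.0


def smooth_sample(
    table: CpGCallTable, params: SmoothingParams, use_numba: bool | None = None
) -> np.ndarray:
    """Smoothed methylation proportion per CpG (aligned with table.df rows).

    Within each CpG cluster (split at max_gap) every CpG gets a window of
    half-width max(h, smallest half-width holding ns CpGs); a quadratic is
    fitted to the covered CpGs' proportions with tricube(distance) x coverage
    weights and evaluated at the CpG, clipped to [0, 1]. Windows with fewer
    than 3 distinct covered positions fall back to the coverage-weighted
    window mean; windows never cross cluster boundaries. CpGs with no covered
    neighbour are NaN.
    """
    df = table.df
    out = np.full(len(df), np.nan)
    kernel = _smooth_cluster_kernel
    if use_numba is False or (use_numba is None and not _HAVE_NUMBA):
        kernel = getattr(_smooth_cluster_kernel, "py_func", _smooth_cluster_kernel)
    row = 0
    for chrom, sub in df.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy(dtype=np.float64)
        cov = (sub["meth"] + sub["unmeth"]).to_numpy(dtype=np.float64)
        with np.errstate(invalid="ignore", divide="ignore"):
            y = np.where(cov > 0, sub["meth"].to_numpy(dtype=np.float64) / cov, 0.0)
        start = 0
        for cluster in cluster_cpgs(pos, params.max_gap):
            m = len(cluster)
            seg = np.empty(m)
            kernel(pos[start : start + m], y[start : start + m], cov[start : start + m],
                   params.ns, float(params.h), seg)
            out[row + start : row + start + m] = seg
            start += m
        row += len(sub)
    return out


def align_samples(samples: list[CpGCallTable]) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Outer-join all samples on (chrom, pos).

    Returns (index frame with chrom/pos, meth[n_cpgs, n_samples],
    unmeth[n_cpgs, n_samples]); missing calls become 0/0.
    """
    keys = None
    for t in samples:
        k = t.df[["chrom", "pos"]]
        keys = k if keys is None else pd.concat([keys, k])
    keys = (
        keys.drop_duplicates()
        .sort_values(["chrom", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )
    n = len(keys)
    meth = np.zeros((n, len(samples)), dtype=np.int64)
    unmeth = np.zeros((n, len(samples)), dtype=np.int64)
    for i, t in enumerate(samples):
        m = keys.merge(t.df, on=["chrom", "pos"], how="left")
        meth[:, i] = m["meth"].fillna(0).to_numpy(dtype=np.int64)
        unmeth[:, i] = m["unmeth"].fillna(0).to_numpy(dtype=np.int64)
    return keys, meth, unmeth


def coverage_filter(
    samples: list[CpGCallTable],
    min_coverage: int,
    coverage_mode: str = "at_least_one_replicate_per_group",
    aligned: tuple[pd.DataFrame, np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Boolean mask over the aligned CpG universe of positions retained for
    testing: coverage >= min_coverage in at least one replicate of every
    group, or in every replicate, per coverage_mode."""
    groups = {t.group for t in samples}
    if WILDTYPE not in groups or MUTANT not in groups:
        raise ValueError("need at least one sample per group")
    keys, meth, unmeth = aligned if aligned is not None else align_samples(samples)
    cov = meth + unmeth
    masks = []
    for grp in (WILDTYPE, MUTANT):
        idx = [i for i, t in enumerate(samples) if t.group == grp]
        grp_cov = cov[:, idx] >= min_coverage
        if coverage_mode == "at_least_one_replicate_per_group":
            masks.append(grp_cov.any(axis=1))
        else:
            masks.append(grp_cov.all(axis=1))
    return masks[0] & masks[1]


def group_tstat(
    smoothed: np.ndarray,
    groups: list[str],
    local_span: int = 101,
    floor_quantile: float | None = 0.75,
    chrom_ids: np.ndarray | None = None,
) -> np.ndarray:
    """Per-CpG t-statistic contrasting mutant vs wild-type smoothed values.

    t_j = (mean_mut - mean_wt) / sqrt(s2_j * (1/n_mut + 1/n_wt)) with s2_j
    the pooled within-group variance of the smoothed values, averaged over
    the local_span nearest retained CpGs (within a chromosome) and floored
    at the genome-wide floor_quantile of the local variance. Positive t
    means hypermethylated in mutant. Pass floor_quantile=None and
    local_span=1 for the unadjusted statistic.

    smoothed: array [n_cpgs, n_samples]; groups: per-sample labels.
    """
    smoothed = np.asarray(smoothed, dtype=float)
    wt_idx = [i for i, g in enumerate(groups) if g == WILDTYPE]
    mut_idx = [i for i, g in enumerate(groups) if g == MUTANT]
    if not wt_idx or not mut_idx:
        raise ValueError("need at least one sample per group")
    n1, n2 = len(wt_idx), len(mut_idx)
    wt = smoothed[:, wt_idx]
    mut = smoothed[:, mut_idx]
    mean_wt = wt.mean(axis=1)
    mean_mut = mut.mean(axis=1)
    dof = n1 + n2 - 2
    if dof > 0:
        ss = ((wt - mean_wt[:, None]) ** 2).sum(axis=1) + (
            (mut - mean_mut[:, None]) ** 2
        ).sum(axis=1)
        s2 = ss / dof
    else:
        s2 = np.zeros(len(smoothed))
    if local_span > 1:
        s = pd.Series(s2)
        if chrom_ids is not None:
            s2 = (
                s.groupby(pd.Series(chrom_ids))
                .transform(lambda x: x.rolling(local_span, center=True, min_periods=1).mean())
                .to_numpy()
            )
        else:
            s2 = s.rolling(local_span, center=True, min_periods=1).mean().to_numpy()
    if floor_quantile is not None and len(s2):
        floor = np.quantile(s2, floor_quantile)
        s2 = np.maximum(s2, floor)
    denom = np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
    num = mean_mut - mean_wt
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(denom > 0, num / denom, np.where(num == 0, 0.0, np.inf * np.sign(num)))
    return t


def threshold_quantiles(
    t: np.ndarray, q_low: float = 0.01, q_high: float = 0.99
) -> tuple[float, float]:
    """Empirical (linear-interpolation) quantile cut-offs of the t values."""
    t = np.asarray(t, dtype=float)
    finite = t[np.isfinite(t)]
    if len(finite) < 100:
        raise ValueError(f"need >=100 finite t values, got {len(finite)}")
    lo, hi = np.quantile(finite, [q_low, q_high])
    return float(lo), float(hi)


@dataclass
class Candidate:
    chrom: str
    cpg_index: np.ndarray  # indices into the retained-CpG arrays
    positions: np.ndarray
    side: Direction
    area_stat: float

    @property
    def start(self) -> int:
        return int(self.positions[0])

    @property
    def end(self) -> int:
        # + 2 covers both strands' cytosines of the last CpG
        return int(self.positions[-1]) + 2


def assemble_dmrs(
    t: np.ndarray,
    cutoffs: tuple[float, float],
    positions: np.ndarray,
    chroms: np.ndarray,
    max_intra_gap: int | None = None,
) -> list[Candidate]:
    """Chain retained CpGs beyond the same cut-off side into candidates.

    A candidate is a maximal run of consecutive retained CpGs with t above
    the high cut (hyper side) or below the low cut (hypo side), consecutive
    CpGs at most max_intra_gap apart (unbounded when None) and on one
    chromosome.
    """
    low_cut, high_cut = cutoffs
    t = np.asarray(t, dtype=float)
    positions = np.asarray(positions)
    side = np.zeros(len(t), dtype=np.int8)
    side[t > high_cut] = 1
    side[t < low_cut] = -1
    out: list[Candidate] = []
    i = 0
    n = len(t)
    while i < n:
        if side[i] == 0:
            i += 1
            continue
        j = i + 1
        while (
            j < n
            and side[j] == side[i]
            and chroms[j] == chroms[i]
            and (max_intra_gap is None or positions[j] - positions[j - 1] <= max_intra_gap)
        ):
            j += 1
        idx = np.arange(i, j)
        out.append(
            Candidate(
                chrom=str(chroms[i]),
                cpg_index=idx,
                positions=positions[idx],
                side=Direction.HYPER if side[i] > 0 else Direction.HYPO,
                area_stat=float(t[idx].sum()),
            )
        )
        i = j
    return out


def filter_dmrs(
    candidates: list[Candidate],
    keys: pd.DataFrame,
    meth: np.ndarray,
    unmeth: np.ndarray,
    groups: list[str],
    retained_index: np.ndarray,
    params: DmrCallParams,
) -> list[Dmr]:
    """Apply the CpG-count and raw mean-methylation-change filters.

    Group means are the coverage-weighted region methylation computed from
    raw read counts, averaged across a group's replicates; the candidate is
    kept when |mean_mut - mean_wt| > min_mean_delta and the CpG count
    satisfies the active rule (strict > in full-depth mode, >= otherwise).
    """
    wt_idx = [i for i, g in enumerate(groups) if g == WILDTYPE]
    mut_idx = [i for i, g in enumerate(groups) if g == MUTANT]
    out: list[Dmr] = []
    for cand in candidates:
        n_cpg = len(cand.cpg_index)
        if params.min_cpgs_strict:
            if not n_cpg > params.min_cpgs:
                continue
        elif not n_cpg >= params.min_cpgs:
            continue
        rows = retained_index[cand.cpg_index]

        def _group_mean(idx: list[int]) -> float:
            vals = []
            for i in idx:
                m = meth[rows, i].sum()
                c = m + unmeth[rows, i].sum()
                if c > 0:
                    vals.append(100.0 * m / c)
            return float(np.mean(vals)) if vals else float("nan")

        mean_wt = _group_mean(wt_idx)
        mean_mut = _group_mean(mut_idx)
        delta = mean_mut - mean_wt
        if not abs(delta) > params.min_mean_delta:
            continue
        direction = Direction.HYPER if delta > 0 else Direction.HYPO
        if direction is not cand.side:
            continue  # raw change contradicts the statistic's side
        out.append(
            Dmr(
                chrom=cand.chrom,
                start=cand.start,
                end=cand.end,
                n_cpgs=n_cpg,
                mean_wt=mean_wt,
                mean_mut=mean_mut,
                delta=delta,
                direction=direction,
                area_stat=cand.area_stat,
            )
        )
    return out


def call_dmrs(
    samples: list[CpGCallTable],
    smoothing: SmoothingParams = FULL_DEPTH_SMOOTHING,
    calling: DmrCallParams = FULL_DEPTH_CALLING,
) -> list[Dmr]:
    """Full pipeline: align, filter coverage, smooth, t-stat, assemble, filter."""
    aligned = align_samples(samples)
    keys, meth, unmeth = aligned
    retained = coverage_filter(samples, calling.min_coverage, calling.coverage_mode, aligned)
    retained_index = np.flatnonzero(retained)
    if len(retained_index) == 0:
        return []
    groups = [t.group for t in samples]
    smoothed = np.column_stack(
        [
            smooth_sample(
                CpGCallTable(
                    t.sample_id,
                    t.group,
                    keys.assign(meth=meth[:, i], unmeth=unmeth[:, i]),
                    t.layout,
                ),
                smoothing,
            )
            for i, t in enumerate(samples)
        ]
    )
    sm = smoothed[retained_index]
    chroms = keys["chrom"].to_numpy()[retained_index]
    positions = keys["pos"].to_numpy()[retained_index]
    chrom_ids = pd.factorize(chroms)[0]
    t = group_tstat(sm, groups, chrom_ids=chrom_ids)
    cutoffs = threshold_quantiles(t, calling.q_low, calling.q_high)
    candidates = assemble_dmrs(t, cutoffs, positions, chroms, calling.max_intra_gap)
    dmrs = filter_dmrs(candidates, keys, meth, unmeth, groups, retained_index, calling)
    log.info("called %d DMRs from %d candidates over %d retained CpGs",
             len(dmrs), len(candidates), len(retained_index))
    return dmrs


def summarize_directions(dmrs: list[Dmr]) -> dict:
    """Counts of hyper/hypo-in-mutant regions and the rounded % hyper."""
    if not dmrs:
        raise ValueError("no DMRs to summarise")
    hyper = sum(1 for d in dmrs if d.direction is Direction.HYPER)
    hypo = len(dmrs) - hyper
    return {
        "n_total": len(dmrs),
        "n_hyper": hyper,
        "n_hypo": hypo,
        "pct_hyper": round(100.0 * hyper / len(dmrs)),
    }


def dmrs_to_frame(dmrs: list[Dmr]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": d.chrom,
                "start": d.start,
                "end": d.end,
                "name": d.direction.value,
                "score": abs(d.delta),
                "n_cpgs": d.n_cpgs,
                "mean_wt": d.mean_wt,
                "mean_mut": d.mean_mut,
                "delta": d.delta,
                "area_stat": d.area_stat,
            }
            for d in dmrs
        ]
    )


def write_dmr_bed(dmrs: list[Dmr], path) -> None:
    """BED6+ export: name = direction, score = |delta|, extra columns
    n_cpgs, mean_wt, mean_mut, area_stat."""
    with open(path, "w") as fh:
        for d in dmrs:
            fh.write(
                f"{d.chrom}\t{d.start}\t{d.end}\t{d.direction.value}\t{abs(d.delta):.3f}\t.\t"
                f"{d.n_cpgs}\t{d.mean_wt:.3f}\t{d.mean_mut:.3f}\t{d.area_stat:.3f}\n"
            )
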