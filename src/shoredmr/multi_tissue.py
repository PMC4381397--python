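"""Multi-tissue DMR integration: merging, methylation matrix, clustering,
tissue-restricted and vestigial-enhancer classification.

DMR sets called independently per tissue/stage are merged by interval union
(overlapping regions coalesce; abutting regions stay separate), a region x
sample matrix of weighted %mCG is built under the eligibility rule (>=8 CpGs
each covered >=6 reads in all samples), and rows/columns are ordered by
average-linkage (UPGMA) hierarchical clustering on Euclidean distance with
deterministic input-order tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dmr_calling import Dmr
from .intervals import Interval
from .methylome_io import MUTANT, WILDTYPE, CpGCallTable, region_weighted_methylation


@dataclass(frozen=True)
class SharedCallParams:
    min_tissue_delta: float = 5.0  # percentage points

    def __post_init__(self) -> None:
        if self.min_tissue_delta <= 0:
            raise ValueError("min_tissue_delta must be positive")


@dataclass
class MergedRegion:
    chrom: str
    start: int
    end: int
    tissues: tuple[str, ...]  # provenance: every tissue that called it
    n_source_dmrs: int

    @property
    def interval(self) -> Interval:
        return (self.start, self.end)


def merge_dmr_sets(sets: dict[str, list[Dmr]]) -> list[MergedRegion]:
    """Merge per-tissue DMR sets into unique coordinates.

    Regions sharing at least one base merge (interval union); abutting
    regions do not. Provenance records every contributing tissue; the sum of
    n_source_dmrs over the output equals the number of input DMRs.
    """
    events: list[tuple[str, int, int, str]] = []
    for tissue, dmrs in sets.items():
        for d in dmrs:
            events.append((d.chrom, d.start, d.end, tissue))
    events.sort(key=lambda r: (r[0], r[1], r[2]))
    out: list[MergedRegion] = []
    cur: list | None = None  # [chrom, start, end, tissues, count]
    for chrom, s, e, tissue in events:
        if cur is not None and chrom == cur[0] and s < cur[2]:
            cur[2] = max(cur[2], e)
            cur[3].append(tissue)
            cur[4] += 1
        else:
            if cur is not None:
                out.append(MergedRegion(cur[0], cur[1], cur[2],
                                        tuple(dict.fromkeys(cur[3])), cur[4]))
            cur = [chrom, s, e, [tissue], 1]
    if cur is not None:
        out.append(MergedRegion(cur[0], cur[1], cur[2],
                                tuple(dict.fromkeys(cur[3])), cur[4]))
    return out


def build_matrix(
    regions: list[MergedRegion],
    samples: dict[str, CpGCallTable],
    min_cpgs: int = 8,
    min_coverage: int = 6,
) -> pd.DataFrame:
    """Region x sample matrix of weighted %mCG.

    A region is eligible when it contains >= min_cpgs CpGs that each reach
    min_coverage reads in every sample; ineligible rows are dropped. Index:
    "chrom:start-end"; columns: sample labels.
    """
    names = list(samples)
    rows = []
    idx = []
    for r in regions:
        qualifying: np.ndarray | None = None
        subs = {}
        for name in names:
            sub = samples[name].restrict(r.chrom, r.start, r.end)
            subs[name] = sub
            cov = (sub["meth"] + sub["unmeth"]).to_numpy()
            ok = set(sub["pos"].to_numpy()[cov >= min_coverage])
            qualifying = ok if qualifying is None else (qualifying & ok)
        if qualifying is None or len(qualifying) < min_cpgs:
            continue
        rows.append(
            [region_weighted_methylation(samples[n], r.chrom, r.start, r.end) for n in names]
        )
        idx.append(f"{r.chrom}:{r.start}-{r.end}")
    return pd.DataFrame(rows, index=idx, columns=names)


def upgma_linkage(data: np.ndarray) -> np.ndarray:
    """Average-linkage agglomeration on Euclidean row distances.

    Returns a (n-1) x 4 merge table in the usual linkage layout (left id,
    right id, distance, cluster size) with new clusters numbered n, n+1, ...
    Ties are broken toward the pair with the lowest (first, second) original
    cluster ids, making the tree deterministic in input order.
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    if n < 2:
        raise ValueError("need at least 2 observations")
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(np.sqrt(((data[i] - data[j]) ** 2).sum()))
    active = {i: 1 for i in range(n)}  # cluster id -> size
    merges = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        best = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        (a, b), d = best
        sa, sb = active[a], active[b]
        merges[step] = (a, b, d, sa + sb)
        del active[a], active[b]
        for c in active:
            ka = (min(a, c), max(a, c))
            kb = (min(b, c), max(b, c))
            # unweighted average over all cross pairs
            dist[(c, next_id)] = (sa * dist.pop(ka) + sb * dist.pop(kb)) / (sa + sb)
        del dist[(a, b)]
        active[next_id] = sa + sb
        next_id += 1
    return merges


def leaf_order(merges: np.ndarray, n: int) -> list[int]:
    """Left-to-right leaf order of the merge tree."""
    children = {}
    for step, (a, b, _, _) in enumerate(merges):
        children[n + step] = (int(a), int(b))

    def walk(node: int) -> list[int]:
        if node < n:
            return [node]
        a, b = children[node]
        return walk(a) + walk(b)

    return walk(n + len(merges) - 1)


def hierarchical_cluster(matrix: pd.DataFrame) -> dict:
    """Cluster the region x sample matrix: UPGMA on Euclidean distance for
    rows and for columns. Rows with missing cells are dropped first.
    Returns row order, column order and both merge tables."""
    m = matrix.dropna(axis=0, how="any")
    if m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    row_merges = upgma_linkage(m.to_numpy())
    col_merges = upgma_linkage(m.to_numpy().T)
    row_ord = leaf_order(row_merges, m.shape[0])
    col_ord = leaf_order(col_merges, m.shape[1])
    return {
        "matrix": m,
        "row_order": [m.index[i] for i in row_ord],
        "col_order": [m.columns[i] for i in col_ord],
        "row_merges": row_merges,
        "col_merges": col_merges,
    }


def tissue_deltas(
    regions: list[MergedRegion],
    tissue_samples: dict[str, list[CpGCallTable]],
) -> pd.DataFrame:
    """Per-region, per-tissue methylation difference (mutant - wild-type)
    recomputed over the merged span; NaN where a tissue lacks coverage."""
    rows = []
    for r in regions:
        row: dict = {"chrom": r.chrom, "start": r.start, "end": r.end}
        for tissue, samples in tissue_samples.items():
            means = {WILDTYPE: [], MUTANT: []}
            for t in samples:
                v = region_weighted_methylation(t, r.chrom, r.start, r.end)
                if not np.isnan(v):
                    means[t.group].append(v)
            if means[WILDTYPE] and means[MUTANT]:
                row[tissue] = float(np.mean(means[MUTANT]) - np.mean(means[WILDTYPE]))
            else:
                row[tissue] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def classify_tissue_restricted(
    deltas: pd.DataFrame,
    tissues: list[str],
    params: SharedCallParams = SharedCallParams(),
) -> pd.DataFrame:
    """Flag each region 'not a DMR in tissue T' where |delta_T| is strictly
    below min_tissue_delta; regions with missing data in a tissue are
    excluded from that tissue's evaluation (flag False, noted)."""
    out = deltas.copy()
    flagged_any = np.zeros(len(out), dtype=bool)
    for t in tissues:
        vals = out[t].to_numpy(dtype=float)
        flag = np.abs(vals) < params.min_tissue_delta
        flag[np.isnan(vals)] = False
        out[f"not_dmr_in_{t}"] = flag
        out[f"missing_in_{t}"] = np.isnan(vals)
        flagged_any |= flag
    out["restricted"] = flagged_any
    return out


VESTIGIAL_MARKS_FOCAL = ("H3K4me1", "H3K27ac", "H3K4me3")


def vestigial_classification(
    enrichment: pd.DataFrame, focal_tissue: str, tissues: list[str]
) -> pd.Series:
    """Classify focal-tissue DMRs by histone-mark evidence.

    `enrichment` columns are named "<tissue>:<mark>" holding booleans.
    marked_in_focal: any of H3K4me1/H3K27ac/H3K4me3 enriched in the focal
    tissue; marked_elsewhere_only: H3K4me1 enriched in another tissue;
    unmarked_everywhere otherwise. The three classes partition the set.
    """
    focal_cols = [
        f"{focal_tissue}:{m}" for m in VESTIGIAL_MARKS_FOCAL
        if f"{focal_tissue}:{m}" in enrichment.columns
    ]
    other_cols = [
        f"{t}:H3K4me1" for t in tissues
        if t != focal_tissue and f"{t}:H3K4me1" in enrichment.columns
    ]
    focal = enrichment[focal_cols].any(axis=1) if focal_cols else pd.Series(False, index=enrichment.index)
    elsewhere = enrichment[other_cols].any(axis=1) if other_cols else pd.Series(False, index=enrichment.index)
    out = pd.Series("unmarked_everywhere", index=enrichment.index, dtype=object)
    out[elsewhere] = "marked_elsewhere_only"
    out[focal] = "marked_in_focal"
    return out
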