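"""Annotation of DMRs against transcript models, TSS windows and CpG islands.

Feature classification follows a precedence ranking so that a point hitting
several features is assigned exactly one class:

    TSS_PROXIMAL > SINGLE_EXON > THREE_PRIME_EXON_UTR > INTERNAL_EXON
    > INTRON > INTERGENIC

The classified point is the central CpG of each region; genic/intergenic
and CGI-overlap summaries use whole-interval intersection instead. The
"expected" genome-wide distribution assigns every base pair to the
highest-ranked feature covering it, giving the background against which the
observed class counts are compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .dmr_calling import Dmr
from .genome import GenomeLayout
from .intervals import (
    Interval,
    merge_union,
    point_to_interval_distance,
    subtract,
    total_bp,
)
from .methylome_io import CpGCallTable, region_weighted_methylation


class FeatureClass(IntEnum):
    """Ordered by precedence: higher value wins."""

    INTERGENIC = 0
    INTRON = 1
    INTERNAL_EXON = 2
    THREE_PRIME_EXON_UTR = 3
    SINGLE_EXON = 4
    TSS_PROXIMAL = 5


@dataclass(frozen=True)
class Transcript:
    id: str
    gene: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[Interval, ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        ex = list(self.exons)
        if ex != sorted(ex):
            raise ValueError("exons must be sorted")
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if e1 > s2:
                raise ValueError("exons overlap")
        if ex and (ex[0][0] < self.start or ex[-1][1] > self.end):
            raise ValueError("exons outside transcript span")

    @property
    def tss(self) -> int:
        """Transcription start site as a point: span start on +, last base on -."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def is_single_exon(self) -> bool:
        return len(self.exons) <= 1

    @property
    def last_exon(self) -> Interval:
        """Strand-aware 3'-most exon."""
        return self.exons[-1] if self.strand == "+" else self.exons[0]

    @property
    def introns(self) -> list[Interval]:
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]) if s2 > e1
        ]


@dataclass
class TranscriptSet:
    transcripts: list[Transcript] = field(default_factory=list)

    def __iter__(self):
        return iter(self.transcripts)

    def __len__(self) -> int:
        return len(self.transcripts)


@dataclass(frozen=True)
class AnnotationParams:
    tss_window: int = 2_500
    shore_window: int = 5_000
    flank_for_profiles: int = 2_000

    def __post_init__(self) -> None:
        if min(self.tss_window, self.shore_window, self.flank_for_profiles) <= 0:
            raise ValueError("annotation windows must be positive")


def read_bed12(path: str | Path) -> TranscriptSet:
    """Read transcript models from BED12 (0-based half-open)."""
    txs = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5] if len(f) > 5 else "+"
            if len(f) >= 12:
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                starts = [int(x) for x in f[11].rstrip(",").split(",")]
                exons = tuple((start + s, start + s + sz) for s, sz in zip(starts, sizes))
            else:
                exons = ((start, end),)
            gene = name.rsplit(".", 1)[0]
            txs.append(Transcript(name, gene, chrom, strand, start, end, exons))
    return TranscriptSet(txs)


def central_cpg(cpg_positions: np.ndarray | list[int]) -> int:
    """The region's central CpG: middle of the sorted positions, lower of
    the two middles for an even count."""
    pos = sorted(int(p) for p in cpg_positions)
    if not pos:
        raise ValueError("region has no CpGs")
    return pos[(len(pos) - 1) // 2]


def _class_intervals_per_transcript(
    tx: Transcript, params: AnnotationParams
) -> list[tuple[FeatureClass, Interval]]:
    out = [(FeatureClass.TSS_PROXIMAL, (tx.tss - params.tss_window, tx.tss + params.tss_window + 1))]
    if tx.is_single_exon:
        out.append((FeatureClass.SINGLE_EXON, (tx.start, tx.end)))
        return out
    last = tx.last_exon
    out.append((FeatureClass.THREE_PRIME_EXON_UTR, last))
    for ex in tx.exons:
        if ex != last:
            out.append((FeatureClass.INTERNAL_EXON, ex))
    for iv in tx.introns:
        out.append((FeatureClass.INTRON, iv))
    return out


class FeatureIndex:
    """Interval-tree index of feature-class intervals for point queries."""

    def __init__(self, transcripts: TranscriptSet, params: AnnotationParams):
        self.params = params
        self._trees: dict[str, IntervalTree] = {}
        for tx in transcripts:
            tree = self._trees.setdefault(tx.chrom, IntervalTree())
            for cls, (s, e) in _class_intervals_per_transcript(tx, params):
                if e > s:
                    tree.addi(s, e, cls)

    def classify(self, chrom: str, point: int) -> FeatureClass:
        tree = self._trees.get(chrom)
        if tree is None:
            return FeatureClass.INTERGENIC
        hits = tree[point]
        if not hits:
            return FeatureClass.INTERGENIC
        return max(iv.data for iv in hits)


def classify_feature(
    chrom: str,
    point: int,
    transcripts: TranscriptSet | FeatureIndex,
    params: AnnotationParams | None = None,
) -> FeatureClass:
    """Classify a point against all transcripts under the precedence ranking."""
    if isinstance(transcripts, FeatureIndex):
        return transcripts.classify(chrom, point)
    assert params is not None
    return FeatureIndex(transcripts, params).classify(chrom, point)


def expected_feature_distribution(
    transcripts: TranscriptSet, layout: GenomeLayout, params: AnnotationParams
) -> dict[FeatureClass, int]:
    """Base pairs per feature class, assigning each bp to its highest-ranked
    covering feature: bp(class) = |union(class) - union(higher-ranked)|.
    The classes partition the genome (INTERGENIC absorbs the rest)."""
    per_chrom: dict[str, dict[FeatureClass, list[Interval]]] = {}
    for tx in transcripts:
        d = per_chrom.setdefault(tx.chrom, {})
        for cls, iv in _class_intervals_per_transcript(tx, params):
            d.setdefault(cls, []).append(iv)
    ranked = sorted(
        [c for c in FeatureClass if c != FeatureClass.INTERGENIC], reverse=True
    )
    out = {c: 0 for c in FeatureClass}
    covered_total = 0
    for chrom, d in per_chrom.items():
        length = layout.chrom_length(chrom) if chrom in layout else None
        clip = (lambda ivs: [(max(0, s), min(length, e)) for s, e in ivs if min(length, e) > max(0, s)]) if length is not None else (lambda ivs: ivs)
        higher: list[Interval] = []
        for cls in ranked:
            ivs = merge_union(clip(d.get(cls, [])))
            own = subtract(ivs, higher)
            out[cls] += total_bp(own)
            higher = merge_union(higher + ivs)
        covered_total += total_bp(higher)
    out[FeatureClass.INTERGENIC] = layout.total_length(include_controls=False) - covered_total
    return out


def overlap_summary(
    dmrs: list[Dmr],
    transcripts: TranscriptSet,
    cgis: list[tuple[str, int, int]],
    params: AnnotationParams,
) -> dict:
    """Interval-level summary: genic vs intergenic (partitioning the set),
    TSS-proximal (nearest TSS within tss_window of the region) and
    CGI-overlapping counts."""
    spans: dict[str, list[Interval]] = {}
    tss_points: dict[str, list[int]] = {}
    for tx in transcripts:
        spans.setdefault(tx.chrom, []).append((tx.start, tx.end))
        tss_points.setdefault(tx.chrom, []).append(tx.tss)
    cgi_by_chrom: dict[str, list[Interval]] = {}
    for chrom, s, e in cgis:
        cgi_by_chrom.setdefault(chrom, []).append((s, e))
    genic = tss_prox = cgi_overlap = 0
    for d in dmrs:
        iv = (d.start, d.end)
        if any(s < iv[1] and iv[0] < e for s, e in spans.get(d.chrom, [])):
            genic += 1
        if any(
            point_to_interval_distance(t, iv) <= params.tss_window
            for t in tss_points.get(d.chrom, [])
        ):
            tss_prox += 1
        if any(s < iv[1] and iv[0] < e for s, e in cgi_by_chrom.get(d.chrom, [])):
            cgi_overlap += 1
    return {
        "n_total": len(dmrs),
        "n_genic": genic,
        "n_intergenic": len(dmrs) - genic,
        "n_tss_proximal": tss_prox,
        "n_cgi_overlapping": cgi_overlap,
    }


def shore_profile(
    dmrs: list[Dmr],
    cgis: list[tuple[str, int, int]],
    table: CpGCallTable,
    params: AnnotationParams,
) -> pd.DataFrame:
    """Per-DMR offset from the nearest CpG-island centre, for DMRs whose
    centre lies within shore_window of a CGI centre, with the island's
    weighted %mCG (for sorting the shore plot). Ties between equidistant
    islands go to the lower coordinate."""
    cgi_by_chrom: dict[str, list[tuple[str, int, int]]] = {}
    for cgi in sorted(cgis):
        cgi_by_chrom.setdefault(cgi[0], []).append(cgi)
    rows = []
    for d in dmrs:
        cands = cgi_by_chrom.get(d.chrom, [])
        if not cands:
            continue
        centre = (d.start + d.end) // 2
        best = min(cands, key=lambda c: (abs(centre - (c[1] + c[2]) // 2), c[1]))
        offset = centre - (best[1] + best[2]) // 2
        if abs(offset) > params.shore_window:
            continue
        rows.append(
            {
                "chrom": d.chrom,
                "dmr_start": d.start,
                "dmr_end": d.end,
                "offset": offset,
                "cgi_start": best[1],
                "cgi_end": best[2],
                "cgi_pct_mcg": region_weighted_methylation(table, best[0], best[1], best[2]),
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "dmr_start", "dmr_end", "offset",
                                       "cgi_start", "cgi_end", "cgi_pct_mcg"])


@dataclass
class ScoreTrack:
    """Fixed-step score track (e.g. conservation or %mCG), one value per
    step-sized window; NaN marks missing data."""

    step: int
    values: dict[str, np.ndarray]

    def slice_centred(self, chrom: str, centre: int, flank: int) -> np.ndarray:
        n = 2 * (flank // self.step) + 1
        arr = self.values.get(chrom)
        out = np.full(n, np.nan)
        if arr is None:
            return out
        c_bin = centre // self.step
        for k in range(n):
            b = c_bin + k - n // 2
            if 0 <= b < len(arr):
                out[k] = arr[b]
        return out


def mean_profile_over_regions(
    track: ScoreTrack, regions: list[tuple[str, int, int]], flank: int
) -> np.ndarray:
    """Average track profile across regions aligned on their centres;
    missing data is excluded from each offset's mean, not zero-filled."""
    if not regions:
        raise ValueError("no regions")
    slices = [
        track.slice_centred(chrom, (s + e) // 2, flank) for chrom, s, e in regions
    ]
    stack = np.vstack(slices)
    counts = (~np.isnan(stack)).sum(axis=0)
    sums = np.nansum(stack, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(counts > 0, sums / counts, np.nan)


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out


def write_bed(intervals: list[tuple[str, int, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e in intervals:
            fh.write(f"{chrom}\t{s}\t{e}\n")
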