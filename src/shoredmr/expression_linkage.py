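"""Linking differential expression to nearby methylation and H3K4me1 changes.

Differential-expression results (precomputed fold changes and adjusted
p-values) are annotated with whether a DMR and/or a changed H3K4me1 peak
lies within a window of the gene's TSS (50 kb by default, edge-to-point,
inclusive), and significant genes are partitioned into up/down strata at a
ladder of fold-change cut-offs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import point_to_interval_distance

DE_COLUMNS = ["gene", "chrom", "tss", "strand", "fold_change", "adjusted_p"]


@dataclass(frozen=True)
class LinkageParams:
    tss_link_window: int = 50_000
    fold_change_cuts: tuple[float, ...] = (1.0, 1.5)
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.tss_link_window <= 0:
            raise ValueError("window must be positive")
        if list(self.fold_change_cuts) != sorted(self.fold_change_cuts):
            raise ValueError("fold_change_cuts must be increasing")


def read_de_table(path: str | Path, alpha: float = 0.05) -> pd.DataFrame:
    """Read a DE TSV with columns gene, chrom, tss, strand, fold_change
    (linear mutant/wild-type), adjusted_p; adds the significance flag."""
    df = pd.read_csv(path, sep="\t")
    missing = set(DE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"DE table missing columns {sorted(missing)}")
    if (df["fold_change"] <= 0).any():
        raise ValueError("fold_change must be positive (linear scale)")
    df["significant"] = df["adjusted_p"] < alpha
    return df


def link_genes(
    genes: pd.DataFrame,
    dmrs: list[tuple[str, int, int]],
    changed_peaks: list[tuple[str, int, int]],
    params: LinkageParams = LinkageParams(),
) -> pd.DataFrame:
    """Flag genes with a DMR / changed peak whose nearest edge is within
    tss_link_window of the TSS point (inclusive). Genes with a missing TSS
    are excluded and counted in the 'n_excluded' frame attribute."""
    by_chrom_dmr: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in dmrs:
        by_chrom_dmr.setdefault(chrom, []).append((s, e))
    by_chrom_peak: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in changed_peaks:
        by_chrom_peak.setdefault(chrom, []).append((s, e))

    valid = genes["tss"].notna()
    out = genes[valid].copy()

    def _near(chrom: str, tss: int, table: dict) -> bool:
        return any(
            point_to_interval_distance(int(tss), iv) <= params.tss_link_window
            for iv in table.get(chrom, [])
        )

    out["has_dmr"] = [
        _near(c, t, by_chrom_dmr) for c, t in zip(out["chrom"], out["tss"])
    ]
    out["has_k4me1_change"] = [
        _near(c, t, by_chrom_peak) for c, t in zip(out["chrom"], out["tss"])
    ]
    out["both"] = out["has_dmr"] & out["has_k4me1_change"]
    out.attrs["n_excluded"] = int((~valid).sum())
    return out


def partition_by_fold_change(
    genes: pd.DataFrame, params: LinkageParams = LinkageParams()
) -> pd.DataFrame:
    """Counts of significantly up/down genes per fold-change cut-off,
    overall and within the epigenetic-change flags.

    up = fold_change > cut, down = fold_change < 1/cut (both strict), so
    counts are non-increasing as the cut grows.
    """
    sig = genes[genes["significant"]] if "significant" in genes else genes
    rows = []
    for cut in params.fold_change_cuts:
        up = sig["fold_change"] > cut
        down = sig["fold_change"] < 1.0 / cut
        row = {"cut": cut, "n_up": int(up.sum()), "n_down": int(down.sum())}
        for flag in ("has_dmr", "has_k4me1_change", "both"):
            if flag in sig:
                row[f"n_up_{flag}"] = int((up & sig[flag]).sum())
                row[f"n_down_{flag}"] = int((down & sig[flag]).sum())
        rows.append(row)
    return pd.DataFrame(rows)
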