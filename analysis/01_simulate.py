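#!/usr/bin/env python
"""Generate the synthetic study: 2v2 methylomes (30x) over 10 Mb with ~1-kb
lowly methylated elements, half of them gaining (94%) or losing (6%) 30
points of CpG methylation in mutants, plus annotation, ChIP libraries and a
DE table. Writes everything under results/simulated/."""

from pathlib import Path

import pandas as pd

from shoredmr.chip_enrichment import write_fragment_bed
from shoredmr.feature_annotation import write_bed
from shoredmr.methylome_io import summarize_sample
from shoredmr.synthetic_data import (
    SimulationConfig,
    simulate_chip,
    simulate_de_table,
    simulate_layout_and_annotation,
    simulate_methylomes,
    write_cytosine_report,
    write_truth_table,
)

OUT = Path(__file__).resolve().parents[1] / "results"
RAW = Path(__file__).resolve().parents[1] / "scratch" / "simulated"
SEED = 11


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    RAW.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(seed=SEED, n_chroms=2, chrom_length=5_000_000)
    ann = simulate_layout_and_annotation(cfg)
    tables, truth = simulate_methylomes(cfg, ann)

    write_bed(ann.cgis, OUT / "cgi.bed")
    ann.elements.to_csv(OUT / "elements.tsv", sep="\t", index=False)

    summaries = []
    for t in tables:
        # raw per-CpG exports are bulky; they go to scratch/, summaries to results/
        write_cytosine_report(t, RAW / f"{t.sample_id}.cytosine_report.tsv", seed=SEED)
        summaries.append(summarize_sample(t))
    pd.DataFrame(summaries).to_csv(OUT / "sample_summary.tsv", sep="\t", index=False)

    chip = simulate_chip(cfg, ann, truth, ("liver_e14",))
    for tissue, libs in chip.items():
        for i, f in enumerate(libs["chip"], 1):
            write_fragment_bed(f, RAW / f"{tissue}_H3K4me1_rep{i}.bed")
        write_fragment_bed(libs["input"], RAW / f"{tissue}_input.bed")

    de, truth = simulate_de_table(cfg, ann, truth)
    de.to_csv(OUT / "de_table.tsv", sep="\t", index=False)
    write_truth_table(truth, OUT / "truth.tsv")

    print(f"simulated {len(tables)} methylomes over {cfg.n_chroms * cfg.chrom_length / 1e6:.0f} Mb")
    print(f"planted elements: {len(truth)}, of which DMRs: {int(truth['is_dmr'].sum())}")
    print(pd.DataFrame(summaries).to_string(index=False))


if __name__ == "__main__":
    main()
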