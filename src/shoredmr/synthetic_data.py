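"""Synthetic study generator: genomes, annotations, replicated methylomes
with planted DMRs, ChIP fragments with planted enrichment, and DE tables.

The generator emulates the study design the pipeline targets: two wild-type
vs two mutant whole-genome bisulphite methylomes in which ~1-kb regulatory
elements sit at low methylation inside a highly methylated genome, a subset
of elements gains (mostly) or loses methylation in the mutant group, CpG
islands are CpG-dense and unmethylated, an unmethylated spike-in contig
measures bisulphite conversion, and a transgene contig carries one
hypermethylating element. ChIP libraries place extra fragments at
histone-marked elements; a DE table links expression loss to elements whose
enhancer mark is attenuated in mutants.

Every generator is a pure function of (seed, config); the TruthTable records
every planted effect so recovery can be scored without hidden state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chip_enrichment import FragmentSet
from .genome import Contig, GenomeLayout
from .feature_annotation import Transcript, TranscriptSet
from .methylome_io import MUTANT, WILDTYPE, CpGCallTable


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 5_000_000
    include_spike_in: bool = True
    include_transgene: bool = True
    spike_in_length: int = 48_502  # lambda-phage-sized control
    transgene_length: int = 5_000

    # CpG landscape
    cpg_density: float = 0.01  # background CpGs per bp
    cgi_cpg_density: float = 0.08
    cgis_per_mb: float = 5.0
    cgi_length: int = 800

    # methylation levels (proportions)
    baseline_meth: float = 0.78
    cgi_meth: float = 0.05
    element_meth: float = 0.30

    # planted regulatory elements
    elements_per_mb: float = 10.0
    element_length: int = 1_000
    cpgs_per_element: int = 15
    planted_dmr_fraction: float = 0.5
    planted_delta: float = 30.0  # percentage points
    planted_fraction_hyper: float = 0.94
    shore_fraction: float = 0.2  # elements placed at a CGI edge

    # sequencing model
    coverage_mean: float = 30.0
    dispersion: float = 0.02  # beta-binomial intraclass correlation
    conversion_error: float = 0.003

    # genes / expression (mammalian-like gene density)
    genes_per_mb: float = 8.0
    de_effect_fold: float = 0.5  # expression fold at linked genes
    de_null_sd: float = 0.10  # sd of log2 fold under the null

    # ChIP model; density sized so a fold-3 1-kb element clears the 2-fold
    # cut-off with >0.95 per-replicate probability (Poisson ratio, normal
    # approximation: sd(log ratio) ~ sqrt(1/(900 d)) must beat log(3/2))
    chip_read_density: float = 0.04  # reads per bp per library
    chip_enrichment_fold: float = 3.0
    chip_fragment_length: int = 200
    marked_fraction_focal: float = 0.3
    active_fraction: float = 0.5  # of focal-marked: also H3K27ac
    marked_fraction_other: float = 0.4  # of focal-unmarked: H3K4me1 elsewhere
    mutant_k4me1_retention: float = 0.3  # residual enrichment at DMR elements

    def __post_init__(self) -> None:
        for name in ("baseline_meth", "cgi_meth", "element_meth",
                     "planted_fraction_hyper", "planted_dmr_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        if self.cpg_density <= 0 or self.coverage_mean <= 0:
            raise ValueError("rates must be positive")


@dataclass
class Annotation:
    layout: GenomeLayout
    transcripts: TranscriptSet
    cgis: list[tuple[str, int, int]]
    elements: pd.DataFrame  # chrom, start, end, in_gene, at_shore


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), stream])


def simulate_layout_and_annotation(config: SimulationConfig) -> Annotation:
    """Deterministically place genes, CpG islands and regulatory elements.

    Genes occupy alternating blocks so they never overlap; CGIs sit at a
    share of TSSs plus intergenic spots; elements are placed one per slot
    with a fraction at CGI edges (shores) and the rest at random, so some
    fall inside exons/introns and some are intergenic.
    """
    rng = _rng(config, 0)
    contigs = [Contig(f"chr{i + 1}", config.chrom_length) for i in range(config.n_chroms)]
    if config.include_spike_in:
        contigs.append(Contig("spikein_lambda", config.spike_in_length, is_spike_in=True))
    if config.include_transgene:
        contigs.append(Contig("transgene_gfp", config.transgene_length, is_transgene=True))
    layout = GenomeLayout(contigs)

    mb = config.chrom_length / 1e6
    n_genes = int(round(config.genes_per_mb * mb))
    n_cgis = int(round(config.cgis_per_mb * mb))
    n_elements = int(round(config.elements_per_mb * mb))
    slot = config.chrom_length // max(n_elements, 1)
    if slot < 4 * config.element_length:
        raise ValueError("too many elements for the chromosome length")

    txs: list[Transcript] = []
    cgis: list[tuple[str, int, int]] = []
    element_rows = []
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        # genes in alternating blocks
        block = config.chrom_length // max(n_genes, 1)
        for g in range(n_genes):
            b0 = g * block
            span = int(rng.integers(10_000, min(60_000, block - 5_000)))
            start = int(rng.integers(b0 + 1_000, b0 + block - span - 1_000))
            strand = "+" if rng.random() < 0.5 else "-"
            n_ex = int(rng.integers(1, 9))
            if n_ex == 1:
                exons = ((start, start + span),)
            else:
                cuts = np.sort(rng.choice(np.arange(1, 2 * n_ex), size=2 * n_ex - 2, replace=False))
                edges = np.concatenate([[0], cuts, [2 * n_ex]]) / (2 * n_ex)
                coords = (start + edges * span).astype(int)
                exons = tuple(
                    (int(coords[2 * k]), int(coords[2 * k + 1]))
                    for k in range(n_ex)
                    if coords[2 * k + 1] > coords[2 * k]
                )
            name = f"{chrom}_g{g}"
            txs.append(Transcript(name, name, chrom, strand, start, start + span, exons))
        # CGIs: 60% at TSSs, rest random
        chrom_txs = [t for t in txs if t.chrom == chrom]
        k_tss = min(len(chrom_txs), int(0.6 * n_cgis))
        for t in rng.permutation(len(chrom_txs))[:k_tss]:
            tss = chrom_txs[t].tss
            s = max(0, tss - config.cgi_length // 2)
            cgis.append((chrom, s, s + config.cgi_length))
        for _ in range(n_cgis - k_tss):
            s = int(rng.integers(0, config.chrom_length - config.cgi_length))
            cgis.append((chrom, s, s + config.cgi_length))
        # elements: one per slot
        chrom_cgis = [c for c in cgis if c[0] == chrom]
        for e in range(n_elements):
            at_shore = bool(rng.random() < config.shore_fraction) and chrom_cgis
            if at_shore:
                cg = chrom_cgis[int(rng.integers(0, len(chrom_cgis)))]
                start = cg[2] + 200 if rng.random() < 0.5 else cg[1] - 200 - config.element_length
                start = int(np.clip(start, 0, config.chrom_length - config.element_length))
            else:
                lo = e * slot + slot // 4
                start = int(rng.integers(lo, lo + slot // 2))
            end = start + config.element_length
            in_gene = any(t.start < end and start < t.end for t in chrom_txs)
            element_rows.append(
                {"chrom": chrom, "start": start, "end": end,
                 "in_gene": in_gene, "at_shore": bool(at_shore)}
            )
    elements = pd.DataFrame(element_rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    # drop elements overlapping a previously placed one (shore placement may collide)
    keep = []
    last_end: dict[str, int] = {}
    for row in elements.itertuples(index=True):
        if row.start >= last_end.get(row.chrom, -1):
            keep.append(row.Index)
            last_end[row.chrom] = row.end
    elements = elements.loc[keep].reset_index(drop=True)
    cgis = sorted(set(cgis))
    return Annotation(layout, TranscriptSet(txs), cgis, elements)


def _cpg_positions(config: SimulationConfig, annotation: Annotation,
                   rng: np.random.Generator) -> dict[str, np.ndarray]:
    """CpG coordinates: geometric background, denser inside CGIs, a fixed
    evenly spaced complement inside each element."""
    out: dict[str, np.ndarray] = {}
    for contig in annotation.layout.contigs:
        chrom, length = contig.name, contig.length
        n_bg = rng.poisson(config.cpg_density * length)
        pos = set(rng.integers(0, length - 2, size=n_bg).tolist())
        if not (contig.is_spike_in or contig.is_transgene):
            for c, s, e in annotation.cgis:
                if c != chrom:
                    continue
                extra = rng.poisson((config.cgi_cpg_density - config.cpg_density) * (e - s))
                pos.update(rng.integers(s, e - 1, size=extra).tolist())
            for row in annotation.elements.itertuples(index=False):
                if row.chrom != chrom:
                    continue
                step = config.element_length // (config.cpgs_per_element + 1)
                pos.update(row.start + step * (k + 1) for k in range(config.cpgs_per_element))
        arr = np.sort(np.fromiter(pos, dtype=np.int64))
        # CpGs occupy two bases; enforce min distance 2
        if len(arr) > 1:
            keep = np.concatenate([[True], np.diff(arr) >= 2])
            arr = arr[keep]
        out[chrom] = arr
    return out


def _truth_table(config: SimulationConfig, annotation: Annotation,
                 rng: np.random.Generator,
                 tissue_labels: tuple[str, ...]) -> pd.DataFrame:
    el = annotation.elements
    n = len(el)
    is_dmr = rng.random(n) < config.planted_dmr_fraction
    hyper = rng.random(n) < config.planted_fraction_hyper
    truth = el.copy()
    truth["is_dmr"] = is_dmr
    truth["direction"] = np.where(hyper, "hyper_in_mutant", "hypo_in_mutant")
    truth["delta"] = np.where(is_dmr, np.where(hyper, config.planted_delta,
                                               -config.planted_delta), 0.0)
    focal = tissue_labels[0]
    marked_focal = rng.random(n) < config.marked_fraction_focal
    active = marked_focal & (rng.random(n) < config.active_fraction)
    truth[f"{focal}:H3K4me1"] = marked_focal
    truth[f"{focal}:H3K27ac"] = active
    truth[f"{focal}:H3K4me3"] = np.zeros(n, dtype=bool)
    for other in tissue_labels[1:]:
        truth[f"{other}:H3K4me1"] = ~marked_focal & (rng.random(n) < config.marked_fraction_other)
        truth[f"{other}:H3K27ac"] = np.zeros(n, dtype=bool)
        truth[f"{other}:H3K4me3"] = np.zeros(n, dtype=bool)
    return truth


def _true_methylation(config: SimulationConfig, annotation: Annotation,
                      truth: pd.DataFrame, positions: dict[str, np.ndarray],
                      mutant: bool) -> dict[str, np.ndarray]:
    """Per-CpG true methylation proportion for one genotype."""
    out = {}
    delta = config.planted_delta / 100.0
    for contig in annotation.layout.contigs:
        chrom = contig.name
        pos = positions[chrom]
        if contig.is_spike_in:
            out[chrom] = np.zeros(len(pos))
            continue
        p = np.full(len(pos), config.baseline_meth)
        if contig.is_transgene:
            # single planted element spanning the transgene, hyper in mutants
            p[:] = config.element_meth + (delta if mutant else 0.0)
            out[chrom] = np.clip(p, 0.0, 1.0)
            continue
        for c, s, e in annotation.cgis:
            if c == chrom:
                p[(pos >= s) & (pos < e)] = config.cgi_meth
        for row in truth.itertuples(index=False):
            if row.chrom != chrom:
                continue
            m = (pos >= row.start) & (pos < row.end)
            if row.direction == "hyper_in_mutant" or not row.is_dmr:
                base = config.element_meth
                p[m] = base + (delta if (mutant and row.is_dmr) else 0.0)
            else:  # hypo: ordinary methylation lost in mutants
                p[m] = config.baseline_meth - (delta if mutant else 0.0)
        out[chrom] = np.clip(p, 0.0, 1.0)
    return out


def _draw_counts(p_true: np.ndarray, config: SimulationConfig,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    cov = rng.poisson(config.coverage_mean, size=len(p_true))
    # conversion failure reads an unmethylated C as methylated
    p_obs = p_true + (1.0 - p_true) * config.conversion_error
    rho = config.dispersion
    if rho > 0:
        conc = (1.0 - rho) / rho
        a = np.maximum(p_obs * conc, 1e-9)
        b = np.maximum((1.0 - p_obs) * conc, 1e-9)
        p_rep = rng.beta(a, b)
    else:
        p_rep = p_obs
    meth = rng.binomial(cov, p_rep)
    return meth, cov - meth


def simulate_methylomes(
    config: SimulationConfig,
    annotation: Annotation,
    n_reps_per_group: int = 2,
    tissue_labels: tuple[str, ...] = ("liver_e14", "brain_e14", "heart_e14"),
) -> tuple[list[CpGCallTable], pd.DataFrame]:
    """Replicated methylomes plus the TruthTable of planted effects."""
    rng = _rng(config, 1)
    positions = _cpg_positions(config, annotation, rng)
    truth = _truth_table(config, annotation, rng, tissue_labels)
    tables = []
    for group, mutant in ((WILDTYPE, False), (MUTANT, True)):
        p_by_chrom = _true_methylation(config, annotation, truth, positions, mutant)
        for rep in range(n_reps_per_group):
            frames = []
            for chrom in annotation.layout.names:
                meth, unmeth = _draw_counts(p_by_chrom[chrom], config, rng)
                frames.append(pd.DataFrame({
                    "chrom": chrom, "pos": positions[chrom],
                    "meth": meth, "unmeth": unmeth,
                }))
            tables.append(CpGCallTable(
                sample_id=f"{group}_{rep + 1}", group=group,
                df=pd.concat(frames, ignore_index=True), layout=annotation.layout,
            ))
    return tables, truth


def simulate_chip(
    config: SimulationConfig,
    annotation: Annotation,
    truth: pd.DataFrame,
    tissue_labels: tuple[str, ...] = ("liver_e14",),
    mark: str = "H3K4me1",
    genotype: str = WILDTYPE,
    stream: int = 2,
) -> dict[str, dict[str, list[FragmentSet] | FragmentSet]]:
    """ChIP fragment sets (2 ChIP replicates + input) per tissue.

    Background reads are uniform; elements marked for (tissue, mark) emit
    chip_enrichment_fold x background in the ChIP libraries. In mutant
    libraries the enrichment at planted-DMR elements is attenuated to
    mutant_k4me1_retention of its excess, emulating enhancer-mark loss.
    """
    rng = _rng(config, stream)
    chroms = [c for c in annotation.layout.contigs if not c.is_spike_in]
    total_len = sum(c.length for c in chroms)
    n_reads = int(config.chip_read_density * total_len)
    out: dict[str, dict] = {}
    for tissue in tissue_labels:
        col = f"{tissue}:{mark}"
        marked = truth[truth.get(col, pd.Series(False, index=truth.index))] \
            if col in truth.columns else truth.iloc[0:0]

        def _library(enriched: bool) -> FragmentSet:
            rows = []
            # background
            offs = rng.integers(0, total_len, size=n_reads)
            bounds = np.cumsum([0] + [c.length for c in chroms])
            idx = np.searchsorted(bounds, offs, side="right") - 1
            for k, c in enumerate(chroms):
                sel = offs[idx == k] - bounds[k]
                for p in sel:
                    rows.append((c.name, int(p), "+" if rng.random() < 0.5 else "-"))
            if enriched:
                dens = config.chip_read_density
                flen = config.chip_fragment_length
                for row in marked.itertuples(index=False):
                    fold = config.chip_enrichment_fold
                    if genotype == MUTANT and row.is_dmr:
                        fold = 1.0 + (fold - 1.0) * config.mutant_k4me1_retention
                    # plant extra fragments over the full overlap footprint
                    # (element + fragment length) so the realized coverage
                    # ratio over the element equals the nominal fold
                    span = row.end - row.start + flen - 1
                    extra = rng.poisson(dens * (fold - 1.0) * span)
                    for _ in range(extra):
                        if rng.random() < 0.5:
                            p = int(rng.integers(row.start - flen + 1, row.end))
                            rows.append((row.chrom, max(0, p), "+"))
                        else:
                            p = int(rng.integers(row.start, row.end + flen - 1))
                            rows.append((row.chrom, p, "-"))
            df = pd.DataFrame(rows, columns=["chrom", "pos", "strand"])
            df = df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
            return FragmentSet(df, fragment_length=config.chip_fragment_length)

        out[tissue] = {
            "chip": [_library(True), _library(True)],
            "input": _library(False),
        }
    return out


def simulate_de_table(
    config: SimulationConfig,
    annotation: Annotation,
    truth: pd.DataFrame,
    link_window: int = 50_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """DE table with planted down-regulation at genes linked to attenuated
    elements (DMR + focal H3K4me1); returns (de_table, truth with links)."""
    rng = _rng(config, 3)
    focal_mark = next((c for c in truth.columns if c.endswith(":H3K4me1")), None)
    attenuated = truth["is_dmr"] & (truth[focal_mark] if focal_mark else False)
    genes = list(annotation.transcripts)
    linked_genes: dict[str, float] = {}
    links = []
    for row in truth[attenuated].itertuples(index=True):
        best, best_d = None, link_window + 1
        for t in genes:
            if t.chrom != row.chrom:
                continue
            d = min(abs(t.tss - row.start), abs(t.tss - (row.end - 1)))
            if row.start <= t.tss < row.end:
                d = 0
            if d < best_d:
                best, best_d = t, d
        if best is not None:
            linked_genes[best.id] = -1.0
            links.append((row.Index, best.id))
    truth = truth.copy()
    truth["linked_gene"] = ""
    truth["expression_sign"] = 0
    for idx, gid in links:
        truth.loc[idx, "linked_gene"] = gid
        truth.loc[idx, "expression_sign"] = -1
    rows = []
    for t in genes:
        if t.id in linked_genes:
            fold = config.de_effect_fold * float(np.exp(rng.normal(0.0, 0.15)))
            padj = float(10 ** rng.uniform(-8, -3))
        else:
            fold = float(2.0 ** rng.normal(0.0, config.de_null_sd))
            padj = float(rng.uniform(0.0, 1.0))
        rows.append({"gene": t.id, "chrom": t.chrom, "tss": t.tss, "strand": t.strand,
                     "fold_change": fold, "adjusted_p": padj})
    de = pd.DataFrame(rows)
    de["significant"] = de["adjusted_p"] < 0.05
    return de, truth


def write_cytosine_report(table: CpGCallTable, path: str | Path, seed: int = 0) -> None:
    """Write a merged table back out as a stranded 1-based cytosine report,
    splitting each CpG's counts between the two strands reproducibly. The
    read-and-merge round trip recovers the table exactly."""
    rng = np.random.default_rng(seed % (2**31))
    with open(path, "w") as fh:
        for chrom, pos, meth, unmeth in table.df.itertuples(index=False):
            mp = int(rng.binomial(meth, 0.5))
            up = int(rng.binomial(unmeth, 0.5))
            fh.write(f"{chrom}\t{pos + 1}\t+\t{mp}\t{up}\tCG\n")
            fh.write(f"{chrom}\t{pos + 2}\t-\t{meth - mp}\t{unmeth - up}\tCG\n")


def write_truth_table(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def score_recovery(dmrs, truth: pd.DataFrame, layout: GenomeLayout) -> dict:
    """Sensitivity and precision of called DMRs against planted truth.

    Sensitivity: fraction of planted DMR elements overlapped by a call.
    Precision: fraction of calls on ordinary chromosomes overlapping a
    planted DMR element (control contigs are excluded from both sides; the
    transgene's planted gain is assessed separately as transgene_called).
    """
    main = {c.name for c in layout.main_contigs()}
    planted = truth[truth["is_dmr"]]
    planted_ivs: dict[str, list[tuple[int, int]]] = {}
    for row in planted.itertuples(index=False):
        planted_ivs.setdefault(row.chrom, []).append((row.start, row.end))
    calls = [d for d in dmrs if d.chrom in main]

    def _hit(chrom, s, e):
        return any(a < e and s < b for a, b in planted_ivs.get(chrom, []))

    n_recovered = sum(
        1
        for row in planted.itertuples(index=False)
        if any(d.chrom == row.chrom and d.start < row.end and row.start < d.end for d in calls)
    )
    n_true_calls = sum(1 for d in calls if _hit(d.chrom, d.start, d.end))
    transgene = next((c.name for c in layout.contigs if c.is_transgene), None)
    return {
        "n_planted": int(len(planted)),
        "n_called": len(calls),
        "sensitivity": n_recovered / len(planted) if len(planted) else float("nan"),
        "precision": n_true_calls / len(calls) if calls else float("nan"),
        "transgene_called": bool(transgene and any(d.chrom == transgene for d in dmrs)),
    }
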