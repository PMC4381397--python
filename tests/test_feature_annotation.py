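"""Feature classification, expected distribution and profile computations."""

import numpy as np
import pytest

from shoredmr.dmr_calling import Direction, Dmr
from shoredmr.feature_annotation import (
    AnnotationParams,
    FeatureClass,
    FeatureIndex,
    ScoreTrack,
    Transcript,
    TranscriptSet,
    central_cpg,
    classify_feature,
    expected_feature_distribution,
    mean_profile_over_regions,
    overlap_summary,
    shore_profile,
)
from shoredmr.genome import Contig, GenomeLayout
from shoredmr.intervals import merge_union, subtract, total_bp

from conftest import make_table

PARAMS = AnnotationParams(tss_window=2_500, shore_window=5_000, flank_for_profiles=2_000)


def mk_dmr(chrom, start, end):
    return Dmr(chrom, start, end, 12, 20.0, 50.0, 30.0, Direction.HYPER, 30.0)


def brute_force_classify(chrom, point, transcripts, params):
    """Independent oracle: enumerate every feature the point hits, take the max."""
    hits = [FeatureClass.INTERGENIC]
    for tx in transcripts:
        if tx.chrom != chrom:
            continue
        if abs(point - tx.tss) <= params.tss_window:
            hits.append(FeatureClass.TSS_PROXIMAL)
        if tx.start <= point < tx.end:
            if tx.is_single_exon:
                hits.append(FeatureClass.SINGLE_EXON)
            else:
                in_exon = False
                for ex in tx.exons:
                    if ex[0] <= point < ex[1]:
                        in_exon = True
                        hits.append(
                            FeatureClass.THREE_PRIME_EXON_UTR
                            if ex == tx.last_exon
                            else FeatureClass.INTERNAL_EXON
                        )
                if not in_exon:
                    hits.append(FeatureClass.INTRON)
    return max(hits)


def random_transcripts(rng, chrom="chr1", n=12, span=200_000):
    txs = []
    for i in range(n):
        start = int(rng.integers(0, span - 20_000))
        length = int(rng.integers(500, 20_000))
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(1, 6))
        if n_ex == 1:
            exons = ((start, start + length),)
        else:
            cuts = np.sort(rng.choice(np.arange(1, 2 * n_ex), 2 * n_ex - 2, replace=False))
            edges = np.concatenate([[0], cuts, [2 * n_ex]]) / (2 * n_ex)
            coords = (start + edges * length).astype(int)
            exons = tuple(
                (int(coords[2 * k]), int(coords[2 * k + 1]))
                for k in range(n_ex)
                if coords[2 * k + 1] > coords[2 * k]
            )
        txs.append(Transcript(f"t{i}", f"g{i}", chrom, strand, start, start + length, exons))
    return TranscriptSet(txs)


class TestCentralCpg:
    def test_odd_and_even_counts(self):
        assert central_cpg([10, 20, 30]) == 20
        assert central_cpg([10, 20, 30, 40]) == 20  # lower middle on ties

    def test_matches_sort_and_index_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            pos = rng.choice(10_000, size=int(rng.integers(1, 40)), replace=False)
            srt = sorted(int(p) for p in pos)
            assert central_cpg(pos) == srt[(len(srt) - 1) // 2]

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            central_cpg([])


class TestClassifyFeature:
    def test_tss_outranks_intron(self):
        a = Transcript("a", "a", "chr1", "+", 0, 10_000, ((0, 100), (9_900, 10_000)))
        b = Transcript("b", "b", "chr1", "+", 6_000, 20_000, ((6_000, 20_000),))
        ts = TranscriptSet([a, b])
        # 5_000 is in a's intron and within 2.5 kb of b's TSS at 6_000
        assert classify_feature("chr1", 5_000, ts, PARAMS) is FeatureClass.TSS_PROXIMAL

    def test_intergenic_when_nothing_hit(self):
        ts = TranscriptSet([Transcript("a", "a", "chr1", "+", 0, 100, ((0, 100),))])
        assert classify_feature("chr1", 50_000, ts, PARAMS) is FeatureClass.INTERGENIC
        assert classify_feature("chr2", 50, ts, PARAMS) is FeatureClass.INTERGENIC

    def test_minus_strand_last_exon_is_three_prime(self):
        tx = Transcript("m", "m", "chr1", "-", 100_000, 120_000,
                        ((100_000, 101_000), (110_000, 111_000), (119_000, 120_000)))
        ts = TranscriptSet([tx])
        # on minus strand the 3'-most exon is the lowest-coordinate one;
        # stay >2.5 kb from the TSS at 119_999
        assert classify_feature("chr1", 100_500, ts, PARAMS) is FeatureClass.THREE_PRIME_EXON_UTR
        assert classify_feature("chr1", 110_500, ts, PARAMS) is FeatureClass.INTERNAL_EXON

    def test_matches_bruteforce_oracle_on_random_annotations(self):
        rng = np.random.default_rng(17)
        for rep in range(20):
            ts = random_transcripts(rng)
            index = FeatureIndex(ts, PARAMS)
            points = rng.integers(0, 200_000, size=60)
            for p in points:
                assert index.classify("chr1", int(p)) is brute_force_classify(
                    "chr1", int(p), ts, PARAMS
                ), f"rep={rep} point={p}"


class TestExpectedDistribution:
    LAYOUT = GenomeLayout([Contig("chr1", 200_000)])

    def test_empty_transcripts_all_intergenic(self):
        out = expected_feature_distribution(TranscriptSet([]), self.LAYOUT, PARAMS)
        assert out[FeatureClass.INTERGENIC] == 200_000
        assert sum(v for k, v in out.items() if k != FeatureClass.INTERGENIC) == 0

    def test_duplicated_transcript_idempotent(self):
        tx = Transcript("a", "a", "chr1", "+", 50_000, 51_000, ((50_000, 51_000),))
        one = expected_feature_distribution(TranscriptSet([tx]), self.LAYOUT, PARAMS)
        two = expected_feature_distribution(TranscriptSet([tx, tx]), self.LAYOUT, PARAMS)
        assert one == two

    def test_single_exon_loses_bp_to_own_tss_window(self):
        tx = Transcript("a", "a", "chr1", "+", 50_000, 51_000, ((50_000, 51_000),))
        out = expected_feature_distribution(TranscriptSet([tx]), self.LAYOUT, PARAMS)
        assert out[FeatureClass.TSS_PROXIMAL] == 5_001  # TSS +/- 2500
        assert out[FeatureClass.SINGLE_EXON] == 0  # fully inside the window
        assert sum(out.values()) == 200_000

    def test_partition_matches_interval_algebra_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            ts = random_transcripts(rng)
            out = expected_feature_distribution(ts, self.LAYOUT, PARAMS)
            # classes partition the genome
            assert sum(out.values()) == 200_000
            # non-intergenic total equals the union of all feature intervals
            all_ivs = []
            from shoredmr.feature_annotation import _class_intervals_per_transcript

            for tx in ts:
                for _, iv in _class_intervals_per_transcript(tx, PARAMS):
                    all_ivs.append((max(0, iv[0]), min(200_000, iv[1])))
            covered = total_bp(merge_union(all_ivs))
            assert sum(v for k, v in out.items() if k != FeatureClass.INTERGENIC) == covered
            # per-bp oracle: sample points, classify, compare frequencies exactly
            bitmap = np.zeros(200_000, dtype=np.int8)
            for tx in ts:
                for cls, (s, e) in _class_intervals_per_transcript(tx, PARAMS):
                    s, e = max(0, s), min(200_000, e)
                    if e > s:
                        np.maximum.at(bitmap, np.arange(s, e), np.int8(cls))
            for cls in FeatureClass:
                assert out[cls] == int((bitmap == cls).sum())


class TestOverlapSummary:
    def test_partition_and_half_open_convention(self):
        ts = TranscriptSet([Transcript("a", "a", "chr1", "+", 10_000, 20_000, ((10_000, 20_000),))])
        dmrs = [mk_dmr("chr1", 9_000, 10_000),  # abuts, no shared base -> intergenic
                mk_dmr("chr1", 19_999, 21_000),
                mk_dmr("chr1", 100_000, 101_000)]
        out = overlap_summary(dmrs, ts, [], PARAMS)
        assert out["n_genic"] == 1
        assert out["n_intergenic"] == 2
        assert out["n_genic"] + out["n_intergenic"] == out["n_total"]

    def test_matches_pairwise_intersection_oracle(self):
        rng = np.random.default_rng(31)
        ts = random_transcripts(rng)
        cgis = [("chr1", int(s), int(s) + 500) for s in rng.integers(0, 199_000, 10)]
        dmrs = [mk_dmr("chr1", int(s), int(s) + 800) for s in rng.integers(0, 199_000, 40)]
        out = overlap_summary(dmrs, ts, cgis, PARAMS)
        genic = sum(
            1 for d in dmrs
            if any(tx.start < d.end and d.start < tx.end for tx in ts)
        )
        cgi_n = sum(
            1 for d in dmrs if any(s < d.end and d.start < e for _, s, e in cgis)
        )
        assert out["n_genic"] == genic
        assert out["n_cgi_overlapping"] == cgi_n


class TestShoreProfile:
    TABLE = make_table([("chr1", p, 1, 9) for p in range(10_000, 11_000, 50)])

    def test_offsets(self):
        cgis = [("chr1", 10_000, 11_000)]  # centre 10_500
        dmrs = [mk_dmr("chr1", 9_200, 10_200),  # centre 9_700 -> offset -800
                mk_dmr("chr1", 10_000, 11_000),  # centred on CGI -> 0
                mk_dmr("chr1", 16_000, 17_200)]  # 6 kb away -> excluded
        out = shore_profile(dmrs, cgis, self.TABLE, PARAMS)
        assert list(out["offset"]) == [-800, 0]
        assert out["cgi_pct_mcg"].iloc[0] == pytest.approx(10.0)

    def test_nearest_cgi_tie_goes_low(self):
        cgis = [("chr1", 8_000, 9_000), ("chr1", 11_000, 12_000)]  # centres 8500, 11500
        dmrs = [mk_dmr("chr1", 9_500, 10_500)]  # centre 10_000, equidistant (1500)
        out = shore_profile(dmrs, cgis, self.TABLE, PARAMS)
        assert out["cgi_start"].iloc[0] == 8_000


class TestMeanProfile:
    def test_single_region_equals_slice(self):
        track = ScoreTrack(10, {"chr1": np.arange(100, dtype=float)})
        prof = mean_profile_over_regions(track, [("chr1", 400, 600)], flank=50)
        assert np.allclose(prof, np.arange(45, 56))

    def test_symmetric_values_cancel(self):
        track = ScoreTrack(10, {"chr1": np.full(100, 3.0), "chr2": np.full(100, -3.0)})
        prof = mean_profile_over_regions(track, [("chr1", 500, 500), ("chr2", 500, 500)], 40)
        assert np.allclose(prof, 0.0)

    def test_missing_data_excluded_not_zero(self):
        vals = np.full(100, 7.0)
        vals[:40] = np.nan
        track = ScoreTrack(10, {"chr1": vals})
        prof = mean_profile_over_regions(track, [("chr1", 400, 420)], 100)
        assert np.nanmax(prof) == 7.0
        assert np.isnan(prof[0])  # off-track flank stays missing
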