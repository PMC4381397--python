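"""Smoothing, t-statistics and DMR assembly/filter behaviour."""

import numpy as np
import pandas as pd
import pytest

from shoredmr.dmr_calling import (
    CROSS_TISSUE_CALLING,
    FULL_DEPTH_CALLING,
    Candidate,
    Direction,
    DmrCallParams,
    SmoothingParams,
    align_samples,
    assemble_dmrs,
    call_dmrs,
    cluster_cpgs,
    coverage_filter,
    filter_dmrs,
    group_tstat,
    smooth_sample,
    summarize_directions,
    threshold_quantiles,
)
from shoredmr.methylome_io import MUTANT, WILDTYPE

from conftest import make_table


class TestClusterCpgs:
    def test_gap_splitting(self):
        cl = cluster_cpgs(np.array([100, 200, 5_000_000]), max_gap=10_000)
        assert [list(c) for c in cl] == [[100, 200], [5_000_000]]

    def test_singleton_and_wide_gap(self):
        assert len(cluster_cpgs(np.array([42]), 10)) == 1
        assert len(cluster_cpgs(np.array([0, 50, 100]), 100)) == 1

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            cluster_cpgs(np.array([5, 3]), 10)


def tricube_cov_wls_oracle(pos, y, cov, ns, h, j):
    """Independent weighted-least-squares fit at CpG j (quadratic basis)."""
    pj = pos[j]
    d = np.abs(pos - pj)
    w_half = max(h, np.sort(d)[min(ns, len(pos)) - 1]) if len(pos) > ns else max(h, d.max())
    inside = d <= w_half
    u = d[inside] / (w_half + 1.0)
    w = (1 - u**3) ** 3 * cov[inside]
    x = (pos[inside] - pj).astype(float)
    X = np.column_stack([np.ones_like(x), x, x**2])
    W = np.diag(w)
    beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y[inside])
    return float(np.clip(beta[0], 0, 1))


class TestSmoothing:
    def make(self, pos, p, cov):
        return make_table(
            [("chr1", int(q), int(round(p_i * c_i)), int(c_i - round(p_i * c_i)))
             for q, p_i, c_i in zip(pos, p, cov)]
        )

    @pytest.mark.parametrize("use_numba", [True, False])
    def test_constant_is_fixed_point(self, use_numba):
        pos = np.arange(0, 10_000, 100)
        cov = np.full(len(pos), 10)
        t = self.make(pos, np.full(len(pos), 0.8), cov)
        sm = smooth_sample(t, SmoothingParams(ns=20, h=250), use_numba=use_numba)
        assert np.allclose(sm, 0.8, atol=1e-9)

    def test_singleton_cluster_returns_raw_proportion(self):
        t = make_table([("chr1", 100, 3, 7)])
        sm = smooth_sample(t, SmoothingParams(ns=20, h=250, max_gap=1000))
        assert sm[0] == pytest.approx(0.3)

    def test_linear_ramp_matches_wls_oracle(self):
        rng = np.random.default_rng(11)
        pos = np.sort(rng.choice(np.arange(0, 40_000, 2), size=400, replace=False))
        p = 0.1 + 0.8 * pos / pos.max()
        cov = rng.integers(5, 40, size=len(pos))
        meth = np.round(p * cov).astype(int)
        t = make_table(
            [("chr1", int(q), int(m), int(c - m)) for q, m, c in zip(pos, meth, cov)]
        )
        params = SmoothingParams(ns=20, h=250)
        sm = smooth_sample(t, params)
        y = meth / cov
        for j in rng.choice(len(pos), size=50, replace=False):
            expect = tricube_cov_wls_oracle(pos, y, cov.astype(float), params.ns, params.h, int(j))
            assert sm[j] == pytest.approx(expect, abs=1e-6)

    def test_numba_and_python_paths_agree(self):
        rng = np.random.default_rng(5)
        pos = np.sort(rng.choice(np.arange(0, 20_000, 2), size=150, replace=False))
        cov = rng.integers(0, 30, size=len(pos))
        meth = rng.binomial(cov, 0.6)
        t = make_table([("chr1", int(q), int(m), int(c - m)) for q, m, c in zip(pos, meth, cov)])
        a = smooth_sample(t, SmoothingParams(), use_numba=True)
        b = smooth_sample(t, SmoothingParams(), use_numba=False)
        assert np.allclose(a, b, atol=1e-12, equal_nan=True)

    def test_invariant_to_uniform_coverage_scaling(self):
        rng = np.random.default_rng(9)
        pos = np.sort(rng.choice(np.arange(0, 20_000, 2), size=120, replace=False))
        cov = rng.integers(1, 15, size=len(pos))
        meth = rng.binomial(cov, 0.4)
        t1 = make_table([("chr1", int(q), int(m), int(c - m)) for q, m, c in zip(pos, meth, cov)])
        t2 = make_table([("chr1", int(q), 3 * int(m), 3 * int(c - m)) for q, m, c in zip(pos, meth, cov)])
        assert np.allclose(smooth_sample(t1, SmoothingParams()),
                           smooth_sample(t2, SmoothingParams()), atol=1e-9)


class TestCoverageFilter:
    def build(self, wt_cov, mut_cov):
        samples = []
        for i, c in enumerate(wt_cov):
            samples.append(make_table([("chr1", 100, c, 0)], f"wt{i}", WILDTYPE))
        for i, c in enumerate(mut_cov):
            samples.append(make_table([("chr1", 100, c, 0)], f"mut{i}", MUTANT))
        return samples

    @pytest.mark.parametrize(
        "wt,mut,mode,mincov,expect",
        [
            ((8, 2), (9, 0), "at_least_one_replicate_per_group", 8, True),
            ((7, 7), (9, 9), "at_least_one_replicate_per_group", 8, False),
            ((6, 5), (6, 6), "both_replicates", 6, False),
            ((6, 6), (6, 6), "both_replicates", 6, True),
        ],
    )
    def test_retention_rules(self, wt, mut, mode, mincov, expect):
        mask = coverage_filter(self.build(wt, mut), mincov, mode)
        assert bool(mask[0]) is expect

    def test_missing_group_errors(self):
        s = [make_table([("chr1", 0, 9, 0)], "a", WILDTYPE)]
        with pytest.raises(ValueError):
            coverage_filter(s, 8)


class TestGroupTstat:
    def test_identical_groups_give_zero(self):
        sm = np.tile(np.linspace(0.2, 0.8, 50)[:, None], (1, 4))
        t = group_tstat(sm, [WILDTYPE, WILDTYPE, MUTANT, MUTANT])
        assert np.allclose(t, 0.0)

    def test_sign_convention_mutant_above(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(0.2, 0.4, size=(200, 1))
        sm = np.hstack([base + rng.normal(0, 0.01, (200, 2)),
                        base + 0.3 + rng.normal(0, 0.01, (200, 2))])
        t = group_tstat(sm, [WILDTYPE, WILDTYPE, MUTANT, MUTANT])
        assert (t > 0).all()

    def test_matches_pooled_variance_closed_form(self):
        # flooring and local averaging disabled -> plain two-sample t
        rng = np.random.default_rng(1)
        sm = rng.uniform(0, 1, size=(30, 4))
        groups = [WILDTYPE, WILDTYPE, MUTANT, MUTANT]
        t = group_tstat(sm, groups, local_span=1, floor_quantile=None)
        for j in range(30):
            wt, mut = sm[j, :2], sm[j, 2:]
            s2 = (((wt - wt.mean()) ** 2).sum() + ((mut - mut.mean()) ** 2).sum()) / 2
            expect = (mut.mean() - wt.mean()) / np.sqrt(s2 * (0.5 + 0.5))
            assert t[j] == pytest.approx(expect, abs=1e-9)


class TestThresholdQuantiles:
    def test_symmetric_distribution(self):
        rng = np.random.default_rng(2)
        t = rng.standard_normal(200_00)
        lo, hi = threshold_quantiles(t, 0.01, 0.99)
        assert lo == pytest.approx(-hi, abs=0.1)

    def test_extreme_quantiles_and_constant(self):
        t = np.concatenate([np.arange(100), [500]])
        lo, hi = threshold_quantiles(t, 0.01, 0.99)
        assert lo >= t.min() and hi <= t.max()
        const = np.full(150, 3.3)
        lo, hi = threshold_quantiles(const)
        assert lo == hi == 3.3

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            threshold_quantiles(np.arange(50))


class TestAssembleDmrs:
    def test_run_of_high_t(self):
        t = np.array([3.0, 3.0, 3.0])
        pos = np.array([100, 200, 300])
        chroms = np.array(["chr1"] * 3)
        cands = assemble_dmrs(t, (-2.0, 2.0), pos, chroms)
        assert len(cands) == 1
        assert cands[0].start == 100 and cands[0].end == 302
        assert cands[0].side is Direction.HYPER

    def test_sign_flip_splits(self):
        t = np.array([3.0, 3.0, -3.0, -3.0])
        pos = np.array([0, 100, 200, 300])
        chroms = np.array(["chr1"] * 4)
        cands = assemble_dmrs(t, (-2.0, 2.0), pos, chroms)
        assert [c.side for c in cands] == [Direction.HYPER, Direction.HYPO]

    def test_gap_boundary_splits(self):
        t = np.array([3.0, 3.0, 3.0])
        pos = np.array([0, 2000, 3400])
        chroms = np.array(["chr1"] * 3)
        assert len(assemble_dmrs(t, (-2, 2), pos, chroms, max_intra_gap=1500)) == 2
        assert len(assemble_dmrs(t, (-2, 2), pos, chroms, max_intra_gap=None)) == 1


class TestFilterDmrs:
    def build_candidate(self, n_cpg, wt_p, mut_p):
        pos = np.arange(0, 2 * n_cpg, 2)
        keys = pd.DataFrame({"chrom": "chr1", "pos": pos})
        meth = np.column_stack([
            np.full(n_cpg, round(20 * wt_p)), np.full(n_cpg, round(20 * wt_p)),
            np.full(n_cpg, round(20 * mut_p)), np.full(n_cpg, round(20 * mut_p)),
        ]).astype(int)
        unmeth = 20 - meth
        cand = Candidate("chr1", np.arange(n_cpg), pos, Direction.HYPER, float(n_cpg))
        groups = [WILDTYPE, WILDTYPE, MUTANT, MUTANT]
        return cand, keys, meth, unmeth, groups, np.arange(n_cpg)

    def test_cpg_count_strictness(self):
        for n, expect_full, expect_cross in [(8, 0, 1), (10, 0, 1), (11, 1, 1), (7, 0, 0)]:
            cand, keys, meth, unmeth, groups, ridx = self.build_candidate(n, 0.2, 0.6)
            full = filter_dmrs([cand], keys, meth, unmeth, groups, ridx, FULL_DEPTH_CALLING)
            cross = filter_dmrs([cand], keys, meth, unmeth, groups, ridx, CROSS_TISSUE_CALLING)
            assert len(full) == expect_full, n
            assert len(cross) == expect_cross, n

    def test_delta_boundary_strict(self):
        # delta exactly 15.0 points must be rejected (strict >)
        cand, keys, meth, unmeth, groups, ridx = self.build_candidate(12, 0.25, 0.40)
        assert filter_dmrs([cand], keys, meth, unmeth, groups, ridx, FULL_DEPTH_CALLING) == []
        cand, keys, meth, unmeth, groups, ridx = self.build_candidate(12, 0.25, 0.45)
        out = filter_dmrs([cand], keys, meth, unmeth, groups, ridx, FULL_DEPTH_CALLING)
        assert len(out) == 1
        d = out[0]
        assert d.delta == pytest.approx(20.0)
        assert d.direction is Direction.HYPER
        assert d.n_cpgs == 12


class TestEndToEnd:
    def test_group_swap_negates_deltas(self, sim_config, sim_annotation, sim_methylomes):
        tables, _ = sim_methylomes
        swapped = []
        for t in tables:
            s = make_table(
                list(t.df.itertuples(index=False)),
                t.sample_id,
                MUTANT if t.group == WILDTYPE else WILDTYPE,
            )
            s.layout = t.layout
            swapped.append(s)
        a = call_dmrs(tables)
        b = call_dmrs(swapped)
        ka = {(d.chrom, d.start, d.end): d for d in a}
        kb = {(d.chrom, d.start, d.end): d for d in b}
        assert ka.keys() == kb.keys()
        for k in ka:
            assert ka[k].delta == pytest.approx(-kb[k].delta, abs=1e-9)
            assert ka[k].direction is not kb[k].direction

    def test_called_dmrs_disjoint_and_sorted(self, sim_methylomes):
        tables, _ = sim_methylomes
        dmrs = call_dmrs(tables)
        assert len(dmrs) > 0
        by_chrom = {}
        for d in dmrs:
            by_chrom.setdefault(d.chrom, []).append((d.start, d.end))
        for ivs in by_chrom.values():
            assert ivs == sorted(ivs)
            assert all(a[1] <= b[0] for a, b in zip(ivs, ivs[1:]))


class TestDirectionSummary:
    def test_published_style_tally(self):
        dmrs = [self._dmr(Direction.HYPER)] * 1246 + [self._dmr(Direction.HYPO)] * 83
        s = summarize_directions(dmrs)
        assert s == {"n_total": 1329, "n_hyper": 1246, "n_hypo": 83, "pct_hyper": 94}

    @staticmethod
    def _dmr(direction):
        from shoredmr.dmr_calling import Dmr
        delta = 30.0 if direction is Direction.HYPER else -30.0
        return Dmr("chr1", 0, 100, 12, 20.0, 20.0 + delta, delta, direction, 30.0)

    def test_all_hyper_and_even_split(self):
        hyper = [self._dmr(Direction.HYPER)]
        assert summarize_directions(hyper * 3)["pct_hyper"] == 100
        assert summarize_directions([self._dmr(Direction.HYPER), self._dmr(Direction.HYPO)])["pct_hyper"] == 50

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            summarize_directions([])
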