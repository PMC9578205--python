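import numpy as np
import pytest

from felipop.fstscan import (
    bh_adjust,
    fst_from_calls,
    go_enrichment,
    outlier_genes,
    site_fst,
    window_fst,
)
from felipop.genomatrix import GeneRecord, PopulationMap

from conftest import make_gm


def wc_reference(n1, p1, h1, n2, p2, h2):
    """Independent transcription of the two-population Weir-Cockerham
    variance components (exact rational arithmetic)."""
    from fractions import Fraction as F

    r = F(2)
    n1, n2 = F(n1), F(n2)
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = nbar / nc * (
        s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
    )
    b = nbar / (nbar - 1) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    return a, b, hbar / 2


class TestSiteFst:
    def test_fixed_difference_gives_one(self):
        a, b, c = site_fst(8, 0.0, 0.0, 8, 1.0, 0.0)
        assert a / (a + b + c) == pytest.approx(1.0)

    def test_no_differentiation_nonpositive_a(self):
        a, _, _ = site_fst(8, 0.4, 0.3, 8, 0.4, 0.3)
        assert a <= 0

    def test_matches_symbolic_transcription(self):
        from fractions import Fraction as F

        cases = [
            (8, F(1, 4), F(1, 2), 8, F(7, 8), F(1, 4)),
            (6, F(1, 3), F(1, 3), 10, F(1, 2), F(2, 5)),
            (5, F(4, 5), F(1, 5), 7, F(1, 7), F(3, 7)),
        ]
        for n1, p1, h1, n2, p2, h2 in cases:
            a, b, c = site_fst(n1, float(p1), float(h1), n2, float(p2),
                               float(h2))
            ea, eb, ec = wc_reference(n1, p1, h1, n2, p2, h2)
            assert a == pytest.approx(float(ea), abs=1e-12)
            assert b == pytest.approx(float(eb), abs=1e-12)
            assert c == pytest.approx(float(ec), abs=1e-12)

    def test_spec_worked_example_frozen_values(self):
        a, b, c = site_fst(8, 0.25, 0.5, 8, 0.875, 0.25)
        assert (a, b, c) == pytest.approx((0.1875, -0.03125, 0.1875))
        assert a / (a + b + c) == pytest.approx(6 / 11)


class TestWindowFst:
    def make_two_pop(self, calls):
        gm = make_gm(calls)
        pm = PopulationMap(
            {f"s{i}": ("P" if i < 4 else "Q") for i in range(calls.shape[1])}
        )
        return gm, pm

    def test_all_fixed_different_window_is_one(self):
        calls = np.zeros((5, 8, 2), dtype=np.int8)
        calls[:, 4:] = 1
        gm, pm = self.make_two_pop(calls)
        (w,) = window_fst(gm, pm, ("P", "Q"))
        assert w.fst == pytest.approx(1.0)
        assert w.n_sites == 5

    def test_single_site_window_equals_site_value(self, rng):
        calls = rng.integers(0, 2, size=(1, 8, 2)).astype(np.int8)
        while len(np.unique(calls)) < 2:
            calls = rng.integers(0, 2, size=(1, 8, 2)).astype(np.int8)
        gm, pm = self.make_two_pop(calls)
        wins = window_fst(gm, pm, ("P", "Q"))
        sub = calls[:, :4, :]
        n1 = 4
        p1 = sub.sum() / 8
        h1 = (sub[0, :, 0] != sub[0, :, 1]).mean()
        sub2 = calls[:, 4:, :]
        p2 = sub2.sum() / 8
        h2 = (sub2[0, :, 0] != sub2[0, :, 1]).mean()
        a, b, c = site_fst(4, p1, h1, 4, p2, h2)
        assert wins[0].fst == pytest.approx(a / (a + b + c))

    def test_matches_bruteforce_recompute(self, rng):
        # 30 sites across 3 windows on 2 contigs
        for _ in range(10):
            calls = rng.integers(0, 2, size=(30, 12, 2)).astype(np.int8)
            calls[rng.random((30, 12)) < 0.05] = -1
            pos = np.sort(rng.choice(30_000, size=30, replace=False))
            chroms = ["c1"] * 15 + ["c2"] * 15
            gm = make_gm(calls, positions=list(pos[:15]) + list(pos[:15]),
                         chroms=chroms)
            pm = PopulationMap(
                {f"s{i}": ("P" if i < 6 else "Q") for i in range(12)}
            )
            wins = window_fst(gm, pm, ("P", "Q"), window_size=10_000)
            for w in wins:
                nums, dens = [], []
                for i, v in enumerate(gm.variants):
                    if v.chrom != w.chrom or not w.start <= v.pos < w.end:
                        continue
                    stats = []
                    for sl in (slice(0, 6), slice(6, 12)):
                        sub = calls[i, sl]
                        ok = (sub >= 0).all(axis=1)
                        n = ok.sum()
                        if n == 0:
                            stats.append((0, np.nan, np.nan))
                            continue
                        p = sub[ok].sum() / (2 * n)
                        h = (sub[ok, 0] != sub[ok, 1]).sum() / n
                        stats.append((n, p, h))
                    (n1, p1, h1), (n2, p2, h2) = stats
                    if n1 < 2 or n2 < 2:
                        continue
                    tot = 2 * n1 * p1 + 2 * n2 * p2
                    if tot == 0 or tot == 2 * (n1 + n2):
                        continue
                    a, b, c = site_fst(n1, p1, h1, n2, p2, h2)
                    nums.append(a)
                    dens.append(a + b + c)
                assert w.n_sites == len(nums)
                assert w.fst == pytest.approx(sum(nums) / sum(dens))

    def test_window_fst_invariant_to_bounds(self):
        # weighted estimate lies within [min, max] of per-site ratios
        rng = np.random.default_rng(77)
        calls = rng.integers(0, 2, size=(20, 10, 2)).astype(np.int8)
        gm = make_gm(calls, positions=np.arange(20) * 10)
        pm = PopulationMap(
            {f"s{i}": ("P" if i < 5 else "Q") for i in range(10)}
        )
        (w,) = window_fst(gm, pm, ("P", "Q"))
        ratios = []
        for i in range(20):
            s1, s2 = calls[i, :5], calls[i, 5:]
            tot = calls[i].sum()
            if tot in (0, 20):
                continue
            a, b, c = site_fst(
                5, s1.sum() / 10, (s1[:, 0] != s1[:, 1]).mean(),
                5, s2.sum() / 10, (s2[:, 0] != s2[:, 1]).mean(),
            )
            if a + b + c > 0:
                ratios.append(a / (a + b + c))
        assert min(ratios) - 1e-9 <= w.fst <= max(ratios) + 1e-9


class TestOutliers:
    GENES = [
        GeneRecord("g1", "c1", 19_999, 25_000),
        GeneRecord("g2", "c1", 40_000, 45_000),
        GeneRecord("g3", "c2", 0, 5_000),
    ]

    def test_no_windows_above_threshold(self):
        from felipop.fstscan import FstWindow

        wins = [FstWindow("c1", 0, 10_000, 5, 0.1)]
        assert outlier_genes(wins, 0.5, self.GENES).empty

    def test_half_open_boundary_overlap(self):
        from felipop.fstscan import FstWindow

        wins = [FstWindow("c1", 10_000, 20_000, 5, 0.9)]
        out = outlier_genes(wins, 0.5, self.GENES)
        # window [10000,20000) vs gene [19999,25000): one bp overlap
        assert list(out["gene"]) == ["g1"]
        wins2 = [FstWindow("c1", 10_000, 19_999, 5, 0.9)]
        assert outlier_genes(wins2, 0.5, self.GENES).empty

    def test_max_overlapping_window_reported(self):
        from felipop.fstscan import FstWindow

        wins = [
            FstWindow("c1", 10_000, 20_000, 5, 0.7),
            FstWindow("c1", 20_000, 30_000, 5, 0.95),
            FstWindow("c2", 0, 10_000, 5, 0.8),
        ]
        out = outlier_genes(wins, 0.5, self.GENES).set_index("gene")
        assert out.loc["g1", "max_window_fst"] == 0.95
        assert out.loc["g3", "max_window_fst"] == 0.8


class TestEnrichment:
    def test_worked_hypergeometric_example(self):
        universe = [f"g{i}" for i in range(20)]
        terms = {g: {"T"} for g in universe[:5]}
        candidates = universe[:3] + [universe[10]]
        rows = go_enrichment(candidates, universe, terms)
        assert rows[0].term == "T"
        assert rows[0].p == pytest.approx(155 / 4845)

    def test_candidates_equal_universe_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        terms = {g: {"T1"} for g in universe[:4]}
        rows = go_enrichment(universe, universe, terms, p_cutoff=1.0)
        assert all(r.p == pytest.approx(1.0) for r in rows)

    def test_single_term_q_equals_p(self):
        universe = [f"g{i}" for i in range(12)]
        terms = {g: {"T"} for g in universe[:4]}
        rows = go_enrichment(universe[:4], universe, terms, p_cutoff=1.0)
        (row,) = rows
        assert row.q == pytest.approx(row.p)

    def test_candidates_outside_universe_error(self):
        with pytest.raises(ValueError):
            go_enrichment(["x"], ["a"], {})

    def test_bh_monotone_and_bounded(self, rng):
        p = rng.random(50)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q <= 1).all() and (q >= p - 1e-12).all()


class TestFromCalls:
    def test_monomorphic_window_nan(self):
        calls = np.zeros((3, 8, 2), dtype=np.int8)
        labels = ["P"] * 4 + ["Q"] * 4
        assert np.isnan(fst_from_calls(calls, labels, ("P", "Q")))
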