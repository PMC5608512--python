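"""Size factors, fold changes, FPKM, island distance, promoter grouping."""

import numpy as np
import pandas as pd
import pytest

from greekislands.expression import (
    BASE_MEAN_FLOOR,
    NO_ISLAND_ON_CHROM,
    OVERLAPS_ISLAND,
    distance_to_island,
    fold_changes,
    fpkm,
    group_by_promoter_binding,
    size_factors,
    topk_category_enrichment,
)
from greekislands.intervals import GeneModel, GenomicInterval, PeakSet

import oracles


def counts_df(mat, samples=None):
    mat = np.asarray(mat)
    return pd.DataFrame(
        mat,
        index=[f"g{i}" for i in range(mat.shape[0])],
        columns=samples or [f"s{j}" for j in range(mat.shape[1])],
    )


class TestSizeFactors:
    def test_identical_samples_get_unit_factors(self):
        f = size_factors(counts_df([[10, 10], [3, 3]]))
        assert np.allclose(f, 1.0)

    def test_doubled_sample_splits_around_geometric_mean(self):
        f = size_factors(counts_df([[10, 20], [50, 100], [7, 14]]))
        assert f.iloc[0] == pytest.approx(1 / np.sqrt(2))
        assert f.iloc[1] == pytest.approx(np.sqrt(2))

    def test_no_always_expressed_gene_rejected(self):
        with pytest.raises(ValueError):
            size_factors(counts_df([[0, 5], [5, 0]]))

    def test_matches_formula_by_hand(self, rng):
        mat = rng.negative_binomial(10, 0.3, size=(50, 4)) + 1
        df = counts_df(mat)
        f = size_factors(df)
        geo = np.exp(np.mean(np.log(mat), axis=1))
        expect = np.median(mat / geo[:, None], axis=0)
        assert np.allclose(f, expect)

    def test_column_scaling_recovered_up_to_common_multiplier(self, rng):
        base = rng.poisson(100, size=(200, 3)) + 1
        scales = np.array([0.5, 1.0, 2.0])
        f = size_factors(counts_df(base * scales))
        ratio = f.to_numpy() / scales
        assert np.allclose(ratio, ratio[0], rtol=0.05)


class TestFoldChanges:
    def test_equal_groups_give_zero(self):
        df = counts_df([[100, 100, 100, 100]])
        fc = fold_changes(df, pd.Series(1.0, index=df.columns), ["s0", "s1"], ["s2", "s3"])
        assert fc.log2fc.iloc[0] == pytest.approx(0.0)

    def test_fourfold_change_with_large_counts(self):
        df = counts_df([[1000, 1000, 4000, 4000]])
        fc = fold_changes(df, pd.Series(1.0, index=df.columns), ["s0", "s1"], ["s2", "s3"])
        assert fc.log2fc.iloc[0] == pytest.approx(2.0, abs=0.01)

    def test_low_base_mean_flagged_excluded(self):
        df = counts_df([[5, 5, 5, 5], [4, 5, 5, 5]])
        fc = fold_changes(df, pd.Series(1.0, index=df.columns), ["s0", "s1"], ["s2", "s3"])
        assert not fc.excluded.iloc[0]  # base mean 5.0 is kept (threshold is < 5)
        assert fc.excluded.iloc[1]      # base mean 4.75 < 5

    def test_overlapping_groups_rejected(self):
        df = counts_df([[1, 2, 3]])
        with pytest.raises(ValueError):
            fold_changes(df, pd.Series(1.0, index=df.columns), ["s0"], ["s0", "s1"])


class TestFpkm:
    def test_closed_form(self):
        df = counts_df([[10]])
        factors = pd.Series([1.0], index=["s0"])
        lengths = pd.Series([1000], index=["g0"])
        # library of 1e6 normalised fragments: add a filler gene
        df2 = pd.concat([df, counts_df([[1_000_000 - 10]]).set_axis(["filler"])])
        lengths2 = pd.concat([lengths, pd.Series([500], index=["filler"])])
        out = fpkm(df2, factors, lengths2)
        assert out.loc["g0", "s0"] == pytest.approx(10.0)

    def test_zero_count_gives_zero(self):
        df = counts_df([[0], [100]])
        out = fpkm(df, pd.Series([1.0], index=["s0"]),
                   pd.Series([100, 200], index=["g0", "g1"]))
        assert out.loc["g0", "s0"] == 0.0

    def test_matches_formula_oracle(self, rng):
        mat = rng.poisson(50, size=(20, 3)) + 1
        df = counts_df(mat)
        factors = pd.Series(rng.uniform(0.5, 2.0, 3), index=df.columns)
        lengths = pd.Series(rng.integers(200, 5000, 20), index=df.index)
        out = fpkm(df, factors, lengths)
        norm = mat / factors.to_numpy()
        lib = norm.sum(axis=0)
        expect = norm * 1e9 / lib[None, :] / lengths.to_numpy()[:, None]
        assert np.allclose(out.to_numpy(), expect)


def gene(gid, chrom, start, end, strand="+", cls="OR"):
    tss, tes = (start, end) if strand == "+" else (end, start)
    return GeneModel(gid, chrom, tss, tes, strand, cls)


class TestDistanceToIsland:
    ISLANDS = [GenomicInterval("chr1", 16_000, 16_200, id="i0")]

    def test_overlap_sentinel(self):
        d = distance_to_island([gene("g", "chr1", 15_900, 16_100)], self.ISLANDS)
        assert d["g"] == OVERLAPS_ISLAND

    def test_island_free_chromosome_sentinel(self):
        d = distance_to_island([gene("g", "chr9", 100, 900)], self.ISLANDS)
        assert d["g"] == NO_ISLAND_ON_CHROM

    def test_edge_gap(self):
        d = distance_to_island([gene("g", "chr1", 4_000, 10_000)], self.ISLANDS)
        assert d["g"] == 6_000

    def test_never_returns_zero(self, rng):
        genes = [gene(f"g{i}", "chr1", int(s), int(s) + 500)
                 for i, s in enumerate(rng.integers(0, 40_000, 200))]
        d = distance_to_island(genes, self.ISLANDS)
        assert (d != 0).all()
        assert set(d.unique()) <= {OVERLAPS_ISLAND} | set(d[d > 1])


class TestPromoterGrouping:
    PEAKS_A = PeakSet("A", [GenomicInterval("chr1", 10_800, 11_000)])
    PEAKS_B = PeakSet("B", [GenomicInterval("chr1", 10_000, 10_100)])

    def test_single_factor_within_window(self):
        g = gene("g", "chr1", 10_000 - 200, 10_000 + 5_000)  # TSS at 9800
        out = group_by_promoter_binding([g], self.PEAKS_A, PeakSet("B", []), 1000)
        assert out["g"] == "A-only"  # peak 1000 bp away, inclusive window

    def test_both_factors(self):
        g = gene("g", "chr1", 10_050, 15_000)
        out = group_by_promoter_binding([g], self.PEAKS_A, self.PEAKS_B, 1000)
        assert out["g"] == "both"

    def test_matches_bruteforce_window_overlap(self, rng):
        pa = oracles.random_peakset(rng, "A", 20, chrom_span=50_000)
        pb = oracles.random_peakset(rng, "B", 20, chrom_span=50_000)
        genes = [gene(f"g{i}", "chrT", int(t), int(t) + 1000)
                 for i, t in enumerate(rng.integers(0, 49_000, 100))]
        out = group_by_promoter_binding(genes, pa, pb, 800)

        def near(tss, peaks):
            return any(
                p.start - 800 <= tss < p.end + 800 for p in peaks
            )

        for g in genes:
            a, b = near(g.tss, pa), near(g.tss, pb)
            expect = "both" if a and b else "A-only" if a else "B-only" if b else "none"
            assert out[g.gene_id] == expect


class TestTopkEnrichment:
    def test_exhaustive_enumeration_example(self):
        ranked = ["c1", "c2", "c3", "c4", "u1", "c5", "u2", "u3", "u4", "u5"]
        cat = {"c1", "c2", "c3", "c4", "c5"}
        x, p = topk_category_enrichment(ranked, 4, cat, set(ranked))
        assert x == 4
        assert p == pytest.approx(5 / 210)
        assert p == pytest.approx(oracles.hypergeom_tail_oracle(4, 10, 5, 4))

    def test_zero_overlap_gives_one(self):
        ranked = ["u1", "u2", "c1", "c2"]
        x, p = topk_category_enrichment(ranked, 2, {"c1", "c2"}, set(ranked))
        assert x == 0 and p == pytest.approx(1.0)

    def test_category_equal_to_universe(self):
        ranked = ["a", "b", "c"]
        _, p = topk_category_enrichment(ranked, 2, set(ranked), set(ranked))
        assert p == pytest.approx(1.0)

    def test_category_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            topk_category_enrichment(["a"], 1, {"z"}, {"a"})
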