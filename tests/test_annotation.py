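import math

import numpy as np
import pandas as pd
import pytest

from methylenr import annotation
from methylenr.io import FeatureInterval, GeneRecord, GeneSet


def brute_force_membership(intervals, pos):
    """Oracle: per-position scan of raw (unmerged) intervals."""
    return any(s < pos <= e for s, e in intervals)


def make_catalog(islands=(), exons=(), introns=(), enhancers=(),
                 supers=(), genes=()):
    return annotation.build_catalog(
        islands=[FeatureInterval("chr1", s, e, "cpg_island") for s, e in islands],
        exons=[FeatureInterval("chr1", s, e, "exon") for s, e in exons],
        introns=[FeatureInterval("chr1", s, e, "intron") for s, e in introns],
        enhancers=[FeatureInterval("chr1", s, e, "enhancer") for s, e in enhancers],
        super_enhancers=[FeatureInterval("chr1", s, e, "super_enhancer")
                         for s, e in supers],
        genes=list(genes),
    )


class TestBuildCatalog:
    def test_shores_flank_islands_and_exclude_them(self):
        cat = make_catalog(islands=[(1000, 1200)])
        pos = np.arange(1, 4001)
        chrom = np.array(["chr1"] * len(pos), dtype=object)
        member = cat.classify(chrom, pos)
        # expected shores: [0,1000) u [1200,3200), 1-based 1..1000, 1201..3200
        expected = {p for p in pos if 1 <= p <= 1000 or 1201 <= p <= 3200}
        got = set(pos[member["shore"].to_numpy()])
        assert got == expected

    def test_promoter_spans_tss_plus_minus_1kb(self):
        g = GeneRecord("G1", "Foo", "chr1", 5000, "+")
        cat = make_catalog(genes=[g])
        pos = np.arange(3500, 6501)
        member = cat.classify(np.array(["chr1"] * len(pos), dtype=object), pos)
        got = set(pos[member["promoter"].to_numpy()])
        assert got == set(range(4000, 6001))  # 1-based 4000..6000 inclusive

    def test_adjacent_islands_shores_do_not_double_count(self):
        """Shores between two islands 1 kb apart: compare with a
        brute-force per-position classification."""
        islands = [(1000, 1200), (2200, 2500)]
        cat = make_catalog(islands=islands)
        shore_raw = []
        for s, e in islands:
            shore_raw += [(max(0, s - 2000), s), (e, e + 2000)]
        pos = np.arange(1, 6001)
        member = cat.classify(np.array(["chr1"] * len(pos), dtype=object), pos)
        for p in pos:
            in_island = brute_force_membership(islands, p)
            expect_shore = brute_force_membership(shore_raw, p) and not in_island
            assert member["shore"].iloc[p - 1] == expect_shore
            assert member["cpg_island"].iloc[p - 1] == in_island

    def test_intergenic_is_complement_of_genic(self):
        g = GeneRecord("G1", "Foo", "chr1", 5001, "+")
        cat = make_catalog(exons=[(5000, 5300)], introns=[(5300, 6700)],
                           genes=[g])
        pos = np.arange(1, 10001)
        member = cat.classify(np.array(["chr1"] * len(pos), dtype=object), pos)
        genic = member["exon"] | member["intron"] | member["promoter"]
        assert (member["intergenic"].to_numpy() == ~genic.to_numpy()).all()

    def test_random_layout_matches_brute_force(self):
        rng = np.random.default_rng(12)
        feats = {}
        for name in ("cpg_island", "exon", "intron", "enhancer"):
            feats[name] = [
                (int(s), int(s + rng.integers(50, 800)))
                for s in rng.integers(0, 9000, size=6)
            ]
        cat = make_catalog(islands=feats["cpg_island"], exons=feats["exon"],
                           introns=feats["intron"],
                           enhancers=feats["enhancer"])
        pos = rng.integers(1, 10_000, size=300)
        member = cat.classify(np.array(["chr1"] * 300, dtype=object), pos)
        for name in ("cpg_island", "exon", "intron", "enhancer"):
            for i, p in enumerate(pos):
                assert member[name].iloc[i] == \
                    brute_force_membership(feats[name], p), (name, p)


class TestFeatureEnrichment:
    def _sites(self, n, in_feature_count, start_in=100, start_out=50_000):
        pos = list(range(start_in, start_in + in_feature_count)) + \
              list(range(start_out, start_out + n - in_feature_count))
        return pd.DataFrame({"chrom": ["chr1"] * n, "pos": pos})

    def test_log2_or_matches_cross_product_closed_form(self):
        """dm 30 in / 70 out, background 100 in / 900 out: the fitted
        OR equals the cross-product ratio of the implied 2x2 table."""
        cat = make_catalog(enhancers=[(0, 40_000)])
        bg = self._sites(1000, 100)
        dm = pd.concat([bg.iloc[:30], bg.iloc[100:170]])
        out = annotation.feature_enrichment(dm, bg, cat)
        row = out[out["feature_class"] == "enhancer"].iloc[0]
        assert (row["count_dm_in"], row["count_dm_out"]) == (30, 70)
        cross = (30 * 830) / (70 * 70)
        assert row["log2_odds_ratio"] == pytest.approx(
            math.log2(cross), abs=1e-6)

    def test_proportional_distribution_gives_or_one(self):
        cat = make_catalog(enhancers=[(0, 40_000)])
        bg = self._sites(1000, 100)
        dm = pd.concat([bg.iloc[:10], bg.iloc[100:190]])  # 10% in, like bg
        out = annotation.feature_enrichment(dm, bg, cat)
        row = out[out["feature_class"] == "enhancer"].iloc[0]
        assert row["log2_odds_ratio"] == pytest.approx(0.0, abs=1e-6)

    def test_zero_margin_flagged(self):
        cat = make_catalog(enhancers=[(0, 40_000)])
        bg = self._sites(100, 10)
        dm = bg.iloc[:5]  # all dm inside the feature
        out = annotation.feature_enrichment(dm, bg, cat)
        row = out[out["feature_class"] == "enhancer"].iloc[0]
        assert row["zero_margin"]
        assert np.isfinite(row["log2_odds_ratio_haldane"])

    def test_dm_must_be_subset_of_background(self):
        cat = make_catalog(enhancers=[(0, 100)])
        bg = self._sites(10, 5)
        dm = pd.DataFrame({"chrom": ["chr9"], "pos": [1]})
        with pytest.raises(ValueError):
            annotation.feature_enrichment(dm, bg, cat)


class TestNearestTss:
    def _genes(self, tss_list):
        return [GeneRecord(f"G{i}", f"g{i}", "chr1", t, s)
                for i, (t, s) in enumerate(tss_list)]

    def test_single_gene_takes_everything(self):
        genes = self._genes([(500, "+")])
        sites = pd.DataFrame({"chrom": ["chr1"] * 3, "pos": [1, 400, 9000]})
        out = annotation.annotate_nearest_tss(sites, genes)
        assert (out["gene_id"] == "G0").all()

    def test_equidistant_tie_flagged_and_deterministic(self):
        genes = self._genes([(100, "+"), (300, "+")])
        sites = pd.DataFrame({"chrom": ["chr1"], "pos": [200]})
        out1 = annotation.annotate_nearest_tss(sites, genes)
        out2 = annotation.annotate_nearest_tss(sites, genes)
        assert out1["tss_tie"].iloc[0]
        assert out1["gene_id"].iloc[0] == out2["gene_id"].iloc[0]
        # site at 200 is upstream of G1's TSS (300, + strand)
        assert out1["gene_id"].iloc[0] == "G1"

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(6)
        genes = self._genes([(int(t), "+") for t in
                             rng.integers(1, 50_000, size=20)])
        sites = pd.DataFrame({"chrom": ["chr1"] * 100,
                              "pos": rng.integers(1, 50_000, size=100)})
        out = annotation.annotate_nearest_tss(sites, genes)
        for _, row in out.iterrows():
            dists = {g.gene_id: abs(g.tss_pos - row["pos"]) for g in genes}
            best = min(dists.values())
            assert dists[row["gene_id"]] == best


class TestCallDmGenes:
    def _annotated(self, counts):
        rows = []
        for gene, n in counts.items():
            rows += [{"gene_id": gene}] * n
        return pd.DataFrame(rows)

    def test_threshold_inclusive_at_four(self):
        out = annotation.call_dm_genes(self._annotated({"A": 4, "B": 3}))
        assert list(out["gene_id"]) == ["A"]

    def test_contexts_counted_together(self):
        df = pd.DataFrame({"gene_id": ["A"] * 4,
                           "context": ["CpG", "CpG", "CpH", "CpH"]})
        assert list(annotation.call_dm_genes(df)["gene_id"]) == ["A"]

    def test_monotone_in_min_sites(self):
        counts = {"A": 2, "B": 4, "C": 6, "D": 9}
        df = self._annotated(counts)
        prev = None
        for threshold in (1, 2, 4, 6, 10):
            genes = set(annotation.call_dm_genes(df, min_sites=threshold)["gene_id"])
            if prev is not None:
                assert genes <= prev
            prev = genes


class TestGenesetEnrichment:
    def test_small_exact_value(self):
        # q=2, m=2, n=3, k=2 -> C(2,2)C(3,0)/C(5,2) = 1/10
        assert annotation.hypergeom_test(2, 2, 3, 2) == pytest.approx(0.1)

    def test_zero_overlap_is_one(self):
        assert annotation.hypergeom_test(0, 5, 10, 3) == pytest.approx(1.0)

    def test_query_equal_background_is_one(self):
        bg = {f"g{i}" for i in range(10)}
        sets = [GeneSet("s", frozenset(list(bg)[:4]))]
        out = annotation.geneset_enrichment(bg, bg, sets)
        assert out["pvalue"].iloc[0] == pytest.approx(1.0)

    def test_query_outside_background_rejected(self):
        with pytest.raises(ValueError):
            annotation.geneset_enrichment({"x"}, {"a", "b"}, [])

    def test_matches_enumeration_oracle(self):
        """Exhaustive enumeration of the hypergeometric tail for small
        universes."""
        for m, n, k in [(5, 10, 4), (20, 40, 15), (30, 30, 10), (2, 3, 2)]:
            for q in range(0, min(m, k) + 1):
                exact = sum(
                    math.comb(m, i) * math.comb(n, k - i)
                    for i in range(q, min(m, k) + 1)
                    if k - i <= n
                ) / math.comb(m + n, k)
                assert annotation.hypergeom_test(q, m, n, k) == \
                    pytest.approx(exact, rel=1e-9)


def test_gene_direction_majority_and_ties():
    df = pd.DataFrame({
        "gene_id": ["A"] * 3 + ["B"] * 2 + ["C"] * 4,
        "direction": ["hypo", "hypo", "hyper",
                      "hypo", "hyper",
                      "hyper", "hyper", "hyper", "hypo"],
    })
    out = annotation.gene_direction(df).set_index("gene_id")["direction"]
    assert out["A"] == "hypo"
    assert out["B"] == "mixed"
    assert out["C"] == "hyper"
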