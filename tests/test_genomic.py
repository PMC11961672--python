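"""Unit tests for genome-category classification and enrichment statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import comb

from ptctools import genomic, simulate
from ptctools.exceptions import DataError
from ptctools.io import GenomicInterval


class TestClassifySegment:
    @pytest.mark.parametrize("p, fc, hub, expected", [
        (0.04, 0.5, 1, "PTC"),
        (0.01, 1.0, 0, "very_active"),
        (0.5, 0.3, 0, "moderately_active"),
        (0.5, 0.0, 1, "moderately_active"),   # hub only matters when enriched
        (1.0, -1.0, 0, "inactive"),
        (0.04, -0.5, 0, genomic.UNCLASSIFIED),  # significant depletion
    ])
    def test_rule_table(self, p, fc, hub, expected):
        assert genomic.classify_segment(p, fc, hub) == expected

    def test_invalid_p_raises(self):
        with pytest.raises(DataError, match=r"\[0, 1\]"):
            genomic.classify_segment(1.5, 0.0, 0)

    def test_vectorised_matches_scalar(self, rng):
        df = pd.DataFrame({
            "p": rng.uniform(0, 1, 500),
            "log2fc": rng.normal(0, 1, 500),
            "hub": rng.integers(0, 2, 500),
        })
        vec = genomic.classify_segments(df)
        for i, row in df.iterrows():
            assert vec[i] == genomic.classify_segment(row["p"], row["log2fc"],
                                                      row["hub"])

    def test_fixture_mixing_proportions_recovered(self):
        fx = simulate.gen_genome_fixture(n_segments=2000, seed=3)
        cats = genomic.classify_segments(fx.segments)
        assert (cats == fx.segments["category"]).all()
        frac = cats.value_counts(normalize=True)
        for cat, expected in zip(genomic.CATEGORIES, simulate.DEFAULT_MIXING):
            se = np.sqrt(expected * (1 - expected) / len(cats))
            assert abs(frac.get(cat, 0.0) - expected) < 4 * se + 1e-9


class TestTfTargetEnrichment:
    def test_hand_worked_toy(self):
        cats = {f"g{i}": ("PTC" if i < 20 else "inactive") for i in range(100)}
        # 5 of 10 targets inside the 20-gene category
        targets = [f"g{i}" for i in range(5)] + [f"g{i}" for i in range(50, 55)]
        scores = genomic.tf_target_enrichment({"tf1": targets}, cats)
        row = scores[scores["category"] == "PTC"].iloc[0]
        assert row["expected"] == pytest.approx(2.0)
        assert row["score"] == pytest.approx(2.5)

    def test_category_with_all_genes_scores_one(self):
        cats = {f"g{i}": "PTC" for i in range(50)}
        scores = genomic.tf_target_enrichment({"tf1": ["g0", "g1", "g2"]}, cats)
        assert scores[scores["category"] == "PTC"]["score"].iloc[0] == pytest.approx(1.0)

    def test_weighted_mean_score_is_one(self, genome_fixture):
        fx = genome_fixture
        cats = fx.genes.set_index("gene")["category"]
        network = {tf: set(g["target"]) for tf, g in fx.tf_edges.groupby("tf")}
        scores = genomic.tf_target_enrichment(network, cats)
        for tf, grp in scores.groupby("tf"):
            ok = grp["n_category_genes"] > 0
            weighted = (grp.loc[ok, "score"] * grp.loc[ok, "n_category_genes"]).sum()
            assert weighted / grp["n_category_genes"].sum() == pytest.approx(1.0)

    def test_unbiased_targets_score_near_one(self):
        fx = simulate.gen_genome_fixture(n_tfs=200, targets_per_tf=100,
                                         tf_bias=1.0, seed=5)
        cats = fx.genes.set_index("gene")["category"]
        network = {tf: set(g["target"]) for tf, g in fx.tf_edges.groupby("tf")}
        scores = genomic.tf_target_enrichment(network, cats)
        means = scores.groupby("category")["score"].mean()
        for cat in genomic.CATEGORIES:
            if np.isfinite(means.get(cat, np.nan)):
                assert 0.9 < means[cat] < 1.1

    def test_tf_without_targets_skipped_with_warning(self):
        cats = {"g0": "PTC"}
        with pytest.warns(UserWarning, match="skipped"):
            scores = genomic.tf_target_enrichment({"tf1": ["absent"]}, cats)
        assert scores.empty


class TestTissueSpecificity:
    def test_extremes(self):
        ranks = pd.DataFrame({"blood": [4.0, 1.0], "t1": [1.0, 2.0],
                              "t2": [2.0, 3.0], "t3": [3.0, 4.0]},
                             index=["top", "bottom"])
        assert genomic.tissue_specificity_score(ranks, "top", "blood") == 1.0
        assert genomic.tissue_specificity_score(ranks, "bottom", "blood") == 0.0

    def test_hand_worked_example(self):
        ranks = pd.DataFrame({"blood": [10.0], "t1": [4.0], "t2": [12.0],
                              "t3": [7.0]}, index=["g"])
        assert genomic.tissue_specificity_score(ranks, "g", "blood") \
            == pytest.approx(2 / 3)

    def test_matches_enumeration_oracle(self, rng):
        expr = pd.DataFrame(rng.uniform(0, 100, size=(50, 8)),
                            index=[f"g{i}" for i in range(50)],
                            columns=["blood"] + [f"t{i}" for i in range(7)])
        ranks = genomic.rank_matrix(expr)
        scores = genomic.tissue_specificity_scores(ranks, "blood")
        for gene in ranks.index:
            lower = sum(
                1 for t in ranks.columns if t != "blood"
                and ranks.loc[gene, t] < ranks.loc[gene, "blood"]
            )
            assert scores[gene] == pytest.approx(lower / 7)

    def test_rank_reversal_maps_score_to_complement(self):
        # cyclic-shift construction: every tissue a permutation of 1..n and no
        # gene shares a rank between two tissues, so scores are tie-free
        n = 40
        cols = {"blood": np.arange(1, n + 1)}
        for j in range(1, 6):
            cols[f"t{j}"] = np.roll(np.arange(1, n + 1), j)
        ranks = pd.DataFrame(cols, index=[f"g{i}" for i in range(n)],
                             dtype=float)
        s = genomic.tissue_specificity_scores(ranks, "blood")
        s_rev = genomic.tissue_specificity_scores(-ranks, "blood")
        np.testing.assert_allclose(s_rev, 1.0 - s)

    def test_replicate_columns_averaged(self):
        expr = pd.DataFrame({"blood": [10.0, 1.0], "brainA": [1.0, 10.0],
                             "brainB": [3.0, 8.0]}, index=["g1", "g2"])
        ranks = genomic.rank_matrix(expr, {"blood": ["blood"],
                                           "brain": ["brainA", "brainB"]})
        assert list(ranks.columns) == ["blood", "brain"]
        assert ranks.loc["g1", "brain"] == pytest.approx(1.0)

    def test_missing_gene_raises(self):
        ranks = pd.DataFrame({"blood": [1.0], "t1": [2.0]}, index=["g"])
        with pytest.raises(DataError, match="missing"):
            genomic.tissue_specificity_score(ranks, "absent", "blood")

    def test_focal_shift_dominates_null_genes(self):
        fx = simulate.gen_genome_fixture(n_genes=500, n_focal_shifted=100,
                                         focal_shift=4.0, seed=9)
        ranks = genomic.rank_matrix(fx.tissue_expression)
        scores = genomic.tissue_specificity_scores(ranks, fx.focal_tissue)
        shifted = scores[fx.genes.set_index("gene")["focal_shifted"]]
        null = scores[~fx.genes.set_index("gene")["focal_shifted"]]
        assert stats.mannwhitneyu(shifted, null, alternative="greater").pvalue < 0.01


class TestShuffleIntervals:
    def test_deterministic_and_length_preserving(self):
        genome = {"chr1": 1000, "chr2": 500}
        ivs = [GenomicInterval("chr1", 0, 100), GenomicInterval("chr2", 10, 400)]
        a = genomic.shuffle_intervals(ivs, genome, seed=5)
        b = genomic.shuffle_intervals(ivs, genome, seed=5)
        assert a == b
        assert sorted(iv.length for iv in a) == sorted(iv.length for iv in ivs)
        for iv in a:
            assert 0 <= iv.start and iv.end <= genome[iv.chrom]

    def test_start_positions_uniform_on_single_chromosome(self):
        genome = {"chr1": 1000}
        iv = [GenomicInterval("chr1", 200, 300)]
        rng = np.random.default_rng(0)
        starts = [genomic.shuffle_intervals(iv, genome, rng)[0].start
                  for _ in range(10000)]
        # uniform over [0, 900]
        assert stats.kstest(starts, stats.uniform(0, 901).cdf).pvalue > 0.01

    def test_oversized_interval_raises(self):
        with pytest.raises(DataError, match="exceeds"):
            genomic.shuffle_intervals([GenomicInterval("chr1", 0, 2000)],
                                      {"chr1": 1000}, seed=0)


class TestSnpOverlap:
    def test_count_matches_brute_force(self, rng):
        ivs = [GenomicInterval("chr1", int(s), int(s) + int(l))
               for s, l in zip(rng.integers(0, 900, 30), rng.integers(1, 80, 30))]
        snps = [("chr1", int(p)) for p in rng.integers(0, 1000, 200)]
        brute = sum(1 for c, p in snps
                    if any(iv.start <= p < iv.end for iv in ivs if iv.chrom == c))
        assert genomic.count_snp_overlap(ivs, snps) == brute

    def test_full_genome_coverage_gives_exactly_one(self):
        # a chromosome-spanning interval can only be re-placed onto itself,
        # so the overlap is shuffle-invariant
        genome = {"chr1": 1000}
        ivs = [GenomicInterval("chr1", 0, 1000)]
        snps = [("chr1", 5), ("chr1", 450), ("chr1", 900)]
        res = genomic.snp_overlap_enrichment(ivs, snps, genome, n_perm=20, seed=0)
        assert res.enrichment == pytest.approx(1.0)

    def test_zero_snps(self):
        genome = {"chr1": 1000}
        res = genomic.snp_overlap_enrichment([GenomicInterval("chr1", 0, 100)],
                                             [], genome, n_perm=5, seed=0)
        assert res.observed == 0
        assert res.enrichment == 0.0

    def test_mean_permuted_overlap_matches_closed_form(self, rng):
        # low coverage keeps the clumping correction (1 - exp(-c) vs c) below 1%
        genome = {"chr1": 10_000_000}
        ivs = [GenomicInterval("chr1", int(s), int(s) + 10_000)
               for s in np.linspace(0, 9_500_000, 20)]
        snps = [("chr1", int(p)) for p in rng.integers(0, 10_000_000, 5000)]
        res = genomic.snp_overlap_enrichment(ivs, snps, genome, n_perm=100, seed=1)
        covered = sum(iv.length for iv in ivs)
        expected = len(snps) * covered / genome["chr1"]  # independent placement
        assert abs(res.permuted.mean() - expected) / expected < 0.05


class TestModuleOverlap:
    def test_exact_combinatorial_value(self):
        p = genomic.module_overlap_test([f"g{i}" for i in range(10)],
                                        [f"g{i}" for i in range(10)], 20)
        assert p == pytest.approx(1.0 / comb(20, 10, exact=True), rel=1e-9)

    def test_disjoint_sets_p_near_one(self):
        cluster = [f"g{i}" for i in range(50)]
        module = [f"h{i}" for i in range(50)]
        assert genomic.module_overlap_test(cluster, module, 120) > 0.999

    def test_module_equals_universe(self):
        cluster = [f"g{i}" for i in range(5)]
        module = [f"g{i}" for i in range(20)]
        assert genomic.module_overlap_test(cluster, module, 20) == pytest.approx(1.0)

    def test_oversized_set_raises(self):
        with pytest.raises(DataError, match="subsets"):
            genomic.module_overlap_test([f"g{i}" for i in range(30)], ["g0"], 20)


# ---------------------------------------------------------------------------
# property-based invariants
# ---------------------------------------------------------------------------

from hypothesis import given, settings
from hypothesis import strategies as st


@settings(deadline=None, derandomize=True)
@given(p=st.floats(0.0, 1.0), fc=st.floats(-10.0, 10.0,
                                           allow_nan=False, allow_infinity=False),
       hub=st.integers(0, 1))
def test_classification_partitions_score_space(p, fc, hub):
    """Every (p, log2fc, hub) triple lands in exactly one category (or the
    explicit depleted flag), and the hub flag only matters when enriched."""
    cat = genomic.classify_segment(p, fc, hub)
    assert cat in genomic.CATEGORIES or cat == genomic.UNCLASSIFIED
    if p > 0.05:
        assert cat == genomic.classify_segment(p, fc, 1 - hub)


@settings(deadline=None, derandomize=True)
@given(st.lists(st.lists(st.floats(0.0, 1e6, allow_nan=False, width=32),
                         min_size=4, max_size=4),
                min_size=2, max_size=30))
def test_tissue_scores_bounded(rows):
    """Tissue-specificity scores always lie in [0, 1]."""
    expr = pd.DataFrame(rows, columns=["blood", "t1", "t2", "t3"],
                        index=[f"g{i}" for i in range(len(rows))], dtype=float)
    scores = genomic.tissue_specificity_scores(genomic.rank_matrix(expr), "blood")
    assert ((scores >= 0) & (scores <= 1)).all()
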