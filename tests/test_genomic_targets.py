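import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gastruquant.genomic_targets import (
    CountMatrix,
    GenomicsError,
    assign_region,
    call_enriched_features,
    count_reads,
    de_test,
    enrichment_test,
    integrate_targets,
    make_bins,
    make_gene_models,
    nb_wald_test,
    size_factors,
    spearman,
    region_level_summary,
)
from gastruquant.synthetic_data import (
    GenomicSimParams,
    generate_genomic,
    simulate_de_genes,
    simulate_enrichment_bins,
)


class TestBins:
    def test_exact_tiling(self):
        bins = make_bins({"chr1": 10_000})
        assert len(bins) == 10
        assert (bins.table["end"] - bins.table["start"] == 1000).all()

    def test_truncated_last_bin(self):
        bins = make_bins({"chr1": 10_500})
        assert len(bins) == 11
        assert bins.table.iloc[-1]["end"] - bins.table.iloc[-1]["start"] == 500

    def test_half_open_position_arithmetic(self):
        bins = make_bins({"chr1": 10_000})
        assert bins.bin_index("chr1", 1500) == 1
        assert bins.bin_index("chr1", 999) == 0
        assert bins.bin_index("chr1", 1000) == 1

    def test_tiling_covers_genome(self):
        sizes = {"chr1": 12_345, "chr2": 999}
        bins = make_bins(sizes)
        widths = (bins.table["end"] - bins.table["start"]).sum()
        assert widths == sum(sizes.values())

    def test_nonpositive_size_rejected(self):
        with pytest.raises(GenomicsError):
            make_bins({"chr1": 0})


class TestCountReads:
    def test_totals_conserved(self):
        bins = make_bins({"chr1": 10_000})
        rng = np.random.default_rng(0)
        reads = pd.DataFrame(
            {
                "sample": "s1",
                "chrom": "chr1",
                "pos": rng.integers(0, 10_000, size=100),
            }
        )
        cm = count_reads(reads, bins, {"s1": "control"})
        assert cm.counts["s1"].sum() == 100

    def test_boundary_positions(self):
        bins = make_bins({"chr1": 10_000})
        reads = pd.DataFrame(
            {"sample": ["s1", "s1"], "chrom": "chr1", "pos": [999, 1000]}
        )
        cm = count_reads(reads, bins, {"s1": "control"})
        assert cm.counts.loc[0, "s1"] == 1
        assert cm.counts.loc[1, "s1"] == 1

    def test_out_of_range_position_rejected(self):
        bins = make_bins({"chr1": 10_000})
        reads = pd.DataFrame({"sample": ["s1"], "chrom": "chr1", "pos": [10_000]})
        with pytest.raises(GenomicsError, match="beyond"):
            count_reads(reads, bins, {"s1": "control"})

    def test_planted_poisson_means_recovered(self):
        bins = make_bins({"chr1": 10_000})
        rng = np.random.default_rng(1)
        mean_per_bin = 200
        pos = rng.integers(0, 10_000, size=mean_per_bin * 10)
        reads = pd.DataFrame({"sample": "s1", "chrom": "chr1", "pos": pos})
        cm = count_reads(reads, bins, {"s1": "control"})
        # uniform placement: each bin's count within 5 sigma of the mean
        assert (abs(cm.counts["s1"] - mean_per_bin) < 5 * np.sqrt(mean_per_bin)).all()


class TestGeneModels:
    def test_promoter_plus_strand(self):
        genes = pd.DataFrame(
            [{"gene_id": "g", "chrom": "c", "start": 5000, "end": 8000, "strand": "+"}]
        )
        gm = make_gene_models(genes, {"c": 20_000})
        assert gm.loc[0, "promoter_start"] == 3000
        assert gm.loc[0, "promoter_end"] == 5000

    def test_promoter_minus_strand(self):
        genes = pd.DataFrame(
            [{"gene_id": "g", "chrom": "c", "start": 5000, "end": 8000, "strand": "-"}]
        )
        gm = make_gene_models(genes, {"c": 20_000})
        assert gm.loc[0, "promoter_start"] == 8000
        assert gm.loc[0, "promoter_end"] == 10_000

    def test_promoter_clipped_to_chromosome(self):
        genes = pd.DataFrame(
            [
                {"gene_id": "a", "chrom": "c", "start": 500, "end": 900, "strand": "+"},
                {"gene_id": "b", "chrom": "c", "start": 100, "end": 950, "strand": "-"},
            ]
        )
        gm = make_gene_models(genes, {"c": 1000}).set_index("gene_id")
        assert gm.loc["a", "promoter_start"] == 0
        assert gm.loc["b", "promoter_end"] == 1000

    def test_strand_symmetry_under_reflection(self):
        # a '-' gene equals a '+' gene under coordinate reflection; its
        # promoter must land on the mirrored interval
        size = 50_000
        genes_p = pd.DataFrame(
            [{"gene_id": "g", "chrom": "c", "start": 11_000, "end": 14_000, "strand": "+"}]
        )
        genes_m = pd.DataFrame(
            [
                {
                    "gene_id": "g",
                    "chrom": "c",
                    "start": size - 14_000,
                    "end": size - 11_000,
                    "strand": "-",
                }
            ]
        )
        gp = make_gene_models(genes_p, {"c": size}).iloc[0]
        gm = make_gene_models(genes_m, {"c": size}).iloc[0]
        assert gm["promoter_start"] == size - gp["promoter_end"]
        assert gm["promoter_end"] == size - gp["promoter_start"]


class TestAssignRegion:
    def _setup(self):
        bins = make_bins({"c": 30_000})
        genes = pd.DataFrame(
            [{"gene_id": "g", "chrom": "c", "start": 10_000, "end": 15_000, "strand": "+"}]
        )
        return bins, make_gene_models(genes, {"c": 30_000})

    def test_precedence(self):
        bins, gm = self._setup()
        region = assign_region(bins, gm)
        assert region.loc[12] == "gene_body"
        assert region.loc[8] == "promoter"  # [8000, 10000) upstream
        assert region.loc[9] == "promoter"
        assert region.loc[20] == "intergenic"

    def test_promoter_beats_other_gene_body(self):
        bins = make_bins({"c": 30_000})
        genes = pd.DataFrame(
            [
                {"gene_id": "a", "chrom": "c", "start": 5_000, "end": 12_000, "strand": "+"},
                {"gene_id": "b", "chrom": "c", "start": 14_000, "end": 20_000, "strand": "+"},
            ]
        )
        gm = make_gene_models(genes, {"c": 30_000})
        region = assign_region(bins, gm)
        # bin 12 overlaps gene b's promoter [12000, 14000): promoter wins
        assert region.loc[12] == "promoter"


class TestNBTest:
    def _identical(self, seed=0, n=500):
        rng = np.random.default_rng(seed)
        base = rng.poisson(50, size=(n, 3))
        counts = pd.DataFrame(
            np.hstack([base, base]),
            columns=["c1", "c2", "c3", "f1", "f2", "f3"],
        )
        cond = {f"c{i}": "control" for i in (1, 2, 3)}
        cond.update({f"f{i}": "fusion" for i in (1, 2, 3)})
        return CountMatrix(counts=counts, conditions=pd.Series(cond))

    def test_null_self_comparison_no_calls(self):
        res = enrichment_test(self._identical())
        assert res["significant"].sum() == 0
        assert res["depleted"].sum() == 0

    def test_library_depth_invariance(self):
        cm, truth = simulate_enrichment_bins(
            n_null=2000, n_enriched=50, fold=8.0, seed=7
        )
        sig1 = set(enrichment_test(cm).index[enrichment_test(cm)["significant"]])
        doubled = cm.counts.copy()
        doubled["fusion_1"] = doubled["fusion_1"] * 2  # deeper library, no signal change
        cm2 = CountMatrix(counts=doubled, conditions=cm.conditions)
        sig2 = set(enrichment_test(cm2).index[enrichment_test(cm2)["significant"]])
        overlap = len(sig1 & sig2) / max(len(sig1 | sig2), 1)
        assert overlap > 0.95

    def test_all_zero_feature(self):
        cm = self._identical()
        cm.counts.iloc[0] = 0
        res = nb_wald_test(cm, "control", "fusion")
        assert res.iloc[0]["p"] == 1.0
        assert np.isnan(res.iloc[0]["log2_fc"])

    def test_size_factors_normalize_depth(self):
        rng = np.random.default_rng(2)
        base = rng.poisson(100, size=(1000, 4)).astype(float)
        scaled = base * np.array([1.0, 2.0, 0.5, 1.0])
        sf = size_factors(scaled)
        assert sf == pytest.approx([1.0, 2.0, 0.5, 1.0] / np.exp(np.mean(np.log([1, 2, 0.5, 1]))), rel=0.05)

    def test_replicate_minimum_enforced(self):
        cm = self._identical()
        sub = CountMatrix(
            counts=cm.counts[["c1", "f1", "f2"]],
            conditions=cm.conditions[["c1", "f1", "f2"]],
        )
        with pytest.raises(GenomicsError, match="replicates"):
            nb_wald_test(sub, "control", "fusion")

    def test_strong_enrichment_recovered(self):
        cm, truth = simulate_enrichment_bins(
            n_null=3000, n_enriched=60, fold=8.0, seed=3
        )
        res = enrichment_test(cm)
        sig = res["significant"].to_numpy()
        assert sig[truth].mean() > 0.95
        assert sig[~truth].mean() < 0.005


class TestDE:
    def test_identical_matrices_no_calls(self):
        rng = np.random.default_rng(4)
        base = rng.poisson(80, size=(400, 4))
        counts = pd.DataFrame(
            np.hstack([base, base]),
            columns=[f"WT_{i}" for i in range(4)] + [f"mut_{i}" for i in range(4)],
        )
        cond = {f"WT_{i}": "WT" for i in range(4)}
        cond.update({f"mut_{i}": "mutant" for i in range(4)})
        cm = CountMatrix(counts=counts, conditions=pd.Series(cond))
        assert de_test(cm)["significant"].sum() == 0

    def test_planted_recall(self):
        cm, truth = simulate_de_genes(seed=6)
        res = de_test(cm)
        sig = res["significant"].to_numpy()
        assert sig[truth["de"]].mean() >= 0.85

    def test_direction_sign_convention(self):
        cm, truth = simulate_de_genes(
            n_null=200, n_de=40, up_fraction=0.5, fold=6.0, seed=8
        )
        res = de_test(cm)
        called = res["significant"].to_numpy() & truth["de"].to_numpy()
        assert (
            res["direction"].to_numpy()[called] == truth["direction"].to_numpy()[called]
        ).all()


class TestIntegration:
    def _de_frame(self, universe, sig_ids, down_ids=()):
        df = pd.DataFrame(
            {
                "significant": [g in sig_ids for g in universe],
                "direction": [
                    "down_in_mutant" if g in down_ids else "up_in_mutant"
                    for g in universe
                ],
                "log2_fc": 1.0,
            },
            index=pd.Index(universe, name="gene_id"),
        )
        return df

    def test_published_venn_arithmetic(self):
        # id sets with the printed class sizes over a 2950-gene DE universe
        universe = [f"g{i}" for i in range(2950)]
        body_only = set(universe[:492])
        promoter_only = set(universe[492:662])
        both = set(universe[662:812])
        de = self._de_frame(universe, set(universe))
        cls, summary = integrate_targets(
            de, body_only | both, promoter_only | both
        )
        assert summary["class_counts"]["gene_body_only"] == 492
        assert summary["class_counts"]["promoter_only"] == 170
        assert summary["class_counts"]["both"] == 150
        assert summary["total_direct_targets"] == 812
        assert summary["percent_of_de_genes"] == 28

    def test_disjoint_sets_no_targets(self):
        universe = [f"g{i}" for i in range(10)]
        de = self._de_frame(universe, set(universe[:5]))
        _, summary = integrate_targets(de, {"x1"}, {"x2"})
        assert summary["total_direct_targets"] == 0
        assert summary["percent_of_de_genes"] == 0
        assert summary["orphan_enriched_ids"] == ["x1", "x2"]

    def test_de_equals_body_set_all_direct(self):
        universe = [f"g{i}" for i in range(20)]
        sig = set(universe[:8])
        de = self._de_frame(universe, sig)
        cls, summary = integrate_targets(de, sig, set())
        assert summary["percent_of_de_genes"] == 100
        assert (cls["enrichment_locus"] == "gene_body_only").all()

    def test_set_theoretic_oracle(self):
        rng = np.random.default_rng(9)
        universe = [f"g{i}" for i in range(300)]
        sig = set(rng.choice(universe, 120, replace=False))
        body = set(rng.choice(universe, 60, replace=False))
        prom = set(rng.choice(universe, 40, replace=False))
        _, summary = integrate_targets(self._de_frame(universe, sig), body, prom)
        assert summary["total_direct_targets"] == len(sig & (body | prom))
        assert summary["class_counts"]["both"] == len(sig & body & prom)
        assert summary["class_counts"]["gene_body_only"] == len(sig & body - prom)

    def test_enriched_gene_calling(self):
        cm_params = GenomicSimParams(seed=12, n_genes=800, n_de=100,
                                     venn_body_only=25, venn_promoter_only=20,
                                     venn_both=10)
        gm, bins, damid, expr, truth = generate_genomic(cm_params)
        enr = enrichment_test(damid)
        genes_set, proms_set, unassessed = call_enriched_features(enr, bins, gm)
        planted_body = set(truth.genes[truth.genes["enriched_body"]]["gene_id"])
        planted_prom = set(truth.genes[truth.genes["enriched_promoter"]]["gene_id"])
        assert len(genes_set & planted_body) / len(planted_body) >= 0.85
        assert len(genes_set - planted_body) <= 2
        assert len(proms_set & planted_prom) / len(planted_prom) >= 0.85


class TestSpearman:
    def test_monotone_increasing(self):
        rho, _ = spearman([1, 2, 3, 4, 5], [2, 4, 8, 16, 32])
        assert rho == pytest.approx(1.0)

    def test_monotone_decreasing(self):
        rho, _ = spearman([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_constant_vector_flagged(self):
        rho, p = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(rho) and np.isnan(p)

    def test_exact_p_matches_independent_enumeration(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 5.0])
        y = np.array([2.0, 0.5, 3.0, 4.0, 6.0])
        rho, p = spearman(x, y)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        cnt = tot = 0
        for perm in itertools.permutations(range(5)):
            r = np.corrcoef(rx, ry[list(perm)])[0, 1]
            tot += 1
            cnt += abs(r) >= obs - 1e-12
        assert p == pytest.approx(cnt / tot, abs=1e-12)


class TestRegionSummary:
    def test_identical_samples_zero_ratio(self):
        rng = np.random.default_rng(10)
        base = rng.poisson(40, size=(600, 3))
        counts = pd.DataFrame(
            np.hstack([base, base]),
            columns=["c1", "c2", "c3", "f1", "f2", "f3"],
        )
        cond = {f"c{i}": "control" for i in (1, 2, 3)}
        cond.update({f"f{i}": "fusion" for i in (1, 2, 3)})
        cm = CountMatrix(counts=counts, conditions=pd.Series(cond))
        regions = pd.Series(
            ["gene_body"] * 600, index=counts.index, name="region"
        )
        out = region_level_summary(cm, regions).set_index("region")
        assert abs(out.loc["gene_body", "median_log2_fc"]) < 1e-9
        assert out.loc["intergenic", "n_bins"] == 0
        assert np.isnan(out.loc["intergenic", "median_norm_reads"])

    def test_planted_promoter_enrichment_visible(self):
        # every gene's promoter carries a planted enriched bin: the
        # promoter-region ratio distribution must sit above intergenic
        gm, bins, damid, expr, truth = generate_genomic(
            GenomicSimParams(seed=13, n_genes=100, n_de=100,
                             venn_body_only=0, venn_promoter_only=100, venn_both=0)
        )
        regions = assign_region(bins, gm)
        out = region_level_summary(damid, regions).set_index("region")
        assert (
            out.loc["promoter", "median_log2_fc"]
            >= out.loc["intergenic", "median_log2_fc"]
        )
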