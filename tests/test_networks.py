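import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chromacell import networks as net, synthetic as syn
from chromacell.errors import ParameterError
from chromacell.genome import BinGrid, GeneModel
from chromacell.loops import Loop

from conftest import random_toy_genome
from oracles import brute_force_links, fisher_two_sided_exhaustive


def make_loop(grid, a, b):
    return Loop("chr1", a, b, abs(b - a) * grid.resolution, observed=3.0, p=1e-4, q=1e-3)


class TestLinkPeaksToGenes:
    def test_peak_without_promoter_or_anchor_overlap_gives_no_links(self, toy_genes):
        grid = BinGrid({"chr1": 4_000_000}, 40_000)
        peaks = [("chr1", 3_000_000, 3_000_600, "lonely")]
        assert net.link_peaks_to_genes(peaks, [], toy_genes, grid) == []

    def test_one_peak_looping_to_two_promoters_gives_two_links(self):
        grid = BinGrid({"chr1": 4_000_000}, 40_000)
        genes = [
            GeneModel("G1", "chr1", "+", 82_000, ((82_000, 82_300),)),   # promoter in bin 2
            GeneModel("G2", "chr1", "+", 83_000, ((83_000, 83_300),)),   # promoter in bin 2
        ]
        peaks = [("chr1", 400_100, 400_700, "enh")]  # bin 10
        loops = [make_loop(grid, 2, 10)]
        links = net.link_peaks_to_genes(peaks, loops, genes, grid)
        assert {(l.peak_id, l.gene_id, l.evidence) for l in links} == {
            ("enh", "G1", "loop"),
            ("enh", "G2", "loop"),
        }

    def test_matches_brute_force_oracle_on_random_toy_genomes(self, rng):
        for _ in range(100):
            grid, genes = random_toy_genome(rng, chrom_len=800_000, n_genes=5)
            n = grid.n_bins("chr1")
            peaks = []
            for k in range(int(rng.integers(1, 6))):
                s = int(rng.integers(0, grid.chrom_sizes["chr1"] - 900))
                peaks.append(("chr1", s, s + int(rng.integers(200, 900)), f"pk{k}"))
            loops = []
            for _k in range(int(rng.integers(0, 4))):
                a, b = sorted(rng.choice(n, size=2, replace=False))
                loops.append(make_loop(grid, int(a), int(b)))
            got = {
                (l.peak_id, l.gene_id, l.evidence)
                for l in net.link_peaks_to_genes(peaks, loops, genes, grid)
            }
            assert got == brute_force_links(peaks, loops, genes, grid)

    def test_monotone_in_loops(self, rng):
        grid, genes = random_toy_genome(rng, chrom_len=800_000, n_genes=5)
        peaks = [("chr1", 100, 900, "pk0"), ("chr1", 300_000, 300_500, "pk1")]
        loops = [make_loop(grid, 3, 30), make_loop(grid, 10, 60)]
        base = set(map(str, net.link_peaks_to_genes(peaks, loops[:1], genes, grid)))
        more = set(map(str, net.link_peaks_to_genes(peaks, loops, genes, grid)))
        assert base <= more


@pytest.fixture(scope="module")
def planted():
    grid, genes = syn.generate_genome(1, 10_000_000, 10_000, 250, seed=31)
    params = syn.GeneratorParams(
        L=100.0, alpha=1.0, beta=0.0, tad_boost=1.0, fire_boost=1.0,
        loop_boost=3.0, mu0=5.0, gamma=2.0,
    )
    truth = syn.plant_truth(grid, genes=genes, params=params, seed=32,
                            n_fires_specific=0, n_fires_common=0,
                            max_loops_per_promoter=15, frac_looped_promoters=0.7)
    peaks, expr = syn.simulate_peaks_expression(truth, genes, seed=33)
    loops = [
        make_loop(grid, p, t) for (p, t) in truth.loops["neuron"]["chr1"]
    ]
    links = net.link_peaks_to_genes(peaks["neuron"], loops, genes, grid)
    return grid, genes, truth, peaks["neuron"], expr["neuron"], links


class TestEnhancerCountVsExpression:

    def test_group_means_non_decreasing_with_strong_rank_correlation(self, planted):
        _, genes, _, peaks, expr, links = planted
        table = net.enhancer_count_vs_expression(links, expr, peaks, genes)
        assert len(table) >= 5
        rho = stats.spearmanr(np.arange(len(table)), table["mean_expression"]).statistic
        assert rho >= 0.9

    def test_zero_link_genes_average_near_baseline(self, planted):
        _, genes, truth, peaks, expr, links = planted
        table = net.enhancer_count_vs_expression(links, expr, peaks, genes)
        zero = table[table["enhancers"] == "0"]
        assert len(zero) == 1
        mu0 = truth.params.mu0
        assert zero["mean_expression"].iloc[0] == pytest.approx(
            mu0, abs=4 * truth.params.expr_noise_sd / np.sqrt(zero["n_genes"].iloc[0])
        )

    def test_counts_of_twelve_and_fifteen_pool_into_ten_plus(self):
        grid = BinGrid({"chr1": 4_000_000}, 10_000)
        genes = [GeneModel(f"G{i}", "chr1", "+", 50_000 + 200_000 * i, ()) for i in (0, 1)]
        peaks, links = [], []
        for i, g in enumerate(genes):
            k = 12 if i == 0 else 15
            for j in range(k):
                name = f"e{i}_{j}"
                s = 1_000_000 + (i * 20 + j) * 10_000
                peaks.append(("chr1", s + 100, s + 700, name))
                links.append(net.PeakGeneLink(name, g.gene_id, "", "loop", f"loop{j}"))
        expr = pd.Series([7.0, 9.0], index=["G0", "G1"])
        table = net.enhancer_count_vs_expression(links, expr, peaks, genes)
        assert list(table["enhancers"]) == ["10+"]
        assert table["n_genes"].iloc[0] == 2
        assert table["mean_expression"].iloc[0] == pytest.approx(8.0)

    def test_missing_expression_rejected(self, toy_genes):
        with pytest.raises(ParameterError):
            net.enhancer_count_vs_expression(
                [], pd.Series(dtype=float), [], toy_genes
            )


class TestGeneSetEnrichment:
    def test_balanced_table_gives_or_one_p_one(self):
        universe = {f"g{i}" for i in range(100)}
        query = {f"g{i}" for i in range(50)}
        module = {f"g{i}" for i in range(25)} | {f"g{i}" for i in range(50, 75)}
        res = net.gene_set_enrichment(query, {"m": module}, universe)[0]
        assert res.table == (25, 25, 25, 25)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)

    def test_disjoint_query_and_module_gives_or_below_one(self):
        universe = {f"g{i}" for i in range(60)}
        res = net.gene_set_enrichment(
            {f"g{i}" for i in range(20)},
            {"m": {f"g{i}" for i in range(20, 40)}},
            universe,
        )[0]
        assert res.odds_ratio < 1

    def test_p_matches_exhaustive_hypergeometric_enumeration(self, rng):
        for _ in range(40):
            n = int(rng.integers(8, 31))
            universe = {f"g{i}" for i in range(n)}
            query = set(rng.choice(sorted(universe), size=int(rng.integers(1, n)), replace=False))
            module = set(rng.choice(sorted(universe), size=int(rng.integers(1, n)), replace=False))
            res = net.gene_set_enrichment(query, {"m": module}, universe)[0]
            a, b, c, d = res.table
            assert res.p == pytest.approx(fisher_two_sided_exhaustive(a, b, c, d), rel=1e-9)

    def test_bh_q_monotone_in_rank_ordered_p(self, rng):
        universe = {f"g{i}" for i in range(200)}
        query = set(rng.choice(sorted(universe), size=60, replace=False))
        modules = {
            f"m{k}": set(rng.choice(sorted(universe), size=30, replace=False))
            for k in range(10)
        }
        res = net.gene_set_enrichment(query, modules, universe)
        ordered = sorted(res, key=lambda r: r.p)
        qs = [r.q for r in ordered]
        assert qs == sorted(qs)
        assert all(r.q >= r.p for r in res)

    def test_empty_universe_rejected(self):
        with pytest.raises(ParameterError):
            net.gene_set_enrichment(set(), {}, set())
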