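import numpy as np
import pytest

from chromacell import synthetic as syn
from chromacell.contacts import expected_by_distance, fit_decay_exponent
from chromacell.errors import ParameterError
from chromacell.genome import iter_gene_table


def flat_params(**kw):
    """Decay-only parameters (all structure off) unless overridden."""
    defaults = dict(L=100.0, alpha=1.0, beta=0.0, tad_boost=1.0, fire_boost=1.0, loop_boost=1.0)
    defaults.update(kw)
    return syn.GeneratorParams(**defaults)


class TestGenerateGenome:
    def test_bin_count_matches_length(self):
        grid, _ = syn.generate_genome(1, 20_000_000, 40_000, 10, seed=0)
        assert grid.n_bins("chr1") == 500

    def test_same_seed_gives_byte_identical_gene_table(self):
        _, g1 = syn.generate_genome(2, 5_000_000, 10_000, 40, seed=7)
        _, g2 = syn.generate_genome(2, 5_000_000, 10_000, 40, seed=7)
        assert "\n".join(iter_gene_table(g1)) == "\n".join(iter_gene_table(g2))

    def test_different_seed_changes_genes(self):
        _, g1 = syn.generate_genome(1, 5_000_000, 10_000, 40, seed=7)
        _, g2 = syn.generate_genome(1, 5_000_000, 10_000, 40, seed=8)
        assert g1 != g2

    def test_genes_lie_within_chromosome_with_distinct_tss(self):
        grid, genes = syn.generate_genome(1, 6_000_000, 10_000, 120, seed=3)
        tss = [g.tss for g in genes]
        assert len(set(tss)) == len(tss)
        for g in genes:
            s, e = g.span
            assert 0 <= s < e <= grid.chrom_sizes[g.chrom]

    def test_too_short_chromosome_rejected(self):
        with pytest.raises(ParameterError):
            syn.generate_genome(1, 3_999_999, 40_000, 5, seed=0)


class TestContactSimulation:
    def test_matrix_symmetric_nonnegative_integer(self):
        grid = syn.BinGrid({"chr1": 8_000_000}, 40_000)
        truth = syn.plant_truth(grid, params=flat_params(), seed=1)
        cm = syn.simulate_contact_map(grid, truth, "neuron", seed=2)
        assert np.array_equal(cm.counts, cm.counts.T)
        assert (cm.counts >= 0).all()
        assert np.array_equal(cm.counts, np.round(cm.counts))
        assert np.all(np.diag(cm.counts) == 0)

    def test_mean_decay_matches_power_law(self):
        # boosts off: empirical mean at offset d should converge to L * d^-alpha
        grid = syn.BinGrid({"chr1": 20_000_000}, 40_000)
        truth = syn.plant_truth(
            grid, params=flat_params(L=80.0, alpha=1.2), seed=3,
            n_fires_specific=0, n_fires_common=0,
        )
        cm = syn.simulate_contact_map(grid, truth, "neuron", seed=4)
        profile = expected_by_distance(cm)
        for d in (1, 2, 5, 10):
            expected = 80.0 * d ** -1.2
            n_pairs = 500 - d
            tol = 4 * np.sqrt(expected / n_pairs)  # Monte-Carlo error
            assert abs(profile[d] - expected) < tol
        L_hat, alpha_hat = fit_decay_exponent(profile, d_min=1, d_max=100)
        assert abs(alpha_hat - 1.2) / 1.2 < 0.10

    def test_loop_pixel_expectation_is_boost_times_decay(self):
        grid = syn.BinGrid({"chr1": 8_000_000}, 40_000)
        truth = syn.plant_truth(
            grid,
            genes=syn.generate_genome(1, 8_000_000, 40_000, 20, seed=5)[1],
            params=flat_params(L=50.0, loop_boost=3.0),
            seed=5,
            n_fires_specific=0,
            n_fires_common=0,
        )
        E = syn.expected_matrix(truth, "neuron", "chr1")
        loops = truth.loops["neuron"]["chr1"]
        assert loops, "scenario must plant at least one loop"
        for (p, t) in loops:
            d = abs(t - p)
            assert E[p, t] == pytest.approx(3.0 * 50.0 / d)

    def test_compartment_checkerboard_modulates_expectation(self):
        grid = syn.BinGrid({"chr1": 8_000_000}, 40_000)
        truth = syn.plant_truth(grid, params=flat_params(beta=0.4), seed=6,
                                n_fires_specific=0, n_fires_common=0)
        E = syn.expected_matrix(truth, "neuron", "chr1")
        s = truth.compartment_sign["neuron"]["chr1"]
        i, j = 0, 100
        base = 100.0 / abs(j - i)
        assert E[i, j] == pytest.approx(base * (1 + 0.4 * s[i] * s[j]))

    def test_same_seed_reproduces_counts(self):
        grid = syn.BinGrid({"chr1": 8_000_000}, 40_000)
        truth = syn.plant_truth(grid, params=flat_params(), seed=1)
        a = syn.simulate_contact_map(grid, truth, "neuron", seed=9)
        b = syn.simulate_contact_map(grid, truth, "neuron", seed=9)
        assert np.array_equal(a.counts, b.counts)


class TestPeaksExpression:
    @pytest.fixture()
    def looped_world(self):
        grid, genes = syn.generate_genome(1, 10_000_000, 10_000, 200, seed=11)
        truth = syn.plant_truth(
            grid, genes=genes, params=flat_params(loop_boost=3.0, mu0=5.0, gamma=2.0),
            seed=12, n_fires_specific=0, n_fires_common=0,
            max_loops_per_promoter=15, frac_looped_promoters=0.7,
        )
        return grid, genes, truth

    def test_each_enhancer_bin_yields_one_peak_inside_it(self, looped_world):
        grid, genes, truth = looped_world
        peaks, _ = syn.simulate_peaks_expression(truth, genes, seed=13)
        for ct in truth.cell_types:
            enh = truth.enhancer_bins[ct]["chr1"]
            assert len(peaks[ct]) == len(enh)
            for (chrom, s, e, _name), b in zip(peaks[ct], enh):
                bs, be = grid.bin_interval(chrom, b)
                assert bs <= s < e <= be

    def test_expression_mean_saturates_at_ten_enhancers(self, looped_world):
        _, genes, truth = looped_world
        counts = syn.planted_enhancer_counts(truth, genes, "neuron")
        p = truth.params
        means = {g.gene_id: p.mu0 + p.gamma * min(counts[g.gene_id], 10) for g in genes}
        k0 = [gid for gid, k in counts.items() if k == 0]
        k12 = [gid for gid, k in counts.items() if k >= 12]
        assert k0 and all(means[g] == p.mu0 for g in k0)
        assert all(means[g] == p.mu0 + 10 * p.gamma for g in k12)

    def test_group_mean_expression_non_decreasing_in_enhancer_count(self, looped_world):
        _, genes, truth = looped_world
        _, expr = syn.simulate_peaks_expression(truth, genes, seed=14)
        counts = syn.planted_enhancer_counts(truth, genes, "neuron")
        ks = np.array([min(counts[g.gene_id], 10) for g in genes])
        vals = expr["neuron"].to_numpy()
        group_means = [vals[ks == k].mean() for k in sorted(set(ks)) if (ks == k).sum() >= 3]
        diffs = np.diff(group_means)
        # allow small noise wiggles but require overall monotone trend
        assert (diffs > -1.0).all()
        assert group_means[-1] > group_means[0]


class TestSnps:
    @pytest.fixture()
    def world(self):
        grid, genes = syn.generate_genome(1, 10_000_000, 10_000, 100, seed=21)
        truth = syn.plant_truth(grid, genes=genes, params=flat_params(loop_boost=2.0),
                                seed=22, n_fires_specific=0, n_fires_common=0)
        return grid, genes, truth

    def test_same_seed_gives_identical_table(self, world):
        _, genes, truth = world
        t1, _ = syn.simulate_snps(truth, genes, 60, seed=5)
        t2, _ = syn.simulate_snps(truth, genes, 60, seed=5)
        assert t1.equals(t2)

    def test_promoter_snps_truth_is_their_gene(self, world):
        _, genes, truth = world
        table, labels = syn.simulate_snps(truth, genes, 80, seed=6)
        by_id = {g.gene_id: g for g in genes}
        n_checked = 0
        for row in table.itertuples():
            lab = labels[row.rsid]
            if lab["category"] != "promoter":
                continue
            pos0 = row.pos - 1
            for ct, gene_ids in lab["genes"].items():
                assert gene_ids
                assert any(
                    by_id[g].promoter[0] <= pos0 < by_id[g].promoter[1] for g in gene_ids
                )
            n_checked += 1
        assert n_checked > 0

    def test_intergenic_snp_without_loop_has_empty_truth(self, world):
        grid, genes, truth = world
        table, labels = syn.simulate_snps(truth, genes, 80, seed=7)
        looped_bins = {
            b for ct in truth.cell_types
            for (p, t) in truth.loops[ct]["chr1"]
            for b in (p, t)
        }
        seen = 0
        for row in table.itertuples():
            lab = labels[row.rsid]
            if lab["category"] != "intergenic":
                continue
            if (row.pos - 1) // grid.resolution in looped_bins:
                continue
            for ct in truth.cell_types:
                assert lab["genes"][ct] == []
            seen += 1
        assert seen > 0

    def test_truth_serializes_to_json(self, world):
        _, genes, truth = world
        syn.simulate_snps(truth, genes, 12, seed=8)
        blob = truth.to_json()
        assert "tad_domains" in blob and "snp_truth" in blob
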