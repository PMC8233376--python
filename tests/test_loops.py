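import numpy as np
import pytest
from scipy import stats

from chromacell import loops as lp, synthetic as syn
from chromacell.errors import InsufficientDataError, ParameterError
from chromacell.genome import BinGrid, BinTrack
from chromacell.tads import TadCall

from oracles import intervals_overlap


class TestWeibullFit:
    def test_survival_closed_form_exponential(self):
        fit = lp.WeibullFit(1.0, 1.0, (), 100, "mle")
        assert fit.survival(np.log(2)) == pytest.approx(0.5)
        assert fit.survival(0.0) == 1.0

    def test_parameters_recovered_from_samples(self, rng):
        x = stats.weibull_min.rvs(1.5, scale=2.0, size=2000, random_state=rng)
        fit = lp.fit_weibull(x)
        assert fit.fit_method == "mle"
        assert fit.shape == pytest.approx(1.5, rel=0.1)
        assert fit.scale == pytest.approx(2.0, rel=0.1)

    def test_fixed_shape_one_gives_sample_mean_scale(self, rng):
        x = rng.exponential(3.0, 500)
        fit = lp.fit_weibull(x, fix_shape=1.0)
        assert fit.scale == pytest.approx(x[x > 0].mean())

    def test_all_zero_input_rejected(self):
        with pytest.raises(InsufficientDataError):
            lp.fit_weibull(np.zeros(100))

    def test_too_few_nonzero_values_rejected(self):
        with pytest.raises(InsufficientDataError):
            lp.fit_weibull(np.array([1.0, 2.0, 0.0]), min_n=30)

    def test_zeros_dropped_before_fit(self, rng):
        x = rng.exponential(3.0, 500)
        with_zeros = np.concatenate([x, np.zeros(200)])
        a = lp.fit_weibull(x, fix_shape=1.0)
        b = lp.fit_weibull(with_zeros, fix_shape=1.0)
        assert a.scale == pytest.approx(b.scale)

    def test_negative_values_rejected(self):
        with pytest.raises(ParameterError):
            lp.fit_weibull(np.array([-1.0, 2.0]))


class TestBackgroundAnchors:
    @pytest.fixture()
    def world(self, rng):
        grid = BinGrid({"chr1": 5_000_000}, 10_000)
        gc = BinTrack("chr1", grid, np.clip(rng.normal(0.45, 0.05, 500), 0.3, 0.6))
        promoters = list(range(0, 500, 25))
        return grid, gc, promoters

    def test_anchors_satisfy_gc_tolerance_and_exclude_promoters(self, world):
        grid, gc, promoters = world
        anchors = lp.sample_background_anchors(promoters, grid, gc, gc_tol=0.02, seed=1)
        assert not set(anchors) & set(promoters)
        # each anchor matches at least one promoter's GC within the base tolerance
        # (relaxation may widen individual pools up to 3x)
        for a in anchors:
            assert min(abs(gc.values[a] - gc.values[p]) for p in promoters) <= 0.06

    def test_same_seed_gives_identical_anchor_set(self, world):
        grid, gc, promoters = world
        a = lp.sample_background_anchors(promoters, grid, gc, seed=5)
        b = lp.sample_background_anchors(promoters, grid, gc, seed=5)
        assert np.array_equal(a, b)

    def test_uniform_gc_makes_constraint_vacuous(self, world):
        grid, _, promoters = world
        gc = BinTrack("chr1", grid, np.full(500, 0.45))
        anchors = lp.sample_background_anchors(promoters, grid, gc, n_per_promoter=10, seed=2)
        # a uniform track gives every promoter the full non-promoter pool
        assert len(anchors) > 100

    def test_unsatisfiable_pool_rejected(self):
        grid = BinGrid({"chr1": 100_000}, 10_000)
        gc = BinTrack("chr1", grid, np.linspace(0.3, 0.6, 10))
        with pytest.raises(InsufficientDataError):
            lp.sample_background_anchors([0], grid, gc, n_per_promoter=50, seed=3)


@pytest.fixture(scope="module")
def loop_world():
    """Planted-loop scenario at 10 kb used across calling tests."""
    grid, genes = syn.generate_genome(1, 12_000_000, 10_000, 200, seed=7)
    params = syn.GeneratorParams(
        L=1000.0, alpha=1.0, beta=0.0, tad_boost=1.0, fire_boost=1.0,
        loop_boost=3.0, pixel_weibull_shape=3.5,
    )
    truth = syn.plant_truth(grid, genes=genes, params=params, seed=8,
                            n_fires_specific=0, n_fires_common=0,
                            max_loops_per_promoter=2)
    cm = syn.simulate_contact_map(grid, truth, "neuron", seed=9)
    _gd, gc = syn.simulate_bin_tracks(truth, "chr1", seed=10)
    prom_bins = sorted({grid.bin_index("chr1", g.tss) for g in genes})
    bg = lp.sample_background_anchors(prom_bins, grid, gc, seed=11)
    return grid, genes, truth, cm, prom_bins, bg


class TestCallPromoterLoops:
    def test_zero_observed_has_p_one(self, loop_world):
        grid, _, _, cm, prom_bins, bg = loop_world
        tested = lp.call_promoter_loops(cm, prom_bins, bg, return_all=True)
        zeros = [t for t in tested if t.observed == 0]
        assert zeros and all(t.p == 1.0 for t in zeros)

    def test_raising_observed_never_increases_p(self, loop_world):
        grid, _, _, cm, prom_bins, bg = loop_world
        fits = lp.fit_background(cm, np.asarray(bg))
        fit = fits[5]
        xs = np.linspace(0, 50, 60)
        sv = fit.survival(xs)
        assert (np.diff(sv) <= 1e-12).all()

    def test_planted_loops_recovered_with_low_false_discovery(self, loop_world):
        grid, _, truth, cm, prom_bins, bg = loop_world
        calls = lp.call_promoter_loops(cm, prom_bins, bg)
        truth_pairs = {frozenset(p) for p in truth.loops["neuron"]["chr1"]}
        called = {frozenset((l.promoter_bin, l.target_bin)) for l in calls}
        tp = len(called & truth_pairs)
        assert tp / len(truth_pairs) >= 0.8
        assert 1 - tp / len(called) <= 0.05

    def test_calls_sorted_and_q_at_least_p(self, loop_world):
        grid, _, _, cm, prom_bins, bg = loop_world
        calls = lp.call_promoter_loops(cm, prom_bins, bg)
        keys = [(l.chrom, l.promoter_bin, l.target_bin) for l in calls]
        assert keys == sorted(keys)
        assert all(l.q >= l.p for l in calls)
        assert all(20_000 <= l.distance <= 2_000_000 for l in calls)

    def test_background_overlapping_promoters_rejected(self, loop_world):
        grid, _, _, cm, prom_bins, bg = loop_world
        with pytest.raises(ParameterError):
            lp.call_promoter_loops(cm, prom_bins, list(bg) + [prom_bins[0]])


class TestClassifyInteractions:
    def test_promoter_promoter_class(self, toy_genes):
        grid = BinGrid({"chr1": 4_000_000}, 40_000)
        # G1 promoter in bin 2, G2 promoter in bin 12
        loop = lp.Loop("chr1", 2, 12, 400_000, observed=5.0, p=1e-5, q=1e-4)
        summary = lp.classify_interactions([loop], [], toy_genes, None, grid)
        assert loop.loop_class == "P-P"
        assert summary["frac_PP"] == 1.0

    def test_within_tad_flag(self, toy_genes):
        grid = BinGrid({"chr1": 4_000_000}, 40_000)
        loop = lp.Loop("chr1", 2, 12, 400_000, observed=5.0, p=1e-5, q=1e-4)
        tads = TadCall("chr1", domains=[(0, 20)])
        lp.classify_interactions([loop], [], toy_genes, tads, grid)
        assert loop.within_tad is True
        tads2 = TadCall("chr1", domains=[(0, 10), (10, 20)])
        lp.classify_interactions([loop], [], toy_genes, tads2, grid)
        assert loop.within_tad is False

    def test_matches_brute_force_oracle_on_random_instances(self, rng):
        from conftest import random_toy_genome

        for _ in range(50):
            grid, genes = random_toy_genome(rng, chrom_len=600_000, n_genes=4)
            n = grid.n_bins("chr1")
            peaks = []
            for k in range(4):
                s = int(rng.integers(0, grid.chrom_sizes["chr1"] - 700))
                peaks.append(("chr1", s, s + 600, f"p{k}"))
            loops = []
            for _k in range(3):
                a, b = sorted(rng.choice(n, size=2, replace=False))
                loops.append(lp.Loop("chr1", int(a), int(b), (b - a) * 10_000,
                                     observed=3.0, p=1e-4, q=1e-3))
            lp.classify_interactions(loops, peaks, genes, None, grid)
            proms = [g.promoter for g in genes]
            enh = [
                (s, e) for (_c, s, e, _n) in peaks
                if not any(intervals_overlap(s, e, a, b) for a, b in proms)
            ]
            for loop in loops:
                a1 = grid.bin_interval("chr1", loop.promoter_bin)
                a2 = grid.bin_interval("chr1", loop.target_bin)
                p1 = any(intervals_overlap(*a1, a, b) for a, b in proms)
                p2 = any(intervals_overlap(*a2, a, b) for a, b in proms)
                if p1 and p2:
                    expect = "P-P"
                else:
                    other = a2 if p1 else a1
                    if any(intervals_overlap(*other, a, b) for a, b in enh):
                        expect = "E-P"
                    else:
                        expect = "other"
                assert loop.loop_class == expect
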