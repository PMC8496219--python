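import numpy as np
import pytest

from tetradqtl.cross_sim import CrossConfig, simulate_counts, simulate_cross
from tetradqtl.genmap import synthetic_yeast_map
from tetradqtl.hmm import infer_genotypes
from tetradqtl.multiqtl import (QTLModel, estimate_effects, fit_model,
                                model_lod_hk, refine_positions, split_data,
                                stepwise_search)
from tetradqtl.scan import genotype_probs, scan_hk

from .test_scan import grid_from_probs

Y_2X2 = np.array([1, 1, 1, 0, 1, 0, 0, 0], dtype=float)
Q_2X2 = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=float)


class TestSplit:
    def test_sizes_and_disjoint_exhaustive(self):
        train, test = split_data(255, 150, seed=1)
        assert len(train) == 150 and len(test) == 105
        assert len(np.intersect1d(train, test)) == 0
        assert np.array_equal(np.sort(np.r_[train, test]), np.arange(255))

    def test_same_seed_same_split(self):
        a = split_data(100, 60, seed=7)
        b = split_data(100, 60, seed=7)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    @pytest.mark.parametrize("n_train", [0, -5, 100, 150])
    def test_bad_sizes_rejected(self, n_train):
        with pytest.raises(ValueError):
            split_data(100, n_train)


class TestFitModel:
    def test_two_by_two_variance_explained(self):
        grid = grid_from_probs(Q_2X2)
        model = QTLModel(loci=[("I", 0.0)])
        fitted = fit_model(grid, Y_2X2, model)
        # RSS_null = 2, RSS_model = 1.5
        assert fitted.variance_explained == pytest.approx(0.25, abs=1e-9)
        assert fitted.fit["rss_null"] == pytest.approx(2.0)
        assert fitted.fit["rss_model"] == pytest.approx(1.5)

    def test_perfect_association(self):
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=float)
        fitted = fit_model(grid_from_probs(Q_2X2), y, QTLModel(loci=[("I", 0.0)]))
        assert fitted.variance_explained == pytest.approx(1.0, abs=1e-9)
        assert fitted.model_lod == pytest.approx(8 * np.log10(2), abs=1e-6)
        assert fitted.fit["p_chi2"] < 0.01 and fitted.fit["p_F"] < 1e-6

    def test_null_locus_not_significant(self, rng):
        q = (rng.random(200) < 0.5).astype(float)
        y = (rng.random(200) < 0.5).astype(float)
        fitted = fit_model(grid_from_probs(q), y, QTLModel(loci=[("I", 0.0)]))
        assert fitted.variance_explained < 0.05
        assert fitted.fit["p_chi2"] > 0.01

    def test_single_class_test_set_rejected(self):
        with pytest.raises(ValueError, match="both phenotype classes"):
            fit_model(grid_from_probs(Q_2X2), np.ones(8), QTLModel(loci=[("I", 0.0)]))

    def test_empty_model_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fit_model(grid_from_probs(Q_2X2), Y_2X2, QTLModel())


class TestEffects:
    def test_two_by_two_table(self):
        eff = estimate_effects(Q_2X2, Y_2X2)
        assert eff.mean_B == pytest.approx(0.75)
        assert eff.se_B == pytest.approx(0.216506350946, abs=1e-9)
        assert eff.mean_W == pytest.approx(0.25)
        assert eff.se_W == pytest.approx(0.216506350946, abs=1e-9)

    def test_all_diploid_zero_se(self):
        eff = estimate_effects(Q_2X2, np.ones(8))
        assert eff.mean_B == 1.0 and eff.se_B == 0.0
        assert eff.mean_W == 1.0 and eff.se_W == 0.0

    def test_absent_allele_class_undefined(self):
        eff = estimate_effects(np.ones(4), np.array([1, 0, 1, 0], dtype=float))
        assert np.isnan(eff.mean_W) and np.isnan(eff.se_W)
        assert eff.mean_B == pytest.approx(0.5)

    def test_posterior_weighting_uses_effective_n(self):
        q = np.array([0.5, 0.5, 0.5, 0.5])
        eff = estimate_effects(q, np.array([1, 1, 0, 0], dtype=float))
        assert eff.n_B == pytest.approx(2.0) and eff.n_W == pytest.approx(2.0)
        assert eff.mean_B == pytest.approx(0.5)


@pytest.fixture(scope="module")
def planted_cross():
    """255-segregant cross with one causal locus on chromosome IV."""
    gmap = synthetic_yeast_map(800)
    causal = gmap.marker_ids[(gmap.chrom_slice("IV").start
                              + gmap.chrom_slice("IV").stop) // 2]
    cfg = CrossConfig(map=gmap, causal_marker=causal, n_tetrads=64)
    rng = np.random.default_rng(21)
    cross = simulate_cross(cfg, rng)
    counts = simulate_counts(cross, cfg, rng)
    g = infer_genotypes(counts, gmap)
    grid = genotype_probs(g, gmap, step_cM=None)
    causal_cm = gmap.pos_cM[cfg.causal_index]
    return grid, cross.phenotype.astype(float), ("IV", causal_cm)


class TestStepwise:
    def test_independent_phenotype_gives_empty_model(self, rng):
        q = rng.random((120, 50))
        y = (rng.random(120) < 0.5).astype(float)
        model = stepwise_search(grid_from_probs(q), y, t_main=3.0)
        assert model.n_loci == 0 and model.penalized_lod == 0.0

    def test_single_planted_locus_recovered(self, planted_cross):
        grid, y, (chrom, causal_cm) = planted_cross
        model = stepwise_search(grid, y, t_main=3.0, chromosomes=["IV", "XIV"])
        assert model.n_loci == 1
        assert model.loci[0][0] == chrom
        assert abs(model.loci[0][1] - causal_cm) < 10.0
        assert not model.interactions

    def test_two_additive_loci_recovered(self, rng):
        gmap = synthetic_yeast_map(400)
        cfg = CrossConfig(map=gmap, causal_marker=gmap.marker_ids[0], n_tetrads=75)
        cross = simulate_cross(cfg, rng)
        g = cross.genotypes
        j4 = (gmap.chrom_slice("IV").start + gmap.chrom_slice("IV").stop) // 2
        j14 = (gmap.chrom_slice("XIV").start + gmap.chrom_slice("XIV").stop) // 2
        # additive liability: strong effects on both allowed chromosomes
        p = 0.05 + 0.45 * g[:, j4] + 0.45 * g[:, j14]
        y = (rng.random(len(p)) < p).astype(float)
        from .conftest import make_genotypes
        gm = make_genotypes(g.astype(np.int8), gmap.marker_ids)
        grid = genotype_probs(gm, gmap, step_cM=None)
        model = stepwise_search(grid, y, t_main=3.0, chromosomes=["IV", "XIV"])
        assert model.n_loci == 2
        assert sorted(c for c, _ in model.loci) == ["IV", "XIV"]

    def test_local_optimum_certificate(self, planted_cross):
        grid, y, _ = planted_cross
        t_main = 3.0
        model = stepwise_search(grid, y, t_main, chromosomes=["IV", "XIV"])
        sub = grid.restrict(["IV", "XIV"])
        idx = [sub.index_of(c, p) for c, p in model.loci]
        assert model.penalized_lod >= 0.0
        for k in range(len(idx)):
            keep = [j for m, j in enumerate(idx) if m != k]
            lod = model_lod_hk(sub.probs[:, keep], y, [])
            assert model.penalized_lod >= lod - t_main * len(keep) - 1e-9

    def test_empty_chromosome_restriction_rejected(self, planted_cross):
        grid, y, _ = planted_cross
        with pytest.raises(ValueError, match="no scan positions"):
            stepwise_search(grid, y, 3.0, chromosomes=["nope"])


class TestRefine:
    def test_converges_to_scan_argmax_from_jittered_start(self, planted_cross):
        grid, y, (chrom, causal_cm) = planted_cross
        peak = scan_hk(grid, y).argmax()
        start = QTLModel(loci=[(chrom, causal_cm + 25.0)])
        refined = refine_positions(grid, y, start)
        assert refined.loci[0] == (peak["chrom"], pytest.approx(peak["pos_cM"]))

    def test_model_lod_nondecreasing(self, planted_cross):
        grid, y, (chrom, causal_cm) = planted_cross
        start = QTLModel(loci=[(chrom, causal_cm + 30.0)])
        idx = grid.index_of(chrom, causal_cm + 30.0)
        lod_before = model_lod_hk(grid.probs[:, [idx]], y, [])
        refined = refine_positions(grid, y, start)
        assert refined.model_lod >= lod_before - 1e-12
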