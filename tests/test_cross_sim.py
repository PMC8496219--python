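import numpy as np
import pytest

from tetradqtl.cross_sim import (CrossConfig, assign_phenotypes, simulate_counts,
                                 simulate_cross, simulate_gametes,
                                 simulate_pools, simulate_selected_spores,
                                 simulate_tetrads)
from tetradqtl.genmap import haldane_r, synthetic_yeast_map

from .conftest import make_map


@pytest.fixture
def cfg(small_map):
    return CrossConfig(map=small_map, causal_marker="I_m2", n_tetrads=10, seed=1)


class TestTetrads:
    def test_two_to_two_segregation_everywhere(self, small_map, rng):
        spores = simulate_tetrads(small_map, 50, rng)
        per_tetrad = spores.reshape(50, 4, small_map.n_markers)
        assert (per_tetrad.sum(axis=1) == 2).all()

    def test_zero_recombination_gives_parental_spores(self, rng):
        gmap = make_map({"I": [5.0, 5.0, 5.0, 5.0]})  # all markers coincident
        spores = simulate_tetrads(gmap, 30, rng)
        # every spore fully parental: constant along the chromosome
        assert (spores.all(axis=1) | (~spores).all(axis=1)).all()
        per_tetrad = spores.reshape(30, 4, -1)
        assert (per_tetrad.sum(axis=1) == 2).all()

    def test_recombinant_fraction_matches_haldane(self, rng):
        gmap = make_map({"I": [0.0, 10.0]})
        spores = simulate_tetrads(gmap, 10_000, rng)
        recomb = (spores[:, 0] != spores[:, 1]).mean()
        assert recomb == pytest.approx(haldane_r(10.0), abs=0.01)

    def test_empty_map_rejected(self, rng):
        import pandas as pd
        from tetradqtl.genmap import GeneticMap
        empty = GeneticMap(pd.DataFrame(columns=["marker_id", "chrom", "pos_bp",
                                                 "allele_B", "allele_W"]))
        with pytest.raises(ValueError, match="empty"):
            simulate_gametes(empty, 4, rng)

    def test_gamete_marginal_is_balanced(self, small_map, rng):
        g = simulate_gametes(small_map, 20_000, rng)
        assert g.mean(axis=0) == pytest.approx(np.full(small_map.n_markers, 0.5),
                                               abs=0.02)


class TestPhenotypes:
    def test_zero_penetrance_all_haploid(self, small_map, rng):
        cfg = CrossConfig(map=small_map, causal_marker="I_m2", n_tetrads=20,
                          penetrance_B=0.0, penetrance_W=0.0)
        cross = simulate_cross(cfg, rng)
        assert (cross.phenotype == 0).all()

    def test_deterministic_penetrance_tracks_genotype(self, small_map, rng):
        cfg = CrossConfig(map=small_map, causal_marker="I_m2", n_tetrads=20,
                          penetrance_B=1.0, penetrance_W=0.0)
        cross = simulate_cross(cfg, rng)
        np.testing.assert_array_equal(
            cross.phenotype, cross.genotypes[:, cfg.causal_index].astype(np.int8))

    def test_population_rate_matches_penetrance_mean(self, small_map):
        # with 2:2 segregation the expected rate is (pB + pW)/2 exactly
        cfg = CrossConfig(map=small_map, causal_marker="I_m2", n_tetrads=65)
        rng = np.random.default_rng(4)
        rates = [simulate_cross(cfg, rng).phenotype.mean() for _ in range(300)]
        assert np.mean(rates) == pytest.approx((0.69 + 0.18) / 2, abs=0.01)

    def test_invalid_penetrance_rejected(self, small_map):
        with pytest.raises(ValueError, match="penetrance"):
            CrossConfig(map=small_map, causal_marker="I_m2", penetrance_B=1.5)

    def test_unknown_causal_marker_rejected(self, small_map):
        with pytest.raises(KeyError):
            CrossConfig(map=small_map, causal_marker="nope")


class TestCounts:
    def test_zero_depth_gives_zero_counts(self, cfg, rng):
        cross = simulate_cross(cfg, rng)
        cfg0 = CrossConfig(map=cfg.map, causal_marker=cfg.causal_marker,
                           n_tetrads=cfg.n_tetrads, mean_depth=0.0)
        counts = simulate_counts(cross, cfg0, rng)
        assert counts.n_B.sum() == 0 and counts.n_W.sum() == 0

    def test_error_free_counts_are_pure(self, cfg, rng):
        cross = simulate_cross(cfg, rng)
        cfg0 = CrossConfig(map=cfg.map, causal_marker=cfg.causal_marker,
                           n_tetrads=cfg.n_tetrads, error_rate=0.0)
        counts = simulate_counts(cross, cfg0, rng)
        assert (counts.n_W[cross.genotypes] == 0).all()
        assert (counts.n_B[~cross.genotypes] == 0).all()

    def test_wrong_allele_fraction_matches_error_rate(self, rng):
        gmap = synthetic_yeast_map(200)
        cfg = CrossConfig(map=gmap, causal_marker=gmap.marker_ids[0],
                          n_tetrads=100, mean_depth=5.0, error_rate=0.005)
        cross = simulate_cross(cfg, rng)
        counts = simulate_counts(cross, cfg, rng)
        wrong = np.where(cross.genotypes, counts.n_W, counts.n_B).sum()
        total = (counts.n_B + counts.n_W).sum()
        assert wrong / total == pytest.approx(0.005, rel=0.15)

    def test_same_seed_bit_identical(self, small_map):
        cfg = CrossConfig(map=small_map, causal_marker="I_m2", n_tetrads=15, seed=9)
        a, b = simulate_cross(cfg), simulate_cross(cfg)
        np.testing.assert_array_equal(a.genotypes, b.genotypes)
        np.testing.assert_array_equal(a.phenotype, b.phenotype)
        ca, cb = simulate_counts(a, cfg), simulate_counts(b, cfg)
        np.testing.assert_array_equal(ca.n_B, cb.n_B)
        np.testing.assert_array_equal(ca.n_W, cb.n_W)


class TestPools:
    def test_pure_pool_fraction_one(self, small_map, rng):
        from tetradqtl.cross_sim import TrueCross
        n = 20
        geno = np.ones((n, small_map.n_markers), dtype=bool)
        cross = TrueCross(geno, np.full(n, -1), [f"s{i}" for i in range(n)], small_map)
        cross.phenotype = np.ones(n, dtype=np.int8)
        cfg = CrossConfig(map=small_map, causal_marker="I_m2", error_rate=0.0)
        pools = simulate_pools(cross, cfg, pool_depth=200, rng=rng)
        assert (pools["n_W"] == 0).all()

    def test_balanced_pool_near_half(self, small_map, rng):
        from tetradqtl.cross_sim import TrueCross
        n = 40
        geno = np.zeros((n, small_map.n_markers), dtype=bool)
        geno[: n // 2] = True
        cross = TrueCross(geno, np.full(n, -1), [f"s{i}" for i in range(n)], small_map)
        cross.phenotype = np.ones(n, dtype=np.int8)
        cfg = CrossConfig(map=small_map, causal_marker="I_m2", error_rate=0.0)
        pools = simulate_pools(cross, cfg, pool_depth=20_000, rng=rng)
        frac = pools["n_B"].sum() / (pools["n_B"] + pools["n_W"]).sum()
        assert frac == pytest.approx(0.5, abs=0.01)

    def test_diploid_pool_enriched_at_causal_locus(self, rng):
        gmap = synthetic_yeast_map(100)
        causal = gmap.marker_ids[50]
        cfg = CrossConfig(map=gmap, causal_marker=causal)
        sel = simulate_selected_spores(cfg, 400, rng)
        pools = simulate_pools(sel, cfg, pool_depth=2000, rng=rng)
        at = pools[pools["marker_id"] == causal].set_index("phenotype")
        f = at["n_B"] / (at["n_B"] + at["n_W"])
        assert f["diploid"] > 0.5 > f["haploid"]

    def test_phenotype_required(self, small_map, rng):
        cfg = CrossConfig(map=small_map, causal_marker="I_m2", n_tetrads=5)
        cross = simulate_cross(cfg, rng)
        cross.phenotype = None
        with pytest.raises(ValueError, match="phenotype"):
            simulate_pools(cross, cfg, 100, rng)
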