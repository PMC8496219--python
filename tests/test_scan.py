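import numpy as np
import pandas as pd
import pytest

from tetradqtl.cross_sim import CrossConfig, simulate_counts, simulate_cross
from tetradqtl.genmap import haldane_r, synthetic_yeast_map
from tetradqtl.hmm import infer_genotypes
from tetradqtl.scan import (ScanGrid, em_binary_scan, genotype_probs,
                            permutation_threshold, scan_binary_em, scan_hk,
                            scan_regressout)

from .conftest import make_genotypes, make_map


def grid_from_probs(q, chrom="I"):
    """Single- or multi-position grid directly from a probability matrix."""
    q = np.atleast_2d(np.asarray(q, dtype=float))
    if q.shape[0] == 1:
        q = q.T
    P = q.shape[1]
    pos = pd.DataFrame({"chrom": chrom, "pos_cM": np.arange(P, dtype=float),
                        "is_marker": True, "marker_id": [f"m{j}" for j in range(P)]})
    return ScanGrid(pos, q, [f"s{i}" for i in range(q.shape[0])])


# the worked 2x2 example: allele B -> 3 diploid / 1 haploid, allele W -> 1/3
Y_2X2 = np.array([1, 1, 1, 0, 1, 0, 0, 0], dtype=float)
Q_2X2 = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=float)


class TestGenotypeProbs:
    def test_called_marker_is_near_certain(self, small_map):
        calls = np.ones((1, small_map.n_markers), dtype=np.int8)
        grid = genotype_probs(make_genotypes(calls, small_map.marker_ids),
                              small_map, step_cM=None, error_rate=0.005)
        assert (grid.probs > 0.99).all()

    def test_midpoint_between_opposite_calls_is_half(self):
        gmap = make_map({"I": [0.0, 20.0]})
        calls = np.array([[1, 0]], dtype=np.int8)
        grid = genotype_probs(make_genotypes(calls, gmap.marker_ids), gmap,
                              step_cM=10.0, error_rate=1e-9)
        j = grid.index_of("I", 10.0)
        assert grid.probs[0, j] == pytest.approx(0.5, abs=1e-6)

    def test_midpoint_between_concordant_calls(self):
        gmap = make_map({"I": [0.0, 20.0]})
        calls = np.array([[1, 1]], dtype=np.int8)
        grid = genotype_probs(make_genotypes(calls, gmap.marker_ids), gmap,
                              step_cM=10.0, error_rate=1e-9)
        j = grid.index_of("I", 10.0)
        r10 = haldane_r(10.0)
        expect = (1 - r10) ** 2 / ((1 - r10) ** 2 + r10 ** 2)
        assert grid.probs[0, j] == pytest.approx(expect, abs=1e-6)
        assert expect == pytest.approx(0.9901639988, abs=1e-9)

    def test_grid_includes_markers_and_lattice(self, small_map):
        calls = np.ones((1, small_map.n_markers), dtype=np.int8)
        grid = genotype_probs(make_genotypes(calls, small_map.marker_ids),
                              small_map, step_cM=1.0)
        chrom1 = grid.positions[grid.positions["chrom"] == "I"]
        assert chrom1["pos_cM"].max() == 40.0 and len(chrom1) == 41
        assert chrom1["is_marker"].sum() == 5

    def test_invalid_step_rejected(self, small_map):
        calls = np.ones((1, small_map.n_markers), dtype=np.int8)
        g = make_genotypes(calls, small_map.marker_ids)
        with pytest.raises(ValueError, match="step"):
            genotype_probs(g, small_map, step_cM=0.0)


class TestClosedFormLod:
    def test_em_matches_binomial_closed_form(self):
        res = scan_binary_em(grid_from_probs(Q_2X2), Y_2X2)
        assert res.lod[0] == pytest.approx(0.454487563006, abs=1e-9)

    def test_hk_matches_ols_closed_form(self):
        res = scan_hk(grid_from_probs(Q_2X2), Y_2X2)
        assert res.lod[0] == pytest.approx(4 * np.log10(4 / 3), abs=1e-9)
        assert res.lod[0] == pytest.approx(0.49975494643, abs=1e-9)

    def test_perfect_association_em(self):
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=float)
        res = scan_binary_em(grid_from_probs(Q_2X2), y)
        assert res.lod[0] == pytest.approx(8 * np.log10(2), abs=1e-6)

    @pytest.mark.parametrize("scan_fn", [scan_binary_em, scan_hk])
    def test_constant_phenotype_gives_zero(self, scan_fn):
        res = scan_fn(grid_from_probs(Q_2X2), np.zeros(8))
        assert res.lod == pytest.approx(np.zeros(1), abs=1e-12)

    @pytest.mark.parametrize("scan_fn", [scan_binary_em, scan_hk])
    def test_constant_probability_gives_zero(self, scan_fn):
        res = scan_fn(grid_from_probs(np.full(8, 0.5)), Y_2X2)
        assert res.lod[0] == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("scan_fn", [scan_binary_em, scan_hk])
    def test_label_swap_invariance(self, scan_fn):
        q = np.array([0.9, 0.8, 0.95, 0.7, 0.2, 0.1, 0.3, 0.15])
        a = scan_fn(grid_from_probs(q), Y_2X2).lod[0]
        b = scan_fn(grid_from_probs(1.0 - q), Y_2X2).lod[0]
        assert a == pytest.approx(b, abs=1e-7)

    def test_lod_nonnegative_on_noise(self, rng):
        q = rng.random((30, 40))
        y = (rng.random(30) < 0.5).astype(float)
        for scan_fn in (scan_binary_em, scan_hk):
            assert (scan_fn(grid_from_probs(q), y).lod >= 0).all()


class TestEMInternals:
    def test_loglik_nondecreasing_over_iterations(self, rng):
        q = rng.random((40, 7))
        y = (rng.random(40) < 0.4).astype(float)
        _, trace = em_binary_scan(q, y, return_trace=True)
        traj = np.array(trace)  # (iters, positions)
        assert (np.diff(traj, axis=0) >= -1e-9).all()


class TestPermutations:
    def test_observed_above_all_permutations(self, rng):
        gmap = synthetic_yeast_map(300)
        cfg = CrossConfig(map=gmap, causal_marker=gmap.marker_ids[150], n_tetrads=40)
        cross = simulate_cross(cfg, rng)
        counts = simulate_counts(cross, cfg, rng)
        g = infer_genotypes(counts, gmap)
        grid = genotype_probs(g, gmap, step_cM=None)
        res = scan_hk(grid, cross.phenotype)
        thr, p, maxes = permutation_threshold(grid, cross.phenotype, n_perm=200,
                                              seed=1, observed_max=res.max_lod)
        assert res.max_lod > maxes.max()
        assert p == pytest.approx(1 / 201)
        assert res.max_lod > thr

    def test_observed_below_all_permutations_p_one(self):
        grid = grid_from_probs(np.tile(Q_2X2, (3, 1)).T.ravel()[:24].reshape(24, 1))
        y = (np.arange(24) % 2).astype(float)
        _, p, _ = permutation_threshold(grid, y, n_perm=100, seed=0,
                                        observed_max=-1.0)
        assert p == 1.0

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError, match="n_perm"):
            permutation_threshold(grid_from_probs(Q_2X2), Y_2X2, n_perm=50)

    def test_em_and_hk_nulls_comparable(self, rng):
        q = rng.random((40, 20))
        y = (rng.random(40) < 0.5).astype(float)
        thr_hk, _, _ = permutation_threshold(grid_from_probs(q), y, n_perm=100,
                                             seed=2, method="hk", observed_max=1.0)
        thr_em, _, _ = permutation_threshold(grid_from_probs(q), y, n_perm=100,
                                             seed=2, method="em", observed_max=1.0)
        assert thr_em == pytest.approx(thr_hk, abs=0.5)


@pytest.fixture(scope="module")
def planted():
    gmap = synthetic_yeast_map(500)
    causal = gmap.marker_ids[(gmap.chrom_slice("IV").start
                              + gmap.chrom_slice("IV").stop) // 2]
    cfg = CrossConfig(map=gmap, causal_marker=causal, n_tetrads=64)
    rng = np.random.default_rng(5)
    cross = simulate_cross(cfg, rng)
    counts = simulate_counts(cross, cfg, rng)
    g = infer_genotypes(counts, gmap)
    grid = genotype_probs(g, gmap, step_cM=None)
    return grid, cross.phenotype.astype(float)


class TestRegressOut:

    def test_self_lod_exactly_zero_hk(self, planted):
        grid, y = planted
        peak = int(np.argmax(scan_hk(grid, y).lod))
        res = scan_regressout(grid, y, peak, method="hk")
        assert res.lod[peak] == pytest.approx(0.0, abs=1e-9)

    def test_self_lod_near_zero_em(self, planted):
        # product-weight joint overstates the covariate/position overlap a
        # little, so the EM self-LOD is small but not exactly zero
        grid, y = planted
        peak = int(np.argmax(scan_hk(grid, y).lod))
        res = scan_regressout(grid, y, peak, method="em")
        assert res.lod[peak] < 0.1

    def test_residual_signal_below_threshold(self, planted):
        grid, y = planted
        peak = int(np.argmax(scan_hk(grid, y).lod))
        thr, _, _ = permutation_threshold(grid, y, n_perm=400, seed=7,
                                          observed_max=np.inf)
        res = scan_regressout(grid, y, peak, method="hk")
        assert res.max_lod < thr

    @pytest.mark.parametrize("method", ["hk", "em"])
    def test_constant_covariate_equals_plain_scan(self, method):
        q = np.column_stack([np.full(8, 0.5), Q_2X2])
        grid = grid_from_probs(q)
        plain = (scan_binary_em if method == "em" else scan_hk)(grid, Y_2X2)
        reg = scan_regressout(grid, Y_2X2, 0, method=method)
        assert reg.lod == pytest.approx(plain.lod, abs=1e-4)
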