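"""Simulation studies that characterize the pipeline end to end.

These drive the package's own components under the study conditions the
cross emulates — 65-tetrad crosses, allele penetrances 0.69/0.18, ~5X
coverage with 0.5% read error — and measure what comes out: the population
diploidization rate, genome-wide type-I error of the permutation threshold,
QTL localization and effect recovery, residual signal after regressing out
the mapped QTL, and pooled-sequencing enrichment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cross_sim import CrossConfig, simulate_counts, simulate_cross, \
    simulate_gametes, simulate_pools, simulate_selected_spores
from .genmap import GeneticMap, synthetic_yeast_map
from .hmm import HMMParams, infer_genotypes
from .multiqtl import estimate_effects, split_data, stepwise_search
from .pools import compare_pools
from .scan import ScanGrid, genotype_probs, permutation_threshold, scan_binary_em, \
    scan_hk, scan_regressout

__all__ = [
    "tetrad_diploidization_rate",
    "null_scan_calibration",
    "recovery_study",
    "pool_enrichment_study",
    "default_causal_marker",
]


def default_causal_marker(gmap: GeneticMap, chrom: str = "IV") -> str:
    """Marker nearest the middle of a chromosome (the planted QTL site)."""
    sl = gmap.chrom_slice(chrom)
    return gmap.marker_ids[(sl.start + sl.stop) // 2]


def tetrad_diploidization_rate(n_reps: int = 1000, n_tetrads: int = 65,
                               penetrance_B: float = 0.69,
                               penetrance_W: float = 0.18,
                               seed=None) -> float:
    """Mean percentage of spore populations that diploidize across replicate
    crosses of ``n_tetrads`` tetrads (4 spores each, strict 2:2 segregation
    at the causal locus)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gmap = synthetic_yeast_map(16)  # one marker per chromosome; causal on IV
    cfg = CrossConfig(map=gmap, causal_marker=default_causal_marker(gmap),
                      n_tetrads=n_tetrads, penetrance_B=penetrance_B,
                      penetrance_W=penetrance_W)
    rates = np.empty(n_reps)
    for i in range(n_reps):
        rates[i] = simulate_cross(cfg, rng).phenotype.mean()
    return float(rates.mean() * 100.0)


def _marker_grid(gmap: GeneticMap, genotypes: np.ndarray) -> ScanGrid:
    """Scan grid at marker positions with fully-observed genotypes."""
    positions = pd.DataFrame({
        "chrom": gmap.df["chrom"], "pos_cM": gmap.pos_cM,
        "is_marker": True, "marker_id": gmap.marker_ids,
    })
    return ScanGrid(positions, genotypes.astype(float),
                    [f"s{i}" for i in range(genotypes.shape[0])])


def null_scan_calibration(n_datasets: int = 1000, n_segregants: int = 100,
                          n_markers: int = 192, n_perm: int = 200,
                          alpha: float = 0.05, seed=None) -> float:
    """Genome-wide type-I error of the permutation threshold under the null.

    Each dataset is a cross with no causal locus (phenotype a fair coin,
    independent of genotype); the observed max LOD is compared against its
    own permutation threshold.  Returns the rejection fraction, which
    should approximate ``alpha``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gmap = synthetic_yeast_map(n_markers)
    rejections = 0
    for _ in range(n_datasets):
        genotypes = simulate_gametes(gmap, n_segregants, rng)
        y = (rng.random(n_segregants) < 0.5).astype(float)
        if y.min() == y.max():  # degenerate null draw: never rejects
            continue
        grid = _marker_grid(gmap, genotypes)
        obs = scan_hk(grid, y).max_lod
        thr, _, _ = permutation_threshold(grid, y, n_perm=n_perm, alpha=alpha,
                                          seed=rng, observed_max=obs)
        rejections += obs > thr
    return rejections / n_datasets


def recovery_study(n_reps: int = 50, n_segregants: int = 255,
                   n_markers: int = 2000, mean_depth: float = 5.0,
                   error_rate: float = 0.005, n_train: int = 150,
                   scan_perm: int = 200, stepwise_perm: int = 400,
                   alpha: float = 0.05, seed=None) -> pd.DataFrame:
    """Replicated end-to-end recovery of a single planted QTL.

    Each replicate simulates a tetrad cross with the causal locus mid
    chromosome IV (penetrances 0.69/0.18), sequences it at ``mean_depth``,
    infers genotypes with the HMM, scans (EM interval mapping), runs the
    stepwise search on a ``n_train``-segregant training split restricted to
    chromosomes IV and XIV, estimates allele effects at the mapped peak,
    and rescans after regressing out the peak.  Returns one row per
    replicate with localization error, model size, effect estimates and
    residual-scan outcome.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gmap = synthetic_yeast_map(n_markers)
    causal = default_causal_marker(gmap)
    n_tetrads = int(np.ceil(n_segregants / 4))
    cfg = CrossConfig(map=gmap, causal_marker=causal, n_tetrads=n_tetrads,
                      mean_depth=mean_depth, error_rate=error_rate)
    causal_cm = gmap.pos_cM[cfg.causal_index]
    rows = []
    for rep in range(n_reps):
        cross = simulate_cross(cfg, rng)
        keep = np.arange(n_segregants)  # trim spare spores from the last tetrad
        cross.genotypes = cross.genotypes[keep]
        cross.phenotype = cross.phenotype[keep]
        cross.segregant_ids = cross.segregant_ids[: n_segregants]
        cross.tetrad_of = cross.tetrad_of[keep]
        counts = simulate_counts(cross, cfg, rng)
        g = infer_genotypes(counts, gmap, HMMParams(error_rate, 0.95))
        grid = genotype_probs(g, gmap, step_cM=None, error_rate=error_rate)
        y = cross.phenotype.astype(float)

        res = scan_binary_em(grid, y)
        peak = res.argmax()
        peak_idx = int(np.argmax(res.lod))
        loc_err = (abs(peak["pos_cM"] - causal_cm) if peak["chrom"] == "IV"
                   else np.inf)

        train, _ = split_data(n_segregants, n_train, rng)
        g_train = grid.subset_segregants(train)
        sub = g_train.restrict(["IV", "XIV"])
        t_main, _, _ = permutation_threshold(sub, y[train], n_perm=stepwise_perm,
                                             alpha=alpha, seed=rng, method="hk",
                                             observed_max=np.inf)
        model = stepwise_search(g_train, y[train], t_main,
                                chromosomes=["IV", "XIV"])

        eff = estimate_effects(grid.probs[:, peak_idx], y)

        thr, _, _ = permutation_threshold(grid, y, n_perm=scan_perm, alpha=alpha,
                                          seed=rng, method="hk",
                                          observed_max=np.inf)
        residual = scan_regressout(grid, y, peak_idx, method="hk")

        rows.append({
            "rep": rep,
            "peak_chrom": peak["chrom"], "peak_cM": float(peak["pos_cM"]),
            "peak_lod": float(peak["lod"]), "loc_error_cM": float(loc_err),
            "model_n_loci": model.n_loci,
            "model_chrom": model.loci[0][0] if model.n_loci else "",
            "mean_B": eff.mean_B, "se_B": eff.se_B,
            "mean_W": eff.mean_W, "se_W": eff.se_W,
            "b_within_2se": abs(eff.mean_B - cfg.penetrance_B) <= 2 * eff.se_B,
            "w_within_2se": abs(eff.mean_W - cfg.penetrance_W) <= 2 * eff.se_W,
            "residual_max_lod": residual.max_lod,
            "threshold": thr,
            "residual_below_threshold": residual.max_lod < thr,
        })
    return pd.DataFrame(rows)


def pool_enrichment_study(n_reps: int = 20, n_spores: int = 367,
                          pool_depth: float = 1000.0, n_markers: int = 100,
                          seed=None) -> dict:
    """Phenotype-sorted pool allele fractions at the causal locus.

    With penetrances pB/pW and balanced alleles, Bayes' rule predicts
    B-allele fractions pB/(pB+pW) in the diploid pool and
    (1-pB)/((1-pB)+(1-pW)) in the haploid pool.  Averages the simulated
    fractions over replicates and reports the two-proportion test from the
    first replicate.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gmap = synthetic_yeast_map(n_markers)
    causal = default_causal_marker(gmap)
    cfg = CrossConfig(map=gmap, causal_marker=causal)
    fd, fh = [], []
    first_test = None
    for _ in range(n_reps):
        sel = simulate_selected_spores(cfg, n_spores, rng)
        pools = simulate_pools(sel, cfg, pool_depth, rng)
        at = pools[pools["marker_id"] == causal].set_index("phenotype")
        f = at["n_B"] / (at["n_B"] + at["n_W"])
        fd.append(float(f["diploid"]))
        fh.append(float(f["haploid"]))
        if first_test is None:
            first_test = compare_pools(pools, causal)[0]
    return {
        "fraction_diploid": float(np.mean(fd)),
        "fraction_haploid": float(np.mean(fh)),
        "comparison": first_test,
        "expected_diploid": cfg.penetrance_B / (cfg.penetrance_B + cfg.penetrance_W),
        "expected_haploid": (1 - cfg.penetrance_B)
        / ((1 - cfg.penetrance_B) + (1 - cfg.penetrance_W)),
    }
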