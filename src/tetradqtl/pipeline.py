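"""End-to-end orchestration: simulate -> genotype -> QC -> scan -> model -> pools.

A single YAML config drives every stage; one global seed expands into
per-stage seeds through a fixed ``numpy.random.SeedSequence`` derivation so
any stage can be reproduced independently.  Every run writes its artifacts
plus a manifest recording package version, parameters and seeds; rerunning
with the same config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as tio
from .cross_sim import CrossConfig, assign_phenotypes, simulate_counts, \
    simulate_cross, simulate_pools, simulate_selected_spores
from .genmap import GeneticMap, synthetic_yeast_map
from .hmm import HMMParams, infer_genotypes
from .multiqtl import estimate_effects, fit_model, refine_positions, split_data, \
    stepwise_search
from .pools import compare_pools
from .qc import QCThresholds, apply_qc
from .scan import genotype_probs, permutation_threshold, scan_binary_em, scan_hk

__all__ = ["PipelineConfig", "run_pipeline", "stage_rngs", "default_config"]

log = logging.getLogger("tetradqtl")

_STAGES = ("simulate", "phenotype", "counts", "pools", "scan", "split", "stepwise")


def stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    """Expand one global seed into independent per-stage generators."""
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STAGES, children)}


@dataclass
class SimulateSection:
    n_tetrads: int = 65
    n_selected: int = 0
    n_markers: int = 2000
    causal_marker: str | None = None  # None: marker nearest the middle of chrom IV
    penetrance_B: float = 0.69
    penetrance_W: float = 0.18
    mean_depth: float = 5.0
    error_rate: float = 0.005
    pool_depth: float = 1000.0


@dataclass
class GenotypeSection:
    error_rate: float = 0.005
    call_threshold: float = 0.95


@dataclass
class QCSection:
    distortion_alpha: float | None = 0.05
    similarity: float | None = 0.90
    crossover_mad_k: float | None = 5.0
    crossover_max_map_factor: float | None = 2.0


@dataclass
class ScanSection:
    method: str = "em"
    step_cM: float | None = None  # None scans at marker positions
    error_rate: float = 0.005
    n_perm: int = 1000
    alpha: float = 0.05


@dataclass
class StepwiseSection:
    n_train: int = 150
    max_qtl: int = 4
    chromosomes: list[str] = field(default_factory=lambda: ["IV", "XIV"])
    n_perm: int = 1000
    t_int: float | None = None


@dataclass
class PipelineConfig:
    seed: int = 0
    map_path: str | None = None  # None: synthetic yeast map
    counts_path: str | None = None  # None: simulate
    phenotype_path: str | None = None
    pools_path: str | None = None
    simulate: SimulateSection = field(default_factory=SimulateSection)
    genotype: GenotypeSection = field(default_factory=GenotypeSection)
    qc: QCSection = field(default_factory=QCSection)
    scan: ScanSection = field(default_factory=ScanSection)
    stepwise: StepwiseSection = field(default_factory=StepwiseSection)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        sections = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for key, val in raw.items():
            if key not in sections:
                raise ValueError(f"unknown config key {key!r}")
            f = sections[key]
            if dataclasses.is_dataclass(f.default_factory() if f.default_factory
                                        is not dataclasses.MISSING else None):
                sub_cls = type(f.default_factory())
                sub_fields = {sf.name for sf in dataclasses.fields(sub_cls)}
                unknown = set(val) - sub_fields
                if unknown:
                    raise ValueError(f"unknown config key {key}.{sorted(unknown)[0]}")
                kwargs[key] = sub_cls(**val)
            else:
                kwargs[key] = val
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.scan.n_perm < 100:
            raise ValueError("scan.n_perm must be >= 100")
        if self.stepwise.n_perm < 100:
            raise ValueError("stepwise.n_perm must be >= 100")
        if self.scan.method not in ("em", "hk"):
            raise ValueError(f"unknown scan method {self.scan.method!r}")
        if not 0 < self.scan.alpha < 1:
            raise ValueError("scan.alpha must be in (0, 1)")
        if self.stepwise.n_train <= 0:
            raise ValueError("stepwise.n_train must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def default_config(**overrides) -> PipelineConfig:
    return PipelineConfig.from_dict(overrides)


def _setup_logging(outdir: Path) -> None:
    log.setLevel(logging.INFO)
    log.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for handler in (logging.StreamHandler(sys.stderr),
                    logging.FileHandler(outdir / "pipeline.log", mode="w")):
        handler.setFormatter(fmt)
        log.addHandler(handler)


def _default_causal(gmap: GeneticMap, chrom: str = "IV") -> str:
    sl = gmap.chrom_slice(chrom)
    mid = (sl.start + sl.stop) // 2
    return gmap.marker_ids[mid]


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute all stages, writing artifacts and a manifest under ``outdir``.

    Returns a bundle with the QC report, scan result, fitted model, allele
    effects and pool comparisons.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    t0 = time.time()
    rngs = stage_rngs(config.seed)

    # --- inputs / simulation ------------------------------------------------
    if config.map_path:
        gmap = tio.read_map(config.map_path)
    else:
        gmap = synthetic_yeast_map(config.simulate.n_markers)
    causal = config.simulate.causal_marker or _default_causal(gmap)
    cross_cfg = CrossConfig(
        map=gmap, causal_marker=causal, n_tetrads=config.simulate.n_tetrads,
        penetrance_B=config.simulate.penetrance_B,
        penetrance_W=config.simulate.penetrance_W,
        mean_depth=config.simulate.mean_depth,
        error_rate=config.simulate.error_rate)

    if config.counts_path:
        counts = tio.read_counts(config.counts_path, gmap)
        pheno_df = tio.read_phenotypes(config.phenotype_path)
        log.info("loaded %d segregants x %d markers from %s",
                 counts.shape[0], counts.shape[1], config.counts_path)
    else:
        cross = simulate_cross(cross_cfg, rngs["simulate"])
        cross.phenotype = assign_phenotypes(cross.genotypes, cross_cfg,
                                            rngs["phenotype"])
        counts = simulate_counts(cross, cross_cfg, rngs["counts"])
        pheno_df = cross.truth_frame()
        tio.write_map(gmap, outdir / "map.tsv")
        tio.write_counts(counts, outdir / "counts.tsv")
        tio.write_phenotypes(pheno_df, outdir / "phenotypes.tsv")
        log.info("simulated %d tetrads (%d spores) at %d markers, causal %s",
                 config.simulate.n_tetrads, counts.shape[0], gmap.n_markers, causal)

    if config.pools_path:
        pool_df = tio.read_pools(config.pools_path)
    elif config.simulate.n_selected > 0:
        sel = simulate_selected_spores(cross_cfg, config.simulate.n_selected,
                                       rngs["pools"])
        pool_df = simulate_pools(sel, cross_cfg, config.simulate.pool_depth,
                                 rngs["pools"])
        tio.write_pools(pool_df, outdir / "pools.tsv")
    else:
        pool_df = None

    # --- genotyping and QC ---------------------------------------------------
    params = HMMParams(config.genotype.error_rate, config.genotype.call_threshold)
    genotypes = infer_genotypes(counts, gmap, params)
    tio.write_genotypes(genotypes, outdir / "genotypes.tsv", outdir / "posteriors.tsv")

    clean, clean_map, qc_report = apply_qc(
        genotypes, gmap,
        QCThresholds(config.qc.distortion_alpha, config.qc.similarity,
                     config.qc.crossover_mad_k, config.qc.crossover_max_map_factor))
    qc_report.actions_frame().to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
    log.info("QC kept %d/%d segregants, %d/%d markers",
             clean.shape[0], genotypes.shape[0], clean.shape[1], genotypes.shape[1])

    y = tio.phenotype_vector(pheno_df, clean.segregant_ids)

    # --- single-QTL scan ------------------------------------------------------
    grid = genotype_probs(clean, clean_map, step_cM=config.scan.step_cM,
                          error_rate=config.scan.error_rate)
    scan_fn = scan_binary_em if config.scan.method == "em" else scan_hk
    result = scan_fn(grid, y)
    threshold, gw_p, _ = permutation_threshold(
        grid, y.values, n_perm=config.scan.n_perm, alpha=config.scan.alpha,
        seed=rngs["scan"], method=config.scan.method, observed_max=result.max_lod)
    result.threshold, result.genomewide_p = threshold, gw_p
    result.n_perm, result.alpha = config.scan.n_perm, config.scan.alpha
    tio.write_scan(result, outdir / "scan.tsv")
    peak = result.argmax()
    log.info("scan peak LOD %.2f at %s:%.1f cM (threshold %.2f, genome-wide p %.4g)",
             peak["lod"], peak["chrom"], peak["pos_cM"], threshold, gw_p)

    # --- stepwise model on a train/test split ---------------------------------
    train_idx, test_idx = split_data(clean.shape[0], config.stepwise.n_train,
                                     rngs["split"])
    g_train = grid.subset_segregants(train_idx)
    g_test = grid.subset_segregants(test_idx)
    y_train = y.values[train_idx]
    y_test = y.values[test_idx]
    chroms = [c for c in config.stepwise.chromosomes if c in clean_map.chromosomes]
    sub = g_train.restrict(chroms) if chroms else g_train
    t_main, _, _ = permutation_threshold(sub, y_train, n_perm=config.stepwise.n_perm,
                                         alpha=config.scan.alpha,
                                         seed=rngs["stepwise"], method="hk",
                                         observed_max=np.inf)
    model = stepwise_search(g_train, y_train, t_main, t_int=config.stepwise.t_int,
                            max_qtl=config.stepwise.max_qtl,
                            chromosomes=chroms or None)
    log.info("stepwise model: %d loci, %d interactions, pLOD %.2f (T_main %.2f)",
             model.n_loci, len(model.interactions), model.penalized_lod, t_main)
    if model.n_loci:
        fitted = fit_model(g_test, y_test, model)
        fitted = refine_positions(g_test, y_test, fitted)
        effects = {}
        for chrom, pos in fitted.loci:
            j = grid.index_of(chrom, pos)
            eff = estimate_effects(grid.probs[:, j], y.values)
            effects[f"{chrom}:{pos:.1f}"] = dataclasses.asdict(eff)
        fitted.effects = effects
        tio.write_model(fitted, outdir / "model.json")
        model = fitted

    # --- pool enrichment -------------------------------------------------------
    pool_tests = None
    if pool_df is not None:
        marker = causal if causal in set(pool_df["marker_id"]) else \
            pool_df["marker_id"].iloc[0]
        pool_tests = compare_pools(pool_df, marker)
        log.info("pool contrast at %s: diploid f_B %.3f vs haploid f_B %.3f (p %.3g)",
                 marker, pool_tests[0].fraction_diploid,
                 pool_tests[0].fraction_haploid, pool_tests[0].p_value)

    manifest = {
        "package": "tetradqtl",
        "version": _version(),
        "seed": config.seed,
        "config": config.to_dict(),
        "elapsed_s": round(time.time() - t0, 2),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")

    return {
        "map": clean_map, "genotypes": clean, "qc": qc_report, "grid": grid,
        "phenotype": y, "scan": result, "model": model, "pool_tests": pool_tests,
        "manifest": manifest,
    }


def _version() -> str:
    from importlib.metadata import PackageNotFoundError, version
    try:
        return version("tetradqtl")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"
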