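#!/usr/bin/env python
"""Multi-QTL model selection: stepwise search (max 4 QTLs, chromosomes IV
and XIV, penalties from 1,000 training permutations) on a 150-segregant
training split, then fit and refine on the held-out segregants and
estimate allele effects.
"""

import json
from pathlib import Path

import numpy as np

from tetradqtl import io as tio
from tetradqtl.multiqtl import (estimate_effects, fit_model, refine_positions,
                                split_data, stepwise_search)
from tetradqtl.pipeline import stage_rngs
from tetradqtl.scan import genotype_probs, permutation_threshold

SEED = 2021
run_dir = Path("scratch/run")
results = Path("results")
rngs = stage_rngs(SEED)

gmap = tio.read_map(run_dir / "map_clean.tsv")
g = tio.read_genotypes(run_dir / "genotypes.tsv", run_dir / "posteriors.tsv")
y = tio.phenotype_vector(tio.read_phenotypes(run_dir / "phenotypes.tsv"),
                         g.segregant_ids).values.astype(float)

grid = genotype_probs(g, gmap, step_cM=None, error_rate=0.005)
train, test = split_data(g.shape[0], 150, rngs["split"])
print(f"training on {len(train)} segregants, testing on {len(test)}")

sub = grid.subset_segregants(train).restrict(["IV", "XIV"])
t_main, _, _ = permutation_threshold(sub, y[train], n_perm=1000, alpha=0.05,
                                     seed=rngs["stepwise"], method="hk",
                                     observed_max=np.inf)
model = stepwise_search(grid.subset_segregants(train), y[train], t_main,
                        max_qtl=4, chromosomes=["IV", "XIV"])
print(f"stepwise (T_main {t_main:.2f}): {model.n_loci} locus/loci "
      f"{model.loci}, interactions {model.interactions}, "
      f"penalized LOD {model.penalized_lod:.2f}")

fitted = fit_model(grid.subset_segregants(test), y[test], model)
refined = refine_positions(grid.subset_segregants(test), y[test], fitted)
fitted = fit_model(grid.subset_segregants(test), y[test], refined)
fitted.penalized_lod = model.penalized_lod
print(f"held-out fit: model LOD {fitted.model_lod:.2f}, variance explained "
      f"{100 * fitted.variance_explained:.1f}% "
      f"(chi2 p {fitted.fit['p_chi2']:.2g}, F p {fitted.fit['p_F']:.2g})")

effects = {}
for chrom, pos in fitted.loci:
    j = grid.index_of(chrom, pos)
    eff = estimate_effects(grid.probs[:, j], y)
    effects[f"{chrom}:{pos:.1f}"] = {
        "mean_B": round(eff.mean_B, 3), "se_B": round(eff.se_B, 3),
        "mean_W": round(eff.mean_W, 3), "se_W": round(eff.se_W, 3),
    }
    print(f"allele effects at {chrom}:{pos:.1f} cM -> "
          f"B {eff.mean_B:.2f} +/- {eff.se_B:.2f}, "
          f"W {eff.mean_W:.2f} +/- {eff.se_W:.2f}")
fitted.effects = effects
tio.write_model(fitted, results / "04_model.json")
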