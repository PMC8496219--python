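#!/usr/bin/env python
"""Bulk-segregant check: B-allele fraction at the mapped locus in the
phenotype-sorted pools of bulk-selected spores, with the diploid-vs-haploid
two-proportion contrast.
"""

import json
from pathlib import Path

from tetradqtl import io as tio
from tetradqtl.pools import allele_fraction, compare_pools

run_dir = Path("scratch/run")
results = Path("results")

pools = tio.read_pools(run_dir / "pools.tsv")
causal = json.loads((results / "01_cross_summary.json").read_text())["causal_marker"]

rows = []
for _, pool in pools[pools["marker_id"] == causal].iterrows():
    af = allele_fraction(pool["n_B"], pool["n_W"])
    rows.append({"pool_id": pool["pool_id"], "phenotype": pool["phenotype"],
                 "fraction_B": round(af.fraction_B, 4),
                 "ci_low": round(af.ci_low, 4), "ci_high": round(af.ci_high, 4),
                 "n_reads": af.n_reads})
    print(f"pool {pool['pool_id']}: B fraction {af.fraction_B:.3f} "
          f"[{af.ci_low:.3f}, {af.ci_high:.3f}] (n={af.n_reads})")

comp = compare_pools(pools, causal)[0]
print(f"diploid vs haploid contrast: chi2 {comp.statistic:.1f}, "
      f"p {comp.p_value:.3g}, direction {'B-enriched in diploids' if comp.direction == 1 else 'other'}")

summary = {"marker": causal, "pools": rows,
           "chi2": round(comp.statistic, 2), "p": comp.p_value,
           "fraction_diploid": round(comp.fraction_diploid, 4),
           "fraction_haploid": round(comp.fraction_haploid, 4)}
(results / "06_pool_enrichment.json").write_text(json.dumps(summary, indent=2) + "\n")
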