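"""Bulk-segregant enrichment at a candidate locus.

Independent segregants are phenotype-sorted, pooled, and sequenced; if the
locus is causal, the allele that raises the phenotype probability is
over-represented among reads from the affected pool.  With allele-specific
penetrances pB and pW and a balanced cross, Bayes' rule gives the expected
pool allele fractions: P(B | affected) = pB / (pB + pW) and
P(B | unaffected) = (1 - pB) / ((1 - pB) + (1 - pW)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint, proportions_chisquare

__all__ = ["AlleleFraction", "PoolComparison", "allele_fraction", "compare_pools"]

POOL_COLUMNS = ["pool_id", "phenotype", "marker_id", "n_B", "n_W"]


@dataclass
class AlleleFraction:
    fraction_B: float
    ci_low: float
    ci_high: float
    n_reads: int


@dataclass
class PoolComparison:
    statistic: float
    p_value: float
    direction: int  # sign(fraction_diploid - fraction_haploid)
    fraction_diploid: float
    fraction_haploid: float
    n_diploid: int
    n_haploid: int
    stratum: str | None = None


def allele_fraction(n_B: int, n_W: int, alpha: float = 0.05,
                    method: str = "wilson") -> AlleleFraction:
    """Fraction of reads matching the B allele with a binomial CI."""
    n = n_B + n_W
    if n <= 0:
        raise ValueError("zero read depth at marker: allele fraction undefined")
    lo, hi = proportion_confint(n_B, n, alpha=alpha, method=method)
    return AlleleFraction(n_B / n, float(lo), float(hi), int(n))


def _marker_counts(pools: pd.DataFrame, marker: str, phenotype: str) -> tuple[int, int]:
    sub = pools[(pools["marker_id"] == marker) & (pools["phenotype"] == phenotype)]
    return int(sub["n_B"].sum()), int(sub["n_W"].sum())


def compare_pools(pools: pd.DataFrame, marker: str, by: str | None = None,
                  correction: bool = False) -> list[PoolComparison]:
    """Two-proportion chi-square contrast of diploid vs haploid pools at a marker.

    Counts are aggregated within each phenotype group (per stratum of
    ``by`` when given); the test is the Pearson chi-square on the pooled
    2x2 table, without continuity correction by default.  Returns one
    comparison per stratum (a single one when ``by`` is None).
    """
    if marker not in set(pools["marker_id"]):
        raise KeyError(f"marker {marker!r} not present in pool counts")
    strata = [None] if by is None else sorted(pools[by].astype(str).unique())
    out = []
    for stratum in strata:
        sub = pools if stratum is None else pools[pools[by].astype(str) == stratum]
        dB, dW = _marker_counts(sub, marker, "diploid")
        hB, hW = _marker_counts(sub, marker, "haploid")
        if dB + dW == 0 or hB + hW == 0:
            raise ValueError("both phenotype groups need reads at the marker")
        f_d = dB / (dB + dW)
        f_h = hB / (hB + hW)
        if f_d == f_h:
            stat, p = 0.0, 1.0
        elif correction:
            from scipy.stats import chi2_contingency
            stat, p, _, _ = chi2_contingency([[dB, dW], [hB, hW]], correction=True)
        else:
            stat, p, _ = proportions_chisquare([dB, hB], [dB + dW, hB + hW])
        out.append(PoolComparison(float(stat), float(p), int(np.sign(f_d - f_h)),
                                  f_d, f_h, dB + dW, hB + hW, stratum))
    return out
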