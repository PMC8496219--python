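"""Two-state hidden Markov genotype inference from sparse allele counts.

Each haploid segregant's genome is a mosaic of B and W parental blocks.  At
~5X coverage many markers have 0-2 reads, so per-marker majority calls are
noisy; the HMM shares information along the chromosome.  States are the two
parental origins; transitions between adjacent markers use the Haldane
recombination fraction of their genetic separation; emissions are binomial
read counts with a symmetric per-read error rate.  Genotypes are called by
thresholding the marginal (forward-backward) posterior, leaving
low-confidence markers missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

from .containers import CALL_B, CALL_MISSING, CALL_W, AlleleCountMatrix, GenotypeMatrix
from .genmap import GeneticMap

__all__ = ["HMMParams", "emission_loglik", "forward_backward", "infer_genotypes"]


@dataclass
class HMMParams:
    """Error rate, calling threshold and the map supplying transition distances."""

    error_rate: float = 0.005
    call_threshold: float = 0.95

    def __post_init__(self):
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if not 0.5 < self.call_threshold <= 1.0:
            raise ValueError("call_threshold must be in (0.5, 1]")


def emission_loglik(n_B, n_W, state: str, error_rate: float):
    """Log-probability of observed counts given a parental-origin state.

    Reads are Binomial(n_B + n_W, 1 - error_rate) on the allele matching the
    state.  Zero-depth markers carry no information (log-likelihood 0 for
    both states).  Accepts scalars or arrays.
    """
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    if state not in ("B", "W"):
        raise ValueError("state must be 'B' or 'W'")
    n_B = np.asarray(n_B)
    n_W = np.asarray(n_W)
    if (n_B < 0).any() or (n_W < 0).any():
        raise ValueError("counts must be non-negative")
    n = n_B + n_W
    k = n_B if state == "B" else n_W
    out = binom.logpmf(k, n, 1.0 - error_rate)
    return float(out) if out.ndim == 0 else out


def forward_backward(log_emit: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Scaled forward-backward posterior for a batch of two-state chains.

    Parameters
    ----------
    log_emit:
        (n_chains, L, 2) log emission likelihoods, state order (W, B).
    r:
        (L - 1,) switch probabilities between adjacent positions.

    Returns (n_chains, L, 2) marginal posteriors with uniform (1/2, 1/2)
    initial state.  Rows whose emissions are all -inf (impossible data,
    only reachable with error_rate = 0) are treated as uninformative.
    """
    n, L, _ = log_emit.shape
    # per-site scaling: subtract the max log emission so exp() is stable
    m = np.max(log_emit, axis=2, keepdims=True)
    finite = np.isfinite(m)
    em = np.exp(log_emit - np.where(finite, m, 0.0))
    em[~np.isfinite(em)] = 0.0
    dead = em.sum(axis=2) == 0.0
    if dead.any():
        em[dead] = 1.0

    alpha = np.empty((n, L, 2))
    a = 0.5 * em[:, 0, :]
    a /= a.sum(axis=1, keepdims=True)
    alpha[:, 0, :] = a
    for t in range(1, L):
        stay = 1.0 - r[t - 1]
        pred = a * stay + a[:, ::-1] * r[t - 1]
        a = pred * em[:, t, :]
        a /= a.sum(axis=1, keepdims=True)
        alpha[:, t, :] = a

    post = np.empty_like(alpha)
    b = np.ones((n, 2))
    post[:, L - 1, :] = alpha[:, L - 1, :]
    for t in range(L - 2, -1, -1):
        x = em[:, t + 1, :] * b
        stay = 1.0 - r[t]
        b = x * stay + x[:, ::-1] * r[t]
        b /= b.sum(axis=1, keepdims=True)
        p = alpha[:, t, :] * b
        post[:, t, :] = p / p.sum(axis=1, keepdims=True)
    return post


def infer_genotypes(counts: AlleleCountMatrix, gmap: GeneticMap,
                    params: HMMParams | None = None) -> GenotypeMatrix:
    """Posterior-decode parental-origin genotypes along each chromosome.

    Chains restart at chromosome boundaries (free recombination between
    chromosomes); calls are B where P(B) >= call_threshold, W where
    P(W) >= call_threshold, otherwise missing.
    """
    params = params or HMMParams()
    if counts.marker_ids != gmap.marker_ids:
        raise ValueError("count matrix markers do not match the map")
    n_seg, n_mark = counts.shape
    posterior_B = np.empty((n_seg, n_mark))
    for chrom in gmap.chromosomes:
        sl = gmap.chrom_slice(chrom)
        r = gmap.recomb_fractions(chrom)
        nB = counts.n_B[:, sl]
        nW = counts.n_W[:, sl]
        log_emit = np.stack([
            emission_loglik(nB, nW, "W", params.error_rate),
            emission_loglik(nB, nW, "B", params.error_rate),
        ], axis=2)
        post = forward_backward(log_emit, r)
        posterior_B[:, sl] = post[:, :, 1]

    calls = np.full((n_seg, n_mark), CALL_MISSING, dtype=np.int8)
    calls[posterior_B >= params.call_threshold] = CALL_B
    calls[1.0 - posterior_B >= params.call_threshold] = CALL_W
    return GenotypeMatrix(calls, posterior_B, list(counts.segregant_ids),
                          list(counts.marker_ids))
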