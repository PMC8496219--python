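"""Single-QTL genome scans for a binary phenotype.

Two scan statistics are provided at every position of a pseudomarker grid:

* ``em`` — interval mapping proper: at each position the likelihood of the
  binary phenotype is a two-component binomial mixture with component
  weights given by the genotype probabilities, maximized over the two
  allele-specific penetrances by EM.
* ``hk`` — Haley-Knott regression: ordinary least squares of the 0/1
  phenotype on the genotype probability, with LOD from the residual sum of
  squares ratio.

Genome-wide significance comes from a permutation null: phenotype labels
are shuffled against whole genotype rows and the (1 - alpha) quantile of
the maximum LOD across the genome is the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CALL_B, CALL_W, GenotypeMatrix, PhenotypeVector
from .genmap import GeneticMap, haldane_r
from .hmm import forward_backward

__all__ = [
    "ScanGrid",
    "ScanResult",
    "genotype_probs",
    "scan_binary_em",
    "scan_hk",
    "scan_regressout",
    "permutation_threshold",
    "em_binary_scan",
    "class_penetrance_em",
]

_LN10 = np.log(10.0)
_TINY = 1e-300


@dataclass
class ScanGrid:
    """Genotype probabilities P(B) for every segregant at every scan position."""

    positions: pd.DataFrame  # columns: chrom, pos_cM, is_marker, marker_id
    probs: np.ndarray  # (n_segregants, n_positions)
    segregant_ids: list[str]

    @property
    def n_positions(self) -> int:
        return self.probs.shape[1]

    def restrict(self, chromosomes) -> "ScanGrid":
        mask = self.positions["chrom"].isin(list(chromosomes)).to_numpy()
        if not mask.any():
            raise ValueError(f"no scan positions on chromosomes {list(chromosomes)!r}")
        return ScanGrid(self.positions[mask].reset_index(drop=True),
                        self.probs[:, mask], self.segregant_ids)

    def subset_segregants(self, idx) -> "ScanGrid":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return ScanGrid(self.positions.copy(), self.probs[idx],
                        [self.segregant_ids[i] for i in idx])

    def index_of(self, chrom: str, pos_cM: float) -> int:
        """Grid index nearest to a (chromosome, cM) coordinate."""
        mask = (self.positions["chrom"] == chrom).to_numpy()
        if not mask.any():
            raise KeyError(f"no scan positions on chromosome {chrom!r}")
        cand = np.flatnonzero(mask)
        return int(cand[np.argmin(np.abs(self.positions["pos_cM"].to_numpy()[cand] - pos_cM))])


@dataclass
class ScanResult:
    """LOD per position plus (optionally) a permutation threshold."""

    table: pd.DataFrame  # chrom, pos_cM, lod
    method: str
    threshold: float | None = None
    genomewide_p: float | None = None
    n_perm: int | None = None
    alpha: float | None = None

    @property
    def lod(self) -> np.ndarray:
        return self.table["lod"].to_numpy()

    def argmax(self) -> pd.Series:
        return self.table.iloc[int(np.argmax(self.lod))]

    @property
    def max_lod(self) -> float:
        return float(self.lod.max())


def _as_phenotype(y) -> np.ndarray:
    if isinstance(y, PhenotypeVector):
        y = y.values
    y = np.asarray(y, dtype=float)
    if not np.isin(y, [0.0, 1.0]).all():
        raise ValueError("phenotype must be binary 0/1")
    return y


def genotype_probs(g: GenotypeMatrix, gmap: GeneticMap, step_cM: float | None = 1.0,
                   error_rate: float = 0.005) -> ScanGrid:
    """P(B) for each segregant on a pseudomarker grid.

    Grid positions are the marker cM positions plus a regular lattice of
    ``step_cM`` (``None`` scans at markers only).  Observed genotype calls
    enter as emissions with per-call error ``error_rate`` (missing calls
    and pure pseudomarkers are uninformative); posteriors come from the same
    forward-backward machinery as the read-count HMM, so probabilities at
    markers blend the call with its neighbors.
    """
    if step_cM is not None and step_cM <= 0:
        raise ValueError("step_cM must be positive (or None for markers only)")
    if g.marker_ids != gmap.marker_ids:
        raise ValueError("genotype matrix markers do not match the map")
    n_seg = g.shape[0]
    log_e, log_1e = np.log(error_rate), np.log1p(-error_rate)

    pos_frames, prob_blocks = [], []
    for chrom in gmap.chromosomes:
        sl = gmap.chrom_slice(chrom)
        cm = np.round(gmap.pos_cM[sl], 6)
        if step_cM is None:
            grid = np.unique(cm)
        else:
            lattice = np.round(np.arange(cm[0], cm[-1] + 1e-9, step_cM), 6)
            grid = np.union1d(cm, lattice)
        L = len(grid)
        marker_at = np.searchsorted(grid, cm)
        # accumulate call emissions; coincident markers sum their evidence
        log_emit = np.zeros((n_seg, L, 2))
        calls = g.calls[:, sl]
        for j, gj in enumerate(marker_at):
            cj = calls[:, j]
            log_emit[cj == CALL_B, gj, 1] += log_1e
            log_emit[cj == CALL_B, gj, 0] += log_e
            log_emit[cj == CALL_W, gj, 0] += log_1e
            log_emit[cj == CALL_W, gj, 1] += log_e
        r = haldane_r(np.diff(grid))
        post = forward_backward(log_emit, r)
        is_marker = np.zeros(L, dtype=bool)
        is_marker[marker_at] = True
        marker_id = np.array([""] * L, dtype=object)
        marker_id[marker_at] = [gmap.marker_ids[sl][j] for j in range(len(cm))]
        pos_frames.append(pd.DataFrame({
            "chrom": chrom, "pos_cM": grid, "is_marker": is_marker,
            "marker_id": marker_id,
        }))
        prob_blocks.append(post[:, :, 1])
    positions = pd.concat(pos_frames, ignore_index=True)
    return ScanGrid(positions, np.concatenate(prob_blocks, axis=1), list(g.segregant_ids))


# ---------------------------------------------------------------------------
# Haley-Knott regression
# ---------------------------------------------------------------------------

def _residualize(covariate: np.ndarray | None, n: int):
    """Annihilator matrix of [1, covariates]; None -> plain centering."""
    if covariate is None:
        return None
    C = np.atleast_2d(np.asarray(covariate, dtype=float))
    if C.shape[0] == n and C.ndim == 2 and C.shape[1] != n:
        X = np.column_stack([np.ones(n), C])
    else:
        X = np.column_stack([np.ones(n), C.T])
    # R = I - X (X'X)^+ X'
    return np.eye(n) - X @ np.linalg.pinv(X)


def _hk_lod_matrix(Y: np.ndarray, Q: np.ndarray, covariate=None) -> np.ndarray:
    """LOD for each phenotype row of Y against each column of Q (HK)."""
    n = Q.shape[0]
    R = _residualize(covariate, n)
    if R is None:
        Yr = Y - Y.mean(axis=1, keepdims=True)
        Qr = Q - Q.mean(axis=0, keepdims=True)
    else:
        Yr = Y @ R
        Qr = R @ Q
    Syy = (Yr * Yr).sum(axis=1)  # (n_pheno,)
    Sxx = (Qr * Qr).sum(axis=0)  # (P,)
    Sxy = Yr @ Qr  # (n_pheno, P)
    with np.errstate(divide="ignore", invalid="ignore"):
        rss1 = Syy[:, None] - np.where(Sxx > 1e-12, Sxy ** 2 / np.maximum(Sxx, 1e-12), 0.0)
    rss1 = np.maximum(rss1, _TINY)
    with np.errstate(divide="ignore", invalid="ignore"):
        lod = 0.5 * n * np.log10(np.maximum(Syy[:, None], _TINY) / rss1)
    lod[Syy <= 1e-12, :] = 0.0
    return np.maximum(lod, 0.0)


def scan_hk(grid: ScanGrid, y, covariate=None) -> ScanResult:
    """Haley-Knott regression scan: LOD = (n/2) log10(RSS0 / RSS1)."""
    y = _as_phenotype(y)
    lod = _hk_lod_matrix(y[None, :], grid.probs, covariate=covariate)[0]
    table = grid.positions[["chrom", "pos_cM"]].copy()
    table["lod"] = lod
    return ScanResult(table, "hk")


# ---------------------------------------------------------------------------
# EM interval mapping (binomial mixture)
# ---------------------------------------------------------------------------

def _bernoulli_ll(y: np.ndarray) -> float:
    ybar = y.mean()
    if ybar <= 0.0 or ybar >= 1.0:
        return 0.0
    n1 = y.sum()
    n0 = len(y) - n1
    return float(n1 * np.log(ybar) + n0 * np.log(1.0 - ybar))


def em_binary_scan(Q: np.ndarray, y: np.ndarray, tol: float = 1e-8,
                   max_iter: int = 1000, return_trace: bool = False):
    """Maximized mixture log-likelihood at every position (vectorized EM).

    Q is (n, P) with q_i = P(B) at each position; the likelihood at a
    position is prod_i [ q_i f(y_i; p_B) + (1 - q_i) f(y_i; p_W) ] with
    Bernoulli components, maximized over (p_B, p_W).  Penetrances start at
    the phenotype mean +/- 0.1 (clamped into (0, 1)) and EM stops when no
    position's log-likelihood improves by more than ``tol``.
    """
    y = np.asarray(y, dtype=float)
    n, P = Q.shape
    ybar = y.mean()
    trace: list[np.ndarray] = []
    if ybar <= 0.0 or ybar >= 1.0:
        ll = np.zeros(P)
        return (ll, trace) if return_trace else ll
    pB = np.full(P, min(max(ybar + 0.1, 1e-6), 1 - 1e-6))
    pW = np.full(P, min(max(ybar - 0.1, 1e-6), 1 - 1e-6))
    y1 = y[:, None] == 1.0
    ll_prev = None
    for _ in range(max_iter):
        fB = np.where(y1, pB, 1.0 - pB)
        fW = np.where(y1, pW, 1.0 - pW)
        a = Q * fB
        den = a + (1.0 - Q) * fW
        den = np.maximum(den, _TINY)
        ll = np.log(den).sum(axis=0)
        if return_trace:
            trace.append(ll.copy())
        if ll_prev is not None and np.max(np.abs(ll - ll_prev)) < tol:
            break
        ll_prev = ll
        w = a / den
        sw = w.sum(axis=0)
        swc = n - sw
        pB = np.clip((w * y[:, None]).sum(axis=0) / np.maximum(sw, _TINY), 1e-12, 1 - 1e-12)
        pW = np.clip(((1 - w) * y[:, None]).sum(axis=0) / np.maximum(swc, _TINY), 1e-12, 1 - 1e-12)
    return (ll, trace) if return_trace else ll


def class_penetrance_em(W: np.ndarray, y: np.ndarray, tol: float = 1e-8,
                        max_iter: int = 1000) -> tuple[float, np.ndarray]:
    """Maximized log-likelihood of a k-class penetrance mixture.

    W is (n, k) with rows summing to 1: each segregant's probability of
    belonging to each genotype class; the phenotype is Bernoulli(p_class).
    Initializing every class at the phenotype mean makes the starting
    likelihood equal the null, so the maximized value can never fall below
    it (EM monotonicity).
    """
    y = np.asarray(y, dtype=float)
    n, k = W.shape
    ybar = y.mean()
    if ybar <= 0.0 or ybar >= 1.0:
        return 0.0, np.full(k, ybar)
    p = np.full(k, ybar)
    ll_prev = None
    for _ in range(max_iter):
        f = np.where(y[:, None] == 1.0, p, 1.0 - p)  # (n, k)
        num = W * f
        den = np.maximum(num.sum(axis=1, keepdims=True), _TINY)
        ll = float(np.log(den).sum())
        if ll_prev is not None and abs(ll - ll_prev) < tol:
            break
        ll_prev = ll
        w = num / den
        sw = w.sum(axis=0)
        p = np.where(sw > _TINY,
                     np.clip((w * y[:, None]).sum(axis=0) / np.maximum(sw, _TINY),
                             1e-12, 1 - 1e-12),
                     ybar)
    return ll, p


def scan_binary_em(grid: ScanGrid, y) -> ScanResult:
    """EM interval-mapping scan; LOD = log10 of the mixture/null likelihood ratio."""
    y = _as_phenotype(y)
    ll = em_binary_scan(grid.probs, y)
    lod = np.maximum((ll - _bernoulli_ll(y)) / _LN10, 0.0)
    table = grid.positions[["chrom", "pos_cM"]].copy()
    table["lod"] = lod
    return ScanResult(table, "em")


def _em_covariate_lod(Q: np.ndarray, y: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    """EM scan with a mapped QTL's genotype as a covariate class in both models.

    The null is a two-class penetrance mixture weighted by the covariate's
    genotype probabilities; the alternative at each position is the
    four-cell (covariate x position) mixture with product weights.  The
    null is nested in the alternative, so the LOD is non-negative; at the
    covariate's own position the product weights overstate the joint
    slightly, so the self-LOD is near (not exactly) zero.
    """
    c = np.asarray(covariate, dtype=float)
    n, P = Q.shape
    ll_null, _ = class_penetrance_em(np.column_stack([1.0 - c, c]), y)
    lod = np.empty(P)
    W = np.empty((n, 4))
    for j in range(P):
        q = Q[:, j]
        W[:, 0] = (1.0 - c) * (1.0 - q)
        W[:, 1] = (1.0 - c) * q
        W[:, 2] = c * (1.0 - q)
        W[:, 3] = c * q
        ll, _ = class_penetrance_em(W, y)
        lod[j] = max((ll - ll_null) / _LN10, 0.0)
    return lod


def scan_regressout(grid: ScanGrid, y, qtl_index: int, method: str = "hk") -> ScanResult:
    """Rescan with an already-mapped QTL regressed out as a covariate.

    HK adds the QTL's genotype probability as an extra regressor in both
    null and full models (its self-LOD is exactly zero); EM carries the
    covariate genotype as a mixture class in both likelihoods (self-LOD
    near zero).
    """
    y = _as_phenotype(y)
    covariate = grid.probs[:, qtl_index]
    if method == "hk":
        if np.ptp(covariate) < 1e-12:
            return scan_hk(grid, y)
        return ScanResult(scan_hk(grid, y, covariate=covariate).table, "hk")
    elif method == "em":
        lod = _em_covariate_lod(grid.probs, y, covariate)
        table = grid.positions[["chrom", "pos_cM"]].copy()
        table["lod"] = lod
        return ScanResult(table, "em")
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Permutation thresholds
# ---------------------------------------------------------------------------

def permutation_threshold(grid: ScanGrid, y, n_perm: int = 1000, alpha: float = 0.05,
                          seed=None, method: str = "hk", covariate=None,
                          observed_max: float | None = None):
    """Genome-wide max-LOD permutation null.

    Phenotypes are permuted jointly against whole genotype rows
    (unstratified).  Returns ``(threshold, genomewide_p, perm_maxes)``:
    the (1 - alpha) quantile of the permuted maxima and the add-one
    genome-wide p-value (k + 1)/(n_perm + 1) of the observed maximum.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    y = _as_phenotype(y)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if observed_max is None:
        if method == "hk":
            res = (scan_hk(grid, y, covariate=covariate) if covariate is not None
                   else scan_hk(grid, y))
        else:
            res = scan_binary_em(grid, y)
        observed_max = res.max_lod
    Yp = np.empty((n_perm, len(y)))
    for i in range(n_perm):
        Yp[i] = rng.permutation(y)
    if method == "hk":
        maxes = _hk_lod_matrix(Yp, grid.probs, covariate=covariate).max(axis=1)
    elif method == "em":
        maxes = np.empty(n_perm)
        for i in range(n_perm):
            ll = em_binary_scan(grid.probs, Yp[i])
            maxes[i] = np.max(np.maximum((ll - _bernoulli_ll(Yp[i])) / _LN10, 0.0))
    else:
        raise ValueError(f"unknown method {method!r}")
    threshold = float(np.quantile(maxes, 1.0 - alpha))
    k = int((maxes >= observed_max).sum())
    genomewide_p = (k + 1) / (n_perm + 1)
    return threshold, genomewide_p, maxes
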