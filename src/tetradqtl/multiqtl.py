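"""Stepwise multi-QTL model search, held-out fitting, and allele effects.

The search mirrors the classic penalized-LOD stepwise procedure: forward
additions of loci (and pairwise interactions among included loci) followed
by backward deletions, maximizing

    pLOD = LOD(model) - T_main * (#loci) - T_int * (#interactions)

where the penalties come from genome-wide permutation thresholds.  Model
LOD is computed by Haley-Knott multiple regression on genotype
probabilities; held-out evaluation reports both a likelihood-ratio
chi-square (penetrance-class likelihood) and a regression F test, plus the
variance explained on the 0/1 phenotype scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import PhenotypeVector
from .scan import ScanGrid, _as_phenotype, _bernoulli_ll, class_penetrance_em, scan_hk

__all__ = [
    "QTLModel",
    "EffectEstimate",
    "split_data",
    "model_lod_hk",
    "stepwise_search",
    "fit_model",
    "refine_positions",
    "estimate_effects",
]

_LN10 = np.log(10.0)
_TINY = 1e-300


@dataclass
class QTLModel:
    """A multi-locus model: loci as (chrom, pos_cM), interactions as index pairs."""

    loci: list[tuple[str, float]] = field(default_factory=list)
    interactions: list[tuple[int, int]] = field(default_factory=list)
    penalized_lod: float = 0.0
    model_lod: float | None = None
    variance_explained: float | None = None
    effects: dict | None = None
    fit: dict | None = None

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def to_dict(self) -> dict:
        return {
            "loci": [{"chrom": c, "pos_cM": float(p)} for c, p in self.loci],
            "interactions": [list(pair) for pair in self.interactions],
            "penalized_lod": float(self.penalized_lod),
            "model_lod": None if self.model_lod is None else float(self.model_lod),
            "variance_explained": (None if self.variance_explained is None
                                   else float(self.variance_explained)),
            "effects": self.effects,
            "fit": self.fit,
        }


@dataclass
class EffectEstimate:
    """Phenotype mean per allele class with binomial standard errors."""

    mean_B: float
    se_B: float
    n_B: float
    mean_W: float
    se_W: float
    n_W: float


def split_data(n_segregants: int, n_train: int = 150, seed=None):
    """Seeded disjoint, exhaustive train/test split of segregant indices."""
    if n_train <= 0:
        raise ValueError("n_train must be positive")
    if n_train >= n_segregants:
        raise ValueError("n_train must be smaller than the number of segregants")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(n_segregants)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def _design(Q: np.ndarray, interactions) -> np.ndarray:
    cols = [np.ones(Q.shape[0]), *Q.T]
    for i, j in interactions:
        cols.append(Q[:, i] * Q[:, j])
    return np.column_stack(cols)


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def model_lod_hk(Q: np.ndarray, y: np.ndarray, interactions=()) -> float:
    """Haley-Knott model LOD: (n/2) log10(RSS_null / RSS_model)."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    rss0 = float(((y - y.mean()) ** 2).sum())
    if rss0 <= 1e-12 or Q.shape[1] == 0:
        return 0.0
    rss1 = max(_rss(_design(Q, interactions), y), _TINY)
    return max(0.5 * n * np.log10(rss0 / rss1), 0.0)


def _profile_add(grid: ScanGrid, y: np.ndarray, base_idx: list[int],
                 interactions) -> tuple[int, float]:
    """Best position to add to the model; returns (index, resulting model LOD)."""
    n = len(y)
    rss0 = float(((y - y.mean()) ** 2).sum())
    if base_idx:
        X = _design(grid.probs[:, base_idx], interactions)
        R = np.eye(n) - X @ np.linalg.pinv(X)
        yr = R @ y
        Qr = R @ grid.probs
    else:
        yr = y - y.mean()
        Qr = grid.probs - grid.probs.mean(axis=0, keepdims=True)
    syy = float(yr @ yr)
    sxx = (Qr * Qr).sum(axis=0)
    sxy = yr @ Qr
    with np.errstate(divide="ignore", invalid="ignore"):
        rss = syy - np.where(sxx > 1e-12, sxy ** 2 / np.maximum(sxx, 1e-12), 0.0)
    rss = np.maximum(rss, _TINY)
    j = int(np.argmin(rss))
    lod = max(0.5 * n * np.log10(rss0 / rss[j]), 0.0)
    return j, lod


def _plod(lod: float, n_loci: int, n_int: int, t_main: float, t_int: float) -> float:
    return lod - t_main * n_loci - t_int * n_int


def stepwise_search(grid: ScanGrid, y, t_main: float, t_int: float | None = None,
                    max_qtl: int = 4, chromosomes=None) -> QTLModel:
    """Forward/backward stepwise search maximizing penalized LOD.

    ``t_main`` is the per-locus penalty (a genome-wide permutation
    threshold); ``t_int`` the per-interaction penalty (defaults to
    ``t_main``).  ``chromosomes`` restricts the searched positions.  The
    best model visited is returned and then certified to be a local
    optimum: while any single deletion improves pLOD, the deletion is
    taken.
    """
    y = _as_phenotype(y)
    if t_int is None:
        t_int = t_main
    if chromosomes is not None:
        grid = grid.restrict(chromosomes)

    def lod_of(idx, inter):
        return model_lod_hk(grid.probs[:, idx], y, inter)

    def as_model(idx, inter, lod):
        loci = [(grid.positions["chrom"].iat[j], float(grid.positions["pos_cM"].iat[j]))
                for j in idx]
        return QTLModel(loci, list(inter),
                        _plod(lod, len(idx), len(inter), t_main, t_int))

    visited: list[tuple[list[int], list[tuple[int, int]], float]] = [([], [], 0.0)]
    idx: list[int] = []
    inter: list[tuple[int, int]] = []

    # forward phase: best single action (add locus or add interaction)
    while True:
        actions = []
        if len(idx) < max_qtl:
            j, lod = _profile_add(grid, y, idx, inter)
            actions.append((idx + [j], inter, lod))
        for pair in combinations(range(len(idx)), 2):
            if pair not in inter:
                cand = inter + [pair]
                actions.append((idx, cand, lod_of(idx, cand)))
        if not actions:
            break
        best = max(actions, key=lambda a: _plod(a[2], len(a[0]), len(a[1]), t_main, t_int))
        idx, inter = list(best[0]), list(best[1])
        visited.append((idx, inter, best[2]))
        if len(idx) >= max_qtl and len(inter) >= len(idx) * (len(idx) - 1) // 2:
            break

    # backward phase: repeatedly delete the element whose removal is best
    while idx or inter:
        actions = []
        for k in range(len(idx)):
            keep = [j for m, j in enumerate(idx) if m != k]
            # drop interactions touching the removed locus, reindex the rest
            remap = {old: new for new, old in enumerate(m for m in range(len(idx)) if m != k)}
            kept_inter = [(remap[a], remap[b]) for a, b in inter if a != k and b != k]
            actions.append((keep, kept_inter, lod_of(keep, kept_inter)))
        for k in range(len(inter)):
            kept = [p for m, p in enumerate(inter) if m != k]
            actions.append((idx, kept, lod_of(idx, kept)))
        best = max(actions, key=lambda a: _plod(a[2], len(a[0]), len(a[1]), t_main, t_int))
        idx, inter = list(best[0]), list(best[1])
        visited.append((idx, inter, best[2]))

    best_idx, best_inter, best_lod = max(
        visited, key=lambda v: _plod(v[2], len(v[0]), len(v[1]), t_main, t_int))

    # local-optimum certificate: descend while a single deletion improves pLOD
    improved = True
    while improved and (best_idx or best_inter):
        improved = False
        cur = _plod(best_lod, len(best_idx), len(best_inter), t_main, t_int)
        for k in range(len(best_idx)):
            keep = [j for m, j in enumerate(best_idx) if m != k]
            remap = {old: new for new, old in enumerate(m for m in range(len(best_idx)) if m != k)}
            kept_inter = [(remap[a], remap[b]) for a, b in best_inter if a != k and b != k]
            lod = lod_of(keep, kept_inter)
            if _plod(lod, len(keep), len(kept_inter), t_main, t_int) > cur + 1e-12:
                best_idx, best_inter, best_lod = keep, kept_inter, lod
                improved = True
                break
        if improved:
            continue
        for k in range(len(best_inter)):
            kept = [p for m, p in enumerate(best_inter) if m != k]
            lod = lod_of(best_idx, kept)
            if _plod(lod, len(best_idx), len(kept), t_main, t_int) > cur + 1e-12:
                best_inter, best_lod = kept, lod
                improved = True
                break

    model = as_model(best_idx, best_inter, best_lod)
    if model.penalized_lod <= 0.0:
        return QTLModel()
    model.model_lod = best_lod
    return model


def fit_model(grid: ScanGrid, y, model: QTLModel) -> QTLModel:
    """Fit a fixed model on (held-out) data; returns an annotated copy.

    Reports the likelihood-ratio chi-square of the penetrance-class
    likelihood against the phenotype-only null (model LOD on the log10
    scale), the regression F test, variance explained
    1 - RSS_model/RSS_null on the 0/1 scale, and a deviance-based
    alternative.
    """
    if model.n_loci == 0:
        raise ValueError("model is empty")
    y = _as_phenotype(y)
    if len(np.unique(y)) < 2:
        raise ValueError("held-out data must contain both phenotype classes")
    n = len(y)
    idx = [grid.index_of(c, p) for c, p in model.loci]
    Q = grid.probs[:, idx]

    # regression scale
    X = _design(Q, model.interactions)
    rss0 = float(((y - y.mean()) ** 2).sum())
    rss1 = max(_rss(X, y), 0.0)
    ve = 1.0 - rss1 / rss0
    p_model = X.shape[1] - 1
    df_resid = n - X.shape[1]
    if rss1 > 1e-12 and df_resid > 0:
        F = ((rss0 - rss1) / p_model) / (rss1 / df_resid)
        p_F = float(stats.f.sf(F, p_model, df_resid))
    else:
        F, p_F = np.inf, 0.0

    # likelihood scale: penetrance per joint genotype class
    k = 2 ** model.n_loci
    W = np.ones((n, k))
    for m in range(model.n_loci):
        q = Q[:, m]
        bit = (np.arange(k) >> m) & 1
        W *= np.where(bit[None, :] == 1, q[:, None], 1.0 - q[:, None])
    ll_full, _ = class_penetrance_em(W, y)
    ll_null = _bernoulli_ll(y)
    chi2 = max(2.0 * (ll_full - ll_null), 0.0)
    p_chi2 = float(stats.chi2.sf(chi2, df=k - 1))
    model_lod = max((ll_full - ll_null) / _LN10, 0.0)
    ve_deviance = 0.0 if ll_null == 0 else max(1.0 - ll_full / ll_null, 0.0)

    out = QTLModel(list(model.loci), list(model.interactions), model.penalized_lod)
    out.model_lod = model_lod
    out.variance_explained = float(np.clip(ve, 0.0, 1.0))
    out.fit = {
        "chi2": float(chi2), "p_chi2": p_chi2, "df_chi2": k - 1,
        "F": float(F), "p_F": p_F, "df_F": (p_model, df_resid),
        "rss_null": rss0, "rss_model": rss1,
        "variance_explained_deviance": float(ve_deviance),
        "n": n,
    }
    return out


def refine_positions(grid: ScanGrid, y, model: QTLModel, max_sweeps: int = 20) -> QTLModel:
    """Coordinate-wise position refinement: re-profile each locus on its
    chromosome holding the others fixed, until no position moves.

    Model LOD is non-decreasing because each move maximizes the full-model
    LOD over the moved locus's positions (the current position included).
    """
    if model.n_loci == 0:
        raise ValueError("model is empty")
    y = _as_phenotype(y)
    idx = [grid.index_of(c, p) for c, p in model.loci]
    inter = list(model.interactions)
    for _ in range(max_sweeps):
        moved = False
        for m in range(len(idx)):
            chrom = grid.positions["chrom"].iat[idx[m]]
            chrom_pos = np.flatnonzero((grid.positions["chrom"] == chrom).to_numpy())
            others = [j for t, j in enumerate(idx) if t != m]
            best_j, best_lod = idx[m], -np.inf
            # profile the moved locus over its chromosome given the others
            if others or inter:
                for j in chrom_pos:
                    # keep locus order stable so interaction indices stay valid
                    trial_idx = list(idx)
                    trial_idx[m] = int(j)
                    lod = model_lod_hk(grid.probs[:, trial_idx], y, inter)
                    if lod > best_lod:
                        best_lod, best_j = lod, int(j)
            else:
                sub = ScanGrid(grid.positions.iloc[chrom_pos].reset_index(drop=True),
                               grid.probs[:, chrom_pos], grid.segregant_ids)
                res = scan_hk(sub, y)
                jloc = int(np.argmax(res.lod))
                best_j, best_lod = int(chrom_pos[jloc]), float(res.lod[jloc])
            if best_j != idx[m]:
                idx[m] = best_j
                moved = True
        if not moved:
            break
    lod = model_lod_hk(grid.probs[:, idx], y, inter)
    loci = [(grid.positions["chrom"].iat[j], float(grid.positions["pos_cM"].iat[j]))
            for j in idx]
    out = QTLModel(loci, inter, model.penalized_lod)
    out.model_lod = lod  # profile (HK) scale; re-run fit_model for test stats
    out.variance_explained = model.variance_explained
    out.effects = model.effects
    out.fit = model.fit
    return out


def estimate_effects(q: np.ndarray, y) -> EffectEstimate:
    """Phenotype mean per allele at one locus, posterior-weighted.

    ``q`` is P(B) per segregant; carriers contribute with weight q (B) or
    1 - q (W), effective n is the weight sum, and SE is the binomial
    sqrt(p(1-p)/n_eff).  A class with zero carriers gets NaN estimates.
    """
    y = _as_phenotype(y)
    q = np.asarray(q, dtype=float)
    nB = float(q.sum())
    nW = float((1.0 - q).sum())
    if nB > 0:
        mB = float((q * y).sum() / nB)
        seB = float(np.sqrt(mB * (1.0 - mB) / nB))
    else:
        mB = seB = np.nan
    if nW > 0:
        mW = float(((1.0 - q) * y).sum() / nW)
        seW = float(np.sqrt(mW * (1.0 - mW) / nW))
    else:
        mW = seW = np.nan
    return EffectEstimate(mB, seB, nB, mW, seW, nW)
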