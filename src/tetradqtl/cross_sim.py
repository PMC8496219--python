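"""Synthetic two-parent yeast crosses with tetrad structure.

Generates haploid F1 segregants from a BY-like x W303-like cross: meioses
follow a Haldane (no-interference) crossover process, tetrads segregate
exactly 2:2 at every marker, a single causal biallelic locus drives a binary
phenotype through allele-specific penetrances, and sequencing is emulated as
sparse Poisson read depth with a symmetric per-read allele error.  Also
produces phenotype-sorted pooled counts in the style of bulk segregant
analysis.

The defaults emulate the statistical structure of the autodiploidization
cross this package analyzes: 65 tetrads (260 spores), penetrances 0.69
(functional-allele carriers) versus 0.18 (truncated-allele carriers), ~5X
coverage, and a 0.5% per-read allele error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import AlleleCountMatrix, PhenotypeVector
from .genmap import GeneticMap, haldane_r, synthetic_yeast_map

__all__ = [
    "CrossConfig",
    "TrueCross",
    "simulate_gametes",
    "simulate_tetrads",
    "simulate_cross",
    "simulate_selected_spores",
    "assign_phenotypes",
    "simulate_counts",
    "simulate_pools",
]


@dataclass
class CrossConfig:
    """Study-level parameters of a simulated cross.

    penetrance_B / penetrance_W are P(diploidize | allele) for carriers of
    the B (functional) and W (truncated) allele at the causal locus;
    mean_depth is the expected reads per marker per segregant; error_rate is
    the per-read probability of reporting the wrong parental allele.
    """

    map: GeneticMap
    causal_marker: str
    n_tetrads: int = 65
    penetrance_B: float = 0.69
    penetrance_W: float = 0.18
    mean_depth: float = 5.0
    error_rate: float = 0.005
    seed: int | None = None

    def __post_init__(self):
        if self.n_tetrads < 1:
            raise ValueError("n_tetrads must be >= 1")
        for name in ("penetrance_B", "penetrance_W", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be >= 0")
        self.map.marker_index(self.causal_marker)  # raises KeyError if absent

    @property
    def causal_index(self) -> int:
        return self.map.marker_index(self.causal_marker)

    def with_seed(self, seed: int) -> "CrossConfig":
        return replace(self, seed=seed)


@dataclass
class TrueCross:
    """Ground truth of a simulated cross.

    genotypes is boolean (True = B allele); tetrad_of maps each segregant to
    its tetrad index, -1 for bulk-selected spores without tetrad structure.
    """

    genotypes: np.ndarray  # (n_segregants, n_markers) bool
    tetrad_of: np.ndarray  # (n_segregants,) int, -1 = none
    segregant_ids: list[str]
    map: GeneticMap
    phenotype: np.ndarray | None = None  # (n_segregants,) int8, set later

    @property
    def n_segregants(self) -> int:
        return self.genotypes.shape[0]

    def truth_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "segregant_id": self.segregant_ids,
            "tetrad_id": [f"T{t}" if t >= 0 else "none" for t in self.tetrad_of],
        })
        if self.phenotype is not None:
            df["phenotype"] = self.phenotype
        return df


def _require_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def simulate_gametes(gmap: GeneticMap, n: int, rng) -> np.ndarray:
    """Draw n independent haploid gametes (True = B allele) under Haldane.

    Within each chromosome the first marker is B with probability 1/2 and
    the state switches between adjacent markers with the Haldane
    recombination fraction of their cM separation; chromosomes assort
    independently.
    """
    if gmap.n_markers == 0:
        raise ValueError("marker map is empty")
    rng = _require_rng(rng)
    out = np.empty((n, gmap.n_markers), dtype=bool)
    for chrom in gmap.chromosomes:
        sl = gmap.chrom_slice(chrom)
        r = gmap.recomb_fractions(chrom)
        L = sl.stop - sl.start
        start = rng.random(n) < 0.5
        if L == 1:
            out[:, sl] = start[:, None]
            continue
        switches = rng.random((n, L - 1)) < r[None, :]
        # parity of switch count up to each marker gives the state
        flips = np.cumsum(switches, axis=1) % 2 == 1
        states = np.empty((n, L), dtype=bool)
        states[:, 0] = start
        states[:, 1:] = start[:, None] ^ flips
        out[:, sl] = states
    return out


def simulate_tetrads(gmap: GeneticMap, n_tetrads: int, rng) -> np.ndarray:
    """Simulate tetrad-dissected spores, 4 per tetrad, as a (4n, m) bool array.

    Each tetrad is {s1, complement(s1), s2, complement(s2)} for two
    independent Haldane gametes s1, s2, which enforces exact 2:2 segregation
    at every marker while keeping the correct single-spore marginal.
    Chromatid interference is not modeled.
    """
    rng = _require_rng(rng)
    s = simulate_gametes(gmap, 2 * n_tetrads, rng)  # s1/s2 for each tetrad
    out = np.empty((4 * n_tetrads, gmap.n_markers), dtype=bool)
    out[0::4] = s[0::2]
    out[1::4] = ~s[0::2]
    out[2::4] = s[1::2]
    out[3::4] = ~s[1::2]
    return out


def assign_phenotypes(genotypes: np.ndarray, config: CrossConfig, rng) -> np.ndarray:
    """Bernoulli phenotypes from allele-specific penetrances at the causal locus."""
    rng = _require_rng(rng)
    g_causal = genotypes[:, config.causal_index]
    p = np.where(g_causal, config.penetrance_B, config.penetrance_W)
    return (rng.random(len(p)) < p).astype(np.int8)


def simulate_cross(config: CrossConfig, rng=None) -> TrueCross:
    """Full tetrad-spore cross: genotypes, tetrad structure and phenotypes."""
    rng = _require_rng(config.seed if rng is None else rng)
    genotypes = simulate_tetrads(config.map, config.n_tetrads, rng)
    tetrad_of = np.repeat(np.arange(config.n_tetrads), 4)
    ids = [f"T{t}S{s}" for t in range(config.n_tetrads) for s in range(4)]
    cross = TrueCross(genotypes, tetrad_of, ids, config.map)
    cross.phenotype = assign_phenotypes(genotypes, config, rng)
    return cross


def simulate_selected_spores(config: CrossConfig, n_spores: int, rng=None,
                             prefix: str = "S") -> TrueCross:
    """Bulk-isolated spores: independent gametes with no tetrad structure."""
    rng = _require_rng(config.seed if rng is None else rng)
    genotypes = simulate_gametes(config.map, n_spores, rng)
    cross = TrueCross(genotypes, np.full(n_spores, -1), [f"{prefix}{i}" for i in range(n_spores)],
                      config.map)
    cross.phenotype = assign_phenotypes(genotypes, config, rng)
    return cross


def simulate_counts(cross: TrueCross, config: CrossConfig, rng=None) -> AlleleCountMatrix:
    """Sparse sequencing counts: Poisson depth, binomial allele error.

    Depth at each segregant x marker is Poisson(mean_depth); of those reads,
    Binomial(depth, 1 - error_rate) match the true parental allele and the
    remainder are reported as the other allele (symmetric error).
    """
    rng = _require_rng(config.seed if rng is None else rng)
    depth = rng.poisson(config.mean_depth, size=cross.genotypes.shape)
    correct = rng.binomial(depth, 1.0 - config.error_rate)
    wrong = depth - correct
    n_B = np.where(cross.genotypes, correct, wrong)
    n_W = depth - n_B
    return AlleleCountMatrix(n_B, n_W, list(cross.segregant_ids),
                             cross.map.marker_ids)


def simulate_pools(cross: TrueCross, config: CrossConfig, pool_depth: float,
                   rng=None, tags: dict[str, np.ndarray] | None = None) -> pd.DataFrame:
    """Phenotype-sorted pooled sequencing of a set of segregants.

    Segregants are grouped by phenotype (and optional covariate tags, e.g.
    auxotrophy classes); within each pool, each marker's read depth is
    Poisson(pool_depth) and each read reports the B allele with probability
    f_B (1 - eps) + (1 - f_B) eps where f_B is the B-allele frequency among
    pooled segregants.  Returns a long DataFrame with columns pool_id,
    phenotype, tags, marker_id, n_B, n_W.
    """
    if cross.phenotype is None:
        raise ValueError("segregants must have phenotypes before pooling")
    rng = _require_rng(config.seed if rng is None else rng)
    labels = np.where(cross.phenotype == 1, "diploid", "haploid")
    if tags:
        tag_names = sorted(tags)
        tag_cols = np.array([[str(tags[t][i]) for t in tag_names]
                             for i in range(cross.n_segregants)])
    else:
        tag_names, tag_cols = [], np.empty((cross.n_segregants, 0), dtype=str)

    keys = [tuple([labels[i], *tag_cols[i]]) for i in range(cross.n_segregants)]
    frames = []
    for key in sorted(set(keys)):
        members = np.array([k == key for k in keys])
        if not members.any():
            continue
        f_B = cross.genotypes[members].mean(axis=0)
        eps = config.error_rate
        p_B = f_B * (1 - eps) + (1 - f_B) * eps
        depth = rng.poisson(pool_depth, size=cross.genotypes.shape[1])
        n_B = rng.binomial(depth, p_B)
        pool_id = "_".join(key)
        frame = pd.DataFrame({
            "pool_id": pool_id,
            "phenotype": key[0],
            "marker_id": cross.map.marker_ids,
            "n_B": n_B,
            "n_W": depth - n_B,
        })
        for name, val in zip(tag_names, key[1:]):
            frame.insert(2, name, val)
        frames.append(frame)
    if not frames:
        raise ValueError("no segregants to pool")
    return pd.concat(frames, ignore_index=True)
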