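"""Biallelic marker maps for a two-parent haploid yeast cross.

A :class:`GeneticMap` holds the ordered marker loci that segregate between
the two parental backgrounds (labelled ``B`` and ``W``), with physical and
genetic coordinates.  Genetic positions drive the Haldane map function used
both by the meiosis simulator and by the genotype HMM's transition
probabilities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "CM_PER_BP",
    "MAP_COLUMNS",
    "GeneticMap",
    "haldane_r",
    "synthetic_yeast_map",
]

#: Genome-wide average recombination rate for S. cerevisiae, ~1 cM per 2.5 kb.
CM_PER_BP = 1.0 / 2500.0

MAP_COLUMNS = ["marker_id", "chrom", "pos_bp", "pos_cM", "allele_B", "allele_W"]

# Approximate S. cerevisiae chromosome sizes (kb), chromosomes I..XVI.
_YEAST_CHROM_KB = {
    "I": 230, "II": 813, "III": 317, "IV": 1532, "V": 577, "VI": 270,
    "VII": 1091, "VIII": 563, "IX": 440, "X": 746, "XI": 667, "XII": 1078,
    "XIII": 924, "XIV": 784, "XV": 1091, "XVI": 948,
}


def haldane_r(d_cM):
    """Recombination fraction for a genetic distance under the Haldane map.

    r = (1 - exp(-2 d)) / 2 with d in Morgans; accepts scalars or arrays of
    distances in centimorgans.  0 <= r < 0.5, no crossover interference.
    """
    d = np.asarray(d_cM, dtype=float)
    if np.any(d < 0):
        raise ValueError("genetic distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(r) if np.isscalar(d_cM) else r


class GeneticMap:
    """Ordered biallelic markers with physical and genetic coordinates.

    Parameters
    ----------
    df:
        DataFrame with columns ``marker_id, chrom, pos_bp, allele_B,
        allele_W`` and optionally ``pos_cM``.  Markers must be sorted by
        chromosome block and ascending ``pos_bp`` within each block;
        chromosome labels are opaque strings ordered by first appearance.
    cm_per_bp:
        Physical-to-genetic conversion used when ``pos_cM`` is absent.
    """

    def __init__(self, df: pd.DataFrame, cm_per_bp: float = CM_PER_BP):
        df = df.copy().reset_index(drop=True)
        required = {"marker_id", "chrom", "pos_bp", "allele_B", "allele_W"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"marker map missing columns: {sorted(missing)}")
        if "pos_cM" not in df.columns or df["pos_cM"].isna().all():
            df["pos_cM"] = df["pos_bp"].astype(float) * cm_per_bp
        df["chrom"] = df["chrom"].astype(str)
        df["pos_bp"] = df["pos_bp"].astype(int)
        df["pos_cM"] = df["pos_cM"].astype(float)

        if df["marker_id"].duplicated().any():
            dup = df.loc[df["marker_id"].duplicated(), "marker_id"].iloc[0]
            raise ValueError(f"duplicate marker_id: {dup!r}")
        if (df["allele_B"] == df["allele_W"]).any():
            bad = df.loc[df["allele_B"] == df["allele_W"], "marker_id"].iloc[0]
            raise ValueError(f"marker {bad!r} has identical parental alleles")
        if (df["pos_bp"] < 1).any():
            raise ValueError("pos_bp must be >= 1 (1-based coordinates)")

        chroms = df["chrom"].to_numpy()
        first_seen = list(dict.fromkeys(chroms))
        # chromosome blocks must be contiguous and sorted internally
        for c in first_seen:
            idx = np.flatnonzero(chroms == c)
            if not np.array_equal(idx, np.arange(idx[0], idx[-1] + 1)):
                raise ValueError(f"markers of chromosome {c!r} are not contiguous")
            bp = df["pos_bp"].to_numpy()[idx]
            cm = df["pos_cM"].to_numpy()[idx]
            if np.any(np.diff(bp) <= 0):
                raise ValueError(f"pos_bp not strictly increasing on chromosome {c!r}")
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"pos_cM decreasing on chromosome {c!r}")

        extra = [c for c in df.columns if c not in MAP_COLUMNS]
        self.df = df[MAP_COLUMNS + extra]
        self.chromosomes: list[str] = first_seen
        self._marker_index = {m: i for i, m in enumerate(df["marker_id"])}
        self._chrom_slices = {
            c: slice(int(np.flatnonzero(chroms == c)[0]),
                     int(np.flatnonzero(chroms == c)[-1]) + 1)
            for c in first_seen
        }

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_markers(self) -> int:
        return len(self.df)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.df["marker_id"])

    @property
    def pos_cM(self) -> np.ndarray:
        return self.df["pos_cM"].to_numpy()

    def marker_index(self, marker_id: str) -> int:
        try:
            return self._marker_index[marker_id]
        except KeyError:
            raise KeyError(f"unknown marker {marker_id!r}") from None

    def chrom_slice(self, chrom: str) -> slice:
        try:
            return self._chrom_slices[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def chrom_of(self, index: int) -> str:
        return self.df["chrom"].iat[index]

    def recomb_fractions(self, chrom: str) -> np.ndarray:
        """Haldane recombination fraction between adjacent markers of a chromosome."""
        sl = self.chrom_slice(chrom)
        cm = self.pos_cM[sl]
        return haldane_r(np.diff(cm))

    def map_length_cM(self) -> float:
        """Total genetic map length (sum of per-chromosome spans)."""
        return float(sum(self.pos_cM[self.chrom_slice(c)][-1] - self.pos_cM[self.chrom_slice(c)][0]
                         for c in self.chromosomes))

    def subset(self, keep: np.ndarray) -> "GeneticMap":
        """New map restricted to a boolean mask / index array over markers."""
        return GeneticMap(self.df.iloc[np.asarray(keep)].reset_index(drop=True))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"GeneticMap({self.n_markers} markers, "
                f"{len(self.chromosomes)} chromosomes, "
                f"{self.map_length_cM():.0f} cM)")


def synthetic_yeast_map(n_markers: int = 8505, cm_per_bp: float = CM_PER_BP) -> GeneticMap:
    """Deterministic marker map emulating a BY x W303-style SNP panel.

    Markers are spread over the 16 yeast chromosomes proportionally to
    physical chromosome size, evenly spaced within each chromosome, with
    genetic positions at the genome-wide average rate.  Parental alleles
    alternate through the transversion pairs so every marker is biallelic.
    """
    if n_markers < 16:
        raise ValueError("need at least one marker per chromosome (n_markers >= 16)")
    sizes = np.array(list(_YEAST_CHROM_KB.values()), dtype=float)
    alloc = np.maximum(1, np.round(n_markers * sizes / sizes.sum()).astype(int))
    # fix rounding so the total is exact; adjust the largest chromosome
    alloc[np.argmax(alloc)] += n_markers - alloc.sum()
    pairs = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]
    rows = []
    k = 0
    for (chrom, kb), n_c in zip(_YEAST_CHROM_KB.items(), alloc):
        bp = np.linspace(1000, kb * 1000 - 1000, n_c).astype(int)
        bp = np.unique(bp)
        for p in bp:
            a, b = pairs[k % 4]
            rows.append((f"chr{chrom}_{p}", chrom, int(p), a, b))
            k += 1
    df = pd.DataFrame(rows, columns=["marker_id", "chrom", "pos_bp", "allele_B", "allele_W"])
    return GeneticMap(df, cm_per_bp=cm_per_bp)
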