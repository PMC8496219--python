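"""Shared in-memory containers for counts and genotype calls.

Genotype calls are encoded as int8: 1 = B (BY-parent allele), 0 = W
(W303-parent allele), -1 = missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CALL_B = np.int8(1)
CALL_W = np.int8(0)
CALL_MISSING = np.int8(-1)


@dataclass
class AlleleCountMatrix:
    """Per segregant x marker counts of reads matching each parental allele."""

    n_B: np.ndarray  # (n_segregants, n_markers) int
    n_W: np.ndarray
    segregant_ids: list[str]
    marker_ids: list[str]

    def __post_init__(self):
        self.n_B = np.asarray(self.n_B, dtype=np.int64)
        self.n_W = np.asarray(self.n_W, dtype=np.int64)
        if self.n_B.shape != self.n_W.shape:
            raise ValueError("n_B and n_W shapes differ")
        if self.n_B.shape != (len(self.segregant_ids), len(self.marker_ids)):
            raise ValueError("count matrix shape does not match id lists")
        if (self.n_B < 0).any() or (self.n_W < 0).any():
            raise ValueError("read counts must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.n_B.shape

    def to_long_frame(self) -> pd.DataFrame:
        n_seg, n_mark = self.shape
        return pd.DataFrame({
            "segregant_id": np.repeat(self.segregant_ids, n_mark),
            "marker_id": np.tile(self.marker_ids, n_seg),
            "n_B": self.n_B.ravel(),
            "n_W": self.n_W.ravel(),
        })


@dataclass
class GenotypeMatrix:
    """Called parental-origin genotypes with posterior probabilities.

    ``calls`` holds 1/0/-1 for B/W/missing; ``posterior_B`` the marginal
    posterior probability of the B state at each marker.
    """

    calls: np.ndarray  # (n_segregants, n_markers) int8
    posterior_B: np.ndarray  # float in [0, 1]
    segregant_ids: list[str]
    marker_ids: list[str]

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.posterior_B = np.asarray(self.posterior_B, dtype=float)
        if self.calls.shape != self.posterior_B.shape:
            raise ValueError("calls and posterior shapes differ")
        if self.calls.shape != (len(self.segregant_ids), len(self.marker_ids)):
            raise ValueError("genotype matrix shape does not match id lists")
        if ((self.posterior_B < 0) | (self.posterior_B > 1)).any():
            raise ValueError("posterior_B outside [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.calls.shape

    @property
    def called(self) -> np.ndarray:
        return self.calls != CALL_MISSING

    def missing_fraction(self) -> np.ndarray:
        """Per-segregant fraction of missing calls."""
        return (self.calls == CALL_MISSING).mean(axis=1)

    def subset(self, seg_keep=None, marker_keep=None) -> "GenotypeMatrix":
        seg_idx = np.arange(self.shape[0]) if seg_keep is None else np.asarray(seg_keep)
        mark_idx = np.arange(self.shape[1]) if marker_keep is None else np.asarray(marker_keep)
        if seg_idx.dtype == bool:
            seg_idx = np.flatnonzero(seg_idx)
        if mark_idx.dtype == bool:
            mark_idx = np.flatnonzero(mark_idx)
        return GenotypeMatrix(
            self.calls[np.ix_(seg_idx, mark_idx)],
            self.posterior_B[np.ix_(seg_idx, mark_idx)],
            [self.segregant_ids[i] for i in seg_idx],
            [self.marker_ids[j] for j in mark_idx],
        )


@dataclass
class PhenotypeVector:
    """Binary ploidy phenotype per segregant (0 = haploid, 1 = diploid)."""

    values: np.ndarray
    segregant_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int8)
        if not np.isin(self.values, [0, 1]).all():
            raise ValueError("phenotype must be binary 0/1")
        if self.segregant_ids and len(self.segregant_ids) != len(self.values):
            raise ValueError("phenotype length does not match id list")
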