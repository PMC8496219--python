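"""Pre-mapping diagnostics: segregation distortion, clone detection, crossover outliers.

These probes guard the QTL scan against artifacts: markers whose allele
ratio departs from the Mendelian 1:1 (mapping bias, CNV, selection),
segregant pairs with anomalously similar genotypes (cross-contamination or
accidental duplicates), and segregants with implausible crossover counts
(genotyping failures).  QC only removes rows/columns; it never edits calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CALL_MISSING, GenotypeMatrix
from .genmap import GeneticMap

__all__ = [
    "QCThresholds",
    "QCReport",
    "segregation_distortion",
    "genotype_similarity",
    "crossover_counts",
    "apply_qc",
]


@dataclass
class QCThresholds:
    """Filter settings; set a field to None to disable that filter.

    distortion_alpha is the family-wise level for the 1:1 chi-square test
    (Bonferroni-corrected over markers); similarity is the pairwise identity
    fraction above which a pair is treated as duplicates; crossover outliers
    exceed median + mad_k * MAD or max_map_factor times the expected
    crossover count (map length in Morgans).
    """

    distortion_alpha: float | None = 0.05
    similarity: float | None = 0.90
    crossover_mad_k: float | None = 5.0
    crossover_max_map_factor: float | None = 2.0


@dataclass
class QCReport:
    distortion: pd.DataFrame
    similar_pairs: pd.DataFrame
    crossovers: pd.DataFrame
    dropped_markers: pd.DataFrame
    dropped_segregants: pd.DataFrame
    thresholds: QCThresholds = field(default_factory=QCThresholds)

    def actions_frame(self) -> pd.DataFrame:
        """Flat table of every removal: entity, id, statistic, threshold, reason."""
        frames = []
        if len(self.dropped_markers):
            f = self.dropped_markers.copy()
            f.insert(0, "entity", "marker")
            frames.append(f.rename(columns={"marker_id": "id"}))
        if len(self.dropped_segregants):
            f = self.dropped_segregants.copy()
            f.insert(0, "entity", "segregant")
            frames.append(f.rename(columns={"segregant_id": "id"}))
        if not frames:
            return pd.DataFrame(columns=["entity", "id", "statistic", "threshold", "reason"])
        return pd.concat(frames, ignore_index=True)


def segregation_distortion(g: GenotypeMatrix) -> pd.DataFrame:
    """Chi-square goodness of fit of per-marker B:W calls against 1:1 (1 df).

    Missing calls are excluded; markers with < 2 calls get NaN statistics
    and are flagged for removal rather than tested.
    """
    called = g.called
    n_B = ((g.calls == 1) & called).sum(axis=0).astype(float)
    n_W = ((g.calls == 0) & called).sum(axis=0).astype(float)
    n = n_B + n_W
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(n > 0, (n_B - n_W) ** 2 / n, np.nan)
    p = stats.chi2.sf(chi2, df=1)
    df = pd.DataFrame({
        "marker_id": g.marker_ids,
        "n_B": n_B.astype(int),
        "n_W": n_W.astype(int),
        "chi2": chi2,
        "p": p,
        "untestable": n < 2,
    })
    return df


def genotype_similarity(g: GenotypeMatrix, threshold: float = 0.90) -> pd.DataFrame:
    """Pairwise identity fraction over co-called markers; flags near-clones.

    Pairs with similarity > threshold, or with no co-called markers at all
    (similarity undefined), are flagged.
    """
    if g.shape[0] < 2:
        raise ValueError("need at least two segregants")
    called = g.called.astype(np.float64)
    is_b = ((g.calls == 1) & g.called).astype(np.float64)
    is_w = ((g.calls == 0) & g.called).astype(np.float64)
    co = called @ called.T
    agree = is_b @ is_b.T + is_w @ is_w.T
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(co > 0, agree / co, np.nan)
    iu = np.triu_indices(g.shape[0], k=1)
    pairs = pd.DataFrame({
        "segregant_a": [g.segregant_ids[i] for i in iu[0]],
        "segregant_b": [g.segregant_ids[j] for j in iu[1]],
        "n_cocalled": co[iu].astype(int),
        "similarity": sim[iu],
    })
    pairs["flagged"] = (pairs["n_cocalled"] == 0) | (pairs["similarity"] > threshold)
    return pairs


def crossover_counts(g: GenotypeMatrix, gmap: GeneticMap) -> pd.DataFrame:
    """Per-segregant genome-wide crossover counts from call switches.

    Counts changes between consecutive non-missing calls within each
    chromosome (a switch spanning missing markers counts once).
    """
    if g.marker_ids != gmap.marker_ids:
        raise ValueError("genotype matrix markers do not match the map")
    n_seg = g.shape[0]
    counts = np.zeros(n_seg, dtype=int)
    for chrom in gmap.chromosomes:
        sl = gmap.chrom_slice(chrom)
        calls = g.calls[:, sl]
        for i in range(n_seg):
            row = calls[i][calls[i] != CALL_MISSING]
            if row.size > 1:
                counts[i] += int((np.diff(row) != 0).sum())
    return pd.DataFrame({"segregant_id": g.segregant_ids, "crossovers": counts})


def _crossover_outliers(xo: pd.DataFrame, gmap: GeneticMap,
                        mad_k: float | None, max_map_factor: float | None) -> np.ndarray:
    c = xo["crossovers"].to_numpy(dtype=float)
    flag = np.zeros(len(c), dtype=bool)
    if mad_k is not None:
        med = np.median(c)
        mad = np.median(np.abs(c - med))
        flag |= c > med + mad_k * max(mad, 1.0)  # MAD floor of 1 crossover
    if max_map_factor is not None:
        expected = gmap.map_length_cM() / 100.0
        flag |= c >= max_map_factor * expected
    return flag


def apply_qc(g: GenotypeMatrix, gmap: GeneticMap,
             thresholds: QCThresholds | None = None) -> tuple[GenotypeMatrix, GeneticMap, QCReport]:
    """Run all probes and drop flagged markers / segregants.

    Within a flagged similar pair, the segregant with more missing calls is
    dropped (ties broken toward keeping the lexicographically smaller id).
    Deterministic given thresholds; raises if everything would be removed.
    """
    thresholds = thresholds or QCThresholds()

    dist = segregation_distortion(g)
    drop_marker = np.zeros(g.shape[1], dtype=bool)
    marker_reason = np.array([""] * g.shape[1], dtype=object)
    if thresholds.distortion_alpha is not None:
        drop_marker = dist["untestable"].to_numpy().copy()
        marker_reason = np.where(drop_marker, "untestable (<2 calls)", "")
        cutoff = thresholds.distortion_alpha / g.shape[1]
        bad = dist["p"].to_numpy() < cutoff
        marker_reason = np.where(bad & ~drop_marker, "segregation distortion", marker_reason)
        drop_marker |= bad
    else:
        cutoff = np.nan

    sim_threshold = thresholds.similarity if thresholds.similarity is not None else 1.01
    pairs = genotype_similarity(g, threshold=sim_threshold)
    flagged_pairs = pairs[pairs["flagged"]]
    missing_frac = g.missing_fraction()
    seg_index = {s: i for i, s in enumerate(g.segregant_ids)}
    drop_seg = np.zeros(g.shape[0], dtype=bool)
    seg_reason = np.array([""] * g.shape[0], dtype=object)
    seg_stat = np.full(g.shape[0], np.nan)
    if thresholds.similarity is not None:
        for _, row in flagged_pairs.iterrows():
            ia, ib = seg_index[row["segregant_a"]], seg_index[row["segregant_b"]]
            if drop_seg[ia] or drop_seg[ib]:
                continue  # pair already resolved by an earlier removal
            if missing_frac[ia] > missing_frac[ib]:
                victim = ia
            elif missing_frac[ib] > missing_frac[ia]:
                victim = ib
            else:
                victim = max(ia, ib, key=lambda i: g.segregant_ids[i])
            drop_seg[victim] = True
            seg_reason[victim] = "anomalous similarity"
            seg_stat[victim] = row["similarity"]

    xo = crossover_counts(g, gmap)
    if thresholds.crossover_mad_k is not None or thresholds.crossover_max_map_factor is not None:
        flag = _crossover_outliers(xo, gmap, thresholds.crossover_mad_k,
                                   thresholds.crossover_max_map_factor)
        newly = flag & ~drop_seg
        seg_reason[newly] = "crossover outlier"
        seg_stat[newly] = xo["crossovers"].to_numpy()[newly]
        drop_seg |= flag

    if drop_marker.all():
        raise ValueError("QC would remove every marker")
    if drop_seg.all():
        raise ValueError("QC would remove every segregant")

    dropped_markers = pd.DataFrame({
        "marker_id": [m for m, d in zip(g.marker_ids, drop_marker) if d],
        "statistic": dist["chi2"].to_numpy()[drop_marker],
        "threshold": cutoff,
        "reason": marker_reason[drop_marker],
    })
    dropped_segregants = pd.DataFrame({
        "segregant_id": [s for s, d in zip(g.segregant_ids, drop_seg) if d],
        "statistic": seg_stat[drop_seg],
        "threshold": np.nan,
        "reason": seg_reason[drop_seg],
    })
    report = QCReport(dist, flagged_pairs.reset_index(drop=True), xo,
                      dropped_markers, dropped_segregants, thresholds)
    clean = g.subset(~drop_seg, ~drop_marker)
    clean_map = gmap.subset(~drop_marker)
    return clean, clean_map, report
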