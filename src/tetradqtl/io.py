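"""Readers and writers for the pipeline's plain-text formats.

All tables are tab-separated with headers; genotype matrices travel as a
segregant x marker grid of B/W/NA cells plus a companion posterior matrix;
scan results carry their permutation threshold in ``#``-prefixed footer
lines; models are JSON.  Marker maps can also be imported from a VCF of
biallelic parent-vs-parent SNPs.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CALL_MISSING, AlleleCountMatrix, GenotypeMatrix, PhenotypeVector
from .genmap import MAP_COLUMNS, GeneticMap
from .scan import ScanResult

__all__ = [
    "read_map", "write_map", "map_from_vcf",
    "read_counts", "write_counts",
    "read_genotypes", "write_genotypes",
    "read_phenotypes", "write_phenotypes",
    "read_pools", "write_pools",
    "read_scan", "write_scan",
    "read_model", "write_model",
]

_CALL_STR = {1: "B", 0: "W", -1: "NA"}
_STR_CALL = {"B": 1, "W": 0, "NA": -1}


def _read_tsv(path, required: set[str], what: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:  # re-raise with file context
        raise ValueError(f"failed to parse {what} file {path}: {exc}") from exc
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{what} file {path} missing columns {sorted(missing)}")
    return df


# -- marker map --------------------------------------------------------------

def read_map(path) -> GeneticMap:
    df = _read_tsv(path, set(MAP_COLUMNS) - {"pos_cM"}, "marker map")
    return GeneticMap(df)


def write_map(gmap: GeneticMap, path) -> None:
    gmap.df[MAP_COLUMNS].to_csv(path, sep="\t", index=False)


def map_from_vcf(path, cm_per_bp=None) -> GeneticMap:
    """Marker map from a VCF of biallelic SNPs between the two parents.

    Only CHROM/POS/REF/ALT are consumed; REF is taken as the B-parent
    allele and ALT as the W-parent allele.  Multi-allelic or non-SNP
    records are skipped with a warning.
    """
    from cyvcf2 import VCF  # optional dependency

    rows = []
    for rec in VCF(str(path)):
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            warnings.warn(f"skipping non-biallelic-SNP record at {rec.CHROM}:{rec.POS}")
            continue
        rows.append((f"{rec.CHROM}_{rec.POS}", rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
    df = pd.DataFrame(rows, columns=["marker_id", "chrom", "pos_bp", "allele_B", "allele_W"])
    kwargs = {} if cm_per_bp is None else {"cm_per_bp": cm_per_bp}
    return GeneticMap(df, **kwargs)


# -- allele counts (long form) ----------------------------------------------

def read_counts(path, gmap: GeneticMap) -> AlleleCountMatrix:
    df = _read_tsv(path, {"segregant_id", "marker_id", "n_B", "n_W"}, "counts")
    unknown = set(df["marker_id"]) - set(gmap.marker_ids)
    if unknown:
        raise ValueError(f"counts file {path} references unknown marker "
                         f"{sorted(unknown)[0]!r}")
    segs = list(dict.fromkeys(df["segregant_id"]))
    seg_idx = {s: i for i, s in enumerate(segs)}
    n_B = np.zeros((len(segs), gmap.n_markers), dtype=np.int64)
    n_W = np.zeros_like(n_B)
    si = df["segregant_id"].map(seg_idx).to_numpy()
    mi = df["marker_id"].map(gmap.marker_index).to_numpy()
    n_B[si, mi] = df["n_B"].to_numpy()
    n_W[si, mi] = df["n_W"].to_numpy()
    return AlleleCountMatrix(n_B, n_W, segs, gmap.marker_ids)


def write_counts(counts: AlleleCountMatrix, path) -> None:
    counts.to_long_frame().to_csv(path, sep="\t", index=False)


# -- genotype matrix ---------------------------------------------------------

def write_genotypes(g: GenotypeMatrix, calls_path, posterior_path=None) -> None:
    calls = pd.DataFrame(
        np.vectorize(_CALL_STR.get)(g.calls),
        index=pd.Index(g.segregant_ids, name="segregant_id"),
        columns=g.marker_ids)
    calls.to_csv(calls_path, sep="\t")
    if posterior_path is not None:
        post = pd.DataFrame(g.posterior_B,
                            index=pd.Index(g.segregant_ids, name="segregant_id"),
                            columns=g.marker_ids)
        post.to_csv(posterior_path, sep="\t", float_format="%.6g")


def read_genotypes(calls_path, posterior_path=None) -> GenotypeMatrix:
    calls_df = pd.read_csv(calls_path, sep="\t", index_col=0, dtype=str,
                           keep_default_na=False)
    try:
        calls = calls_df.apply(lambda c: c.map(_STR_CALL)).to_numpy(dtype=float)
    except Exception as exc:
        raise ValueError(f"malformed genotype cell in {calls_path}: {exc}") from exc
    if np.isnan(calls).any():
        i, j = np.argwhere(np.isnan(calls))[0]
        raise ValueError(f"malformed genotype cell at row {i + 2}, "
                         f"marker {calls_df.columns[j]!r} in {calls_path}")
    calls = calls.astype(np.int8)
    if posterior_path is not None:
        post = pd.read_csv(posterior_path, sep="\t", index_col=0).to_numpy(dtype=float)
    else:
        post = np.where(calls == 1, 1.0, np.where(calls == 0, 0.0, 0.5))
    return GenotypeMatrix(calls, post, list(calls_df.index), list(calls_df.columns))


# -- phenotypes --------------------------------------------------------------

def read_phenotypes(path) -> pd.DataFrame:
    df = _read_tsv(path, {"segregant_id", "phenotype"}, "phenotype")
    if not df["phenotype"].isin([0, 1]).all():
        bad = df.loc[~df["phenotype"].isin([0, 1])].index[0]
        raise ValueError(f"phenotype file {path} line {bad + 2}: phenotype must be 0/1")
    if "tetrad_id" not in df.columns:
        df["tetrad_id"] = "none"
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    cols = [c for c in ("segregant_id", "tetrad_id", "phenotype") if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False)


def phenotype_vector(df: pd.DataFrame, segregant_ids) -> PhenotypeVector:
    """Align a phenotype table to a genotype matrix's segregant order."""
    lookup = dict(zip(df["segregant_id"], df["phenotype"]))
    missing = [s for s in segregant_ids if s not in lookup]
    if missing:
        raise ValueError(f"no phenotype for segregant {missing[0]!r}")
    return PhenotypeVector(np.array([lookup[s] for s in segregant_ids]),
                           list(segregant_ids))


# -- pools -------------------------------------------------------------------

def read_pools(path) -> pd.DataFrame:
    return _read_tsv(path, {"pool_id", "phenotype", "marker_id", "n_B", "n_W"}, "pools")


def write_pools(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# -- scan results ------------------------------------------------------------

def write_scan(result: ScanResult, path) -> None:
    with open(path, "w") as fh:
        result.table.to_csv(fh, sep="\t", index=False, float_format="%.6g")
        fh.write(f"# method\t{result.method}\n")
        if result.threshold is not None:
            fh.write(f"# threshold\t{result.threshold:.6g}\n")
            fh.write(f"# alpha\t{result.alpha}\n")
            fh.write(f"# n_perm\t{result.n_perm}\n")
            fh.write(f"# genomewide_p\t{result.genomewide_p:.6g}\n")


def read_scan(path) -> ScanResult:
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines:
        if line.startswith("# "):
            key, _, val = line[2:].strip().partition("\t")
            meta[key] = val
    table = pd.read_csv(path, sep="\t", comment="#")
    return ScanResult(
        table, meta.get("method", "unknown"),
        threshold=float(meta["threshold"]) if "threshold" in meta else None,
        genomewide_p=float(meta["genomewide_p"]) if "genomewide_p" in meta else None,
        n_perm=int(meta["n_perm"]) if "n_perm" in meta else None,
        alpha=float(meta["alpha"]) if "alpha" in meta else None)


# -- models ------------------------------------------------------------------

def write_model(model, path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=2) + "\n")


def read_model(path) -> dict:
    return json.loads(Path(path).read_text())
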