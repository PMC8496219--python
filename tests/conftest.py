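import numpy as np
import pandas as pd
import pytest

from tetradqtl.containers import GenotypeMatrix
from tetradqtl.genmap import GeneticMap


def make_map(chrom_markers: dict[str, list[float]]) -> GeneticMap:
    """Map from {chrom: [cM positions]}; bp spaced at 2.5 kb per cM."""
    rows = []
    for chrom, cms in chrom_markers.items():
        for k, cm in enumerate(cms):
            # k offset keeps pos_bp strictly increasing even for coincident cM
            rows.append((f"{chrom}_m{k}", chrom, int(round(cm * 2500)) + k + 1,
                         float(cm), "A", "G"))
    df = pd.DataFrame(rows, columns=["marker_id", "chrom", "pos_bp", "pos_cM",
                                     "allele_B", "allele_W"])
    return GeneticMap(df)


def make_genotypes(calls: np.ndarray, marker_ids, seg_ids=None) -> GenotypeMatrix:
    """GenotypeMatrix from an int array of 1/0/-1 calls (posterior from calls)."""
    calls = np.asarray(calls, dtype=np.int8)
    post = np.where(calls == 1, 1.0, np.where(calls == 0, 0.0, 0.5))
    seg_ids = seg_ids or [f"s{i}" for i in range(calls.shape[0])]
    return GenotypeMatrix(calls, post, seg_ids, list(marker_ids))


@pytest.fixture
def small_map() -> GeneticMap:
    """Two chromosomes, 5 + 4 markers at 10 cM spacing."""
    return make_map({"I": [0, 10, 20, 30, 40], "II": [0, 10, 20, 30]})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20210602)
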