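import numpy as np
import pandas as pd
import pytest

from dmrpipe.io import SampleInfo
from dmrpipe.pipeline import matrix_from_simulation
from dmrpipe.simulate import SimConfig, simulate_methylomes
from dmrpipe.tiling import TileMatrix, TilingParams


@pytest.fixture(scope="session")
def small_sim():
    """Down-scaled default dataset (2,000 tiles) with planted DMRs."""
    return simulate_methylomes(SimConfig(n_tiles=2000, seed=7))


@pytest.fixture(scope="session")
def small_matrix(small_sim):
    return matrix_from_simulation(small_sim, TilingParams())


def make_matrix(pct_rows, sheet, total=100):
    """TileMatrix from explicit percent values (NaN = missing).

    Counts are reconstructed with a fixed total per cell so that count-based
    tests see tables consistent with the percentages.
    """
    pct = np.asarray(pct_rows, dtype=float)
    T = pct.shape[0]
    tiles = pd.DataFrame(
        {
            "chrom": ["chr1"] * T,
            "start": np.arange(T) * 100,
            "end": np.arange(T) * 100 + 100,
        }
    )
    mask = np.isnan(pct)
    tot = np.where(mask, 0, total).astype(np.int64)
    meth = np.where(mask, 0, np.round(np.nan_to_num(pct) / 100.0 * total)).astype(np.int64)
    return TileMatrix(tiles, list(sheet), pct, meth, tot)


def design(tissues, ages, reps, target_genotype="WT"):
    """Sample sheet covering tissues x ages x replicates."""
    sheet = []
    for t in tissues:
        for a in ages:
            for r in range(reps):
                sheet.append(
                    SampleInfo(f"{t}_{a:g}_{r}", t, float(a), target_genotype, f"r{r+1}")
                )
    return sheet
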