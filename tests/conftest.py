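import numpy as np
import pandas as pd
import pytest

from statefate.grid import DEFAULT_STATES, GenomeGrid, StateTrack
from statefate.simulate import SimulationConfig, simulate_state_tracks


@pytest.fixture
def small_grid() -> GenomeGrid:
    return GenomeGrid(chrom_sizes={"chr1": 10_000, "chr2": 5_000}, bin_size=200)


@pytest.fixture
def toy_tracks(small_grid):
    """Deterministic paired toy tracks on the small grid."""
    rng = np.random.default_rng(42)
    k = len(DEFAULT_STATES)
    n = small_grid.total_bins
    a = StateTrack(small_grid, "DE", DEFAULT_STATES, rng.integers(0, k, n))
    b = StateTrack(small_grid, "PE", DEFAULT_STATES, rng.integers(0, k, n))
    return a, b


@pytest.fixture(scope="session")
def default_cfg() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture(scope="session")
def default_tracks(default_cfg):
    """One 100 000-bin simulated track pair, shared across tests."""
    return simulate_state_tracks(default_cfg, seed=7)


def make_genes(rows) -> pd.DataFrame:
    """Small gene table from (gene_id, chrom, tss, tpm_DE, tpm_PE, de) rows."""
    df = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "tss", "tpm_DE", "tpm_PE", "de_DE_vs_PE"]
    )
    df["strand"] = "+"
    df["is_tf"] = False
    return df
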