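import numpy as np
import pytest

from mimland.genomic_io import GenotypeMatrix, WindowSpec


@pytest.fixture
def make_matrix():
    """Factory for small in-memory genotype matrices.

    ``taxa`` assigns one taxon label per individual; calls is
    (sites, individuals, 2) with -1 for missing.
    """

    def _make(calls, taxa, chrom="c", start_pos=0):
        calls = np.asarray(calls, dtype=np.int8)
        n_sites, n_ind, _ = calls.shape
        individuals = [f"i{k}" for k in range(n_ind)]
        return GenotypeMatrix(
            chroms=np.array([chrom] * n_sites, dtype=object),
            positions=np.arange(start_pos, start_pos + n_sites, dtype=np.int64),
            ref=np.array(["A"] * n_sites, dtype=object),
            alt=np.array(["T"] * n_sites, dtype=object),
            calls=calls,
            individuals=individuals,
            taxon_map={f"i{k}": t for k, t in enumerate(taxa)},
        )

    return _make


@pytest.fixture
def window100():
    return WindowSpec("c", 0, 100, 100, 100)


@pytest.fixture(scope="session")
def small_radiation():
    """A modest 9-taxon radiation with landscape structure, shared across tests."""
    from mimland.synthetic_radiation import SyntheticConfig, generate_radiation

    cfg = SyntheticConfig(n_windows=120, n_chrom=6, window_bp=2000, seed=42)
    return generate_radiation(cfg)
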