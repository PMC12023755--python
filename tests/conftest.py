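import numpy as np
import pytest

from nitracer.io import CommunityTable, SourceSignatureTable


@pytest.fixture
def two_source_signatures():
    """Two well-separated sources on one isotope (toy inference problems)."""
    return SourceSignatureTable(
        sources=["A", "B"],
        isotopes=["d15n"],
        mean_s=np.array([[0.0], [10.0]]),
        sd_s=np.array([[1.0], [1.0]]),
    )


@pytest.fixture
def four_source_signatures():
    rng = np.random.default_rng(7)
    return SourceSignatureTable(
        sources=["AP", "CF", "SN", "MS"],
        isotopes=["d15n", "d18o"],
        mean_s=rng.uniform(-5, 30, size=(4, 2)),
        sd_s=rng.uniform(0.5, 3.0, size=(4, 2)),
        mean_c=rng.uniform(-1, 1, size=(4, 2)),
        sd_c=rng.uniform(0.0, 1.0, size=(4, 2)),
        conc_q=rng.uniform(0.5, 2.0, size=(4, 2)),
    )


@pytest.fixture
def small_community():
    counts = np.array(
        [
            [5, 0, 3, 12, 1],
            [0, 7, 2, 1, 4],
            [9, 9, 0, 0, 2],
            [1, 1, 1, 1, 1],
        ]
    )
    return CommunityTable(
        site_ids=[f"S{i}" for i in range(4)],
        taxon_ids=[f"T{j}" for j in range(5)],
        counts=counts,
    )
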