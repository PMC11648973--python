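import numpy as np
import pytest

from popdrift.genotypes import MISSING, GenotypeMatrix


def random_matrix(
    n: int = 10,
    L: int = 20,
    n_pops: int = 2,
    missing_rate: float = 0.1,
    seed: int = 0,
) -> GenotypeMatrix:
    """Random genotype matrix with optional missingness, for round-trips."""
    rng = np.random.default_rng(seed)
    d = rng.integers(0, 3, size=(n, L)).astype(np.int8)
    if missing_rate > 0:
        d[rng.random((n, L)) < missing_rate] = MISSING
    pops = np.array([f"pop{1 + (i * n_pops) // n}" for i in range(n)], dtype=object)
    return GenotypeMatrix(
        dosages=d,
        pop_labels=pops,
        locus_ids=np.array([f"locus_{j}" for j in range(L)], dtype=object),
    )


@pytest.fixture
def toy_matrix() -> GenotypeMatrix:
    return random_matrix(seed=42)
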