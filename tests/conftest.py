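import numpy as np
import pytest

from fipsa import GenotypeMatrix, MISSING


def gm_from_strings(rows: list[list[str]], ploidy: int = 2) -> GenotypeMatrix:
    """Build a GenotypeMatrix from cells like '0/1' or '1/.'."""
    calls = []
    for row in rows:
        r = []
        for cell in row:
            r.append([MISSING if t == "." else int(t) for t in cell.split("/")])
        calls.append(r)
    arr = np.asarray(calls, dtype=np.int16)
    n, s, _ = arr.shape
    return GenotypeMatrix(
        [f"i{j}" for j in range(n)], [f"l{j}" for j in range(s)], arr, ploidy=ploidy
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def two_block_gm():
    """8 individuals, 50 loci, two private-allele blocks defining two groups."""
    calls = np.zeros((8, 50, 2), dtype=np.int16)
    calls[:4, :25, :] = 1  # group A carries allele 1 at the first block
    calls[4:, 25:, :] = 1  # group B at the second block
    return GenotypeMatrix(
        [f"i{j}" for j in range(8)], [f"l{j}" for j in range(50)], calls
    )
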