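import numpy as np
import pandas as pd
import pytest

from temponorm import CountMatrix

#: 20 genes x 4 samples with depth variation and one zero entry; the frozen
#: edgeR/DESeq2 reference factors in test_normalization were computed on it.
ORACLE_COUNTS = np.array(
    [
        [25, 16, 65, 40],
        [489, 282, 1112, 686],
        [62, 30, 119, 74],
        [107, 0, 234, 142],
        [124, 68, 263, 170],
        [70, 35, 155, 104],
        [43, 15, 69, 52],
        [291, 133, 527, 365],
        [205, 105, 383, 259],
        [25, 11, 42, 24],
        [1487, 738, 3187, 1996],
        [382, 214, 781, 522],
        [74, 40, 111, 102],
        [357, 194, 755, 474],
        [94, 39, 195, 121],
        [149, 58, 248, 167],
        [307, 163, 638, 437],
        [42, 15, 92, 57],
        [250, 122, 537, 335],
        [597, 297, 1172, 797],
    ]
)


@pytest.fixture
def oracle_counts() -> CountMatrix:
    return CountMatrix(
        pd.DataFrame(
            ORACLE_COUNTS,
            index=[f"g{i}" for i in range(20)],
            columns=list("ABCD"),
        )
    )


@pytest.fixture
def random_counts():
    """Factory for random NB-ish count matrices with depth variation."""

    def make(n_genes=30, n_samples=6, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.lognormal(4.0, 1.2, n_genes)
        depth = rng.uniform(0.5, 2.0, n_samples)
        x = rng.poisson(base[:, None] * depth[None, :])
        return CountMatrix.from_arrays(x)

    return make
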