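import numpy as np
import pandas as pd
import pytest

from implinet import BooleanImplicationNetwork, synthetic


@pytest.fixture(scope="session")
def default_cohort():
    """The default planted three-state cohort (3x50 samples, 3x20-gene clusters)."""
    spec = synthetic.default_spec(seed=7)
    return synthetic.generate_cohort(spec)


@pytest.fixture(scope="session")
def fitted(default_cohort):
    """Full pipeline fit of the default cohort, with a 10-permutation FDR."""
    matrix, annotations, _ = default_cohort
    model = BooleanImplicationNetwork(matrix, annotations)
    return model.fit(n_permutations=10, seed=1)


def step_matrix(levels: dict[str, list[float]], n_per_level: int = 30, low=4.0, high=8.0):
    """Noise-free genes x samples matrix from per-gene low/high level patterns.

    ``levels`` maps gene -> list of 0/1 block levels; each block spans
    n_per_level samples at the low/high mean.
    """
    genes = list(levels)
    n_blocks = len(next(iter(levels.values())))
    cols = [f"s{b}_{i}" for b in range(n_blocks) for i in range(n_per_level)]
    rows = []
    for g in genes:
        row = np.repeat([high if lv else low for lv in levels[g]], n_per_level)
        rows.append(row)
    return pd.DataFrame(rows, index=genes, columns=cols, dtype=float)
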