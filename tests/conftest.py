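import numpy as np
import pandas as pd
import pytest

from parenclitic.matrix import MethylationMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def small_cohort():
    """Tiny separable off-line cohort shared by classification tests."""
    from parenclitic.synthetic import SyntheticSpec, generate

    spec = SyntheticSpec(
        n_genes=12, n_control=16, n_healthy=16, n_disease=30, delta_perp=8.0, seed=5
    )
    matrix, truth = generate(spec)
    return matrix, truth


def make_matrix(values, labels=None, genes=None, samples=None) -> MethylationMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    df = pd.DataFrame(values, index=genes, columns=samples)
    lab = None if labels is None else pd.Series(labels, index=samples)
    return MethylationMatrix(df, lab)
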