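import numpy as np
import pandas as pd
import pytest

from parknet.expression import ExpressionStudy
from parknet.synthetic import SyntheticConfig, generate_expression


@pytest.fixture
def toy_study():
    """6 genes x (3 control + 3 disease), fixed values, exhaustive-permutable."""
    rng = np.random.default_rng(42)
    mat = rng.normal(8.0, 1.0, size=(6, 6))
    mat[0, 3:] += 3.0  # one strongly shifted gene
    genes = [f"g{i}" for i in range(6)]
    samples = [f"c{i}" for i in range(3)] + [f"d{i}" for i in range(3)]
    groups = pd.Series(["control"] * 3 + ["disease"] * 3, index=samples)
    return ExpressionStudy(pd.DataFrame(mat, index=genes, columns=samples), groups)


@pytest.fixture
def two_block_study():
    """Two planted 50-gene modules over background, study-scale samples."""
    cfg = SyntheticConfig(
        n_genes=120, module_sizes=(50, 50), module_cor=0.9, noise_sd=0.3,
        de_fraction=0.0, seed=7,
    )
    return generate_expression(cfg)
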