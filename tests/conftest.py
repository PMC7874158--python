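import numpy as np
import pandas as pd
import pytest

from imlnc import CohortSpec, ExpressionMatrix, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort with strong planted signal, shared across tests."""
    spec = CohortSpec(
        n_tumor=60,
        n_normal=5,
        n_genes=400,
        n_lncrnas=150,
        n_planted_lncrnas=6,
        effect_size=3.0,
        seed=42,
    )
    return generate_cohort(spec)


@pytest.fixture
def tiny_matrix():
    """Hand-sized expression matrix: 6 features (half lncRNA) x 8 samples."""
    rng = np.random.default_rng(7)
    feature_ids = [f"F{i}" for i in range(6)]
    sample_ids = [f"S{i}" for i in range(8)]
    values = pd.DataFrame(
        rng.gamma(2.0, 3.0, size=(6, 8)), index=feature_ids, columns=sample_ids
    )
    return ExpressionMatrix(
        values=values,
        biotype=pd.Series(["gene"] * 3 + ["lncRNA"] * 3, index=feature_ids),
        sample_group=pd.Series(["tumor"] * 6 + ["normal"] * 2, index=sample_ids),
    )
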