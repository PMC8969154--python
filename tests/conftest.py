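import numpy as np
import pandas as pd
import pytest

from acylpipe import synthio
from acylpipe.coexpr import ExpressionMatrix


@pytest.fixture
def small_expr() -> ExpressionMatrix:
    """5 genes x 4 samples with mixed tumor flags, fixed values."""
    rng = np.random.default_rng(42)
    values = pd.DataFrame(
        rng.normal(size=(5, 4)),
        index=[f"g{i}" for i in range(5)],
        columns=[f"s{i}" for i in range(4)],
    )
    meta = pd.DataFrame({"tumor": [False, False, True, False]}, index=values.columns)
    return ExpressionMatrix(values=values, sample_meta=meta)


@pytest.fixture
def acyl_table() -> tuple[pd.DataFrame, synthio.GroundTruth]:
    effects = {i: 3.0 for i in range(1, 7)}
    return synthio.gen_acyl_table(
        n_sites=10, n_unmod_peptides=4, conditions=["unmod", "glut"],
        n_reps=3, effect_log2fc=effects, missing_rate=0.1, seed=123,
    )


@pytest.fixture
def melting_curve():
    curve, truth = synthio.gen_melting_curve(55.0, 300.0, noise_sd=0.0, seed=0)
    return curve, truth
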