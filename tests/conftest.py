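import numpy as np
import pandas as pd
import pytest

from permdeg import (
    DegCallParams,
    ExpressionMatrix,
    GroupDesign,
    SimulationParams,
    simulate_expression,
)
from permdeg.containers import SCALE_LOG2_QNORM
from permdeg.preprocess import filter_expressed, log2_transform, quantile_normalize


@pytest.fixture(scope="session")
def small_study():
    """A 300-gene 3v3 study with planted DE and silent genes."""
    params = SimulationParams(
        n_genes=300, frac_de=0.1, frac_silent=0.1, seed=7
    )
    return simulate_expression(params)


@pytest.fixture(scope="session")
def small_processed(small_study):
    matrix = quantile_normalize(
        log2_transform(filter_expressed(small_study.matrix), offset=0.0)
    )
    return matrix


@pytest.fixture()
def design_3v3():
    return GroupDesign(
        groups={
            "WT_1": "wildtype",
            "WT_2": "wildtype",
            "WT_3": "wildtype",
            "KO_1": "knockout",
            "KO_2": "knockout",
            "KO_3": "knockout",
        },
        reference="wildtype",
    )


def make_qnorm_matrix(values: np.ndarray, gene_ids=None, sample_ids=None):
    """Wrap raw values as an already-normalized matrix for engine tests."""
    n, m = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n)]
    sample_ids = sample_ids or (
        [f"WT_{j+1}" for j in range(m // 2)] + [f"KO_{j+1}" for j in range(m - m // 2)]
    )
    return ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids),
        SCALE_LOG2_QNORM,
    )


@pytest.fixture()
def deg_params():
    return DegCallParams(n_perm=200, seed=11)
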