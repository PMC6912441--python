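import numpy as np
import pandas as pd
import pytest

import surprisalx as sx


def make_matrix(values, genes=None, samples=None) -> sx.ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i+1}" for i in range(values.shape[0])]
    samples = samples or [f"s{j+1}" for j in range(values.shape[1])]
    return sx.ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


@pytest.fixture(scope="session")
def default_dataset():
    """One generated dataset at the default study conditions (seed 0)."""
    return sx.generate(sx.SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def default_model(default_dataset):
    """Surprisal fit of the collapsed default dataset, oriented so the
    exponential-phase and high-dose groups carry positive multipliers."""
    m, d, _, _ = default_dataset
    exp, _ = d.condition_groups_by_time((1, 2))
    hi, _ = d.condition_groups_by_dose((3, 4))
    return sx.fit_surprisal(m, d, reference={1: exp, 2: hi})


@pytest.fixture
def grid_design():
    """2 x 2 condition grid with 2 replicates each."""
    rows = []
    for k in (1, 2):
        for m in (1, 2):
            for r in (1, 2):
                rows.append((f"ac{k}t{m}_r{r}", k, m, r))
    table = pd.DataFrame(
        rows,
        columns=["sample_id", "concentration_index", "time_index", "replicate_index"],
    ).set_index("sample_id")
    return sx.SampleDesign(table)
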