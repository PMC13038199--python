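import numpy as np
import pandas as pd
import pytest

import ce3screen as c
from ce3screen import preprocess


@pytest.fixture(scope="session")
def default_config():
    return c.SimulationConfig(seed=1, n_proteins=1000)


@pytest.fixture(scope="session")
def ibaq_run(default_config):
    """One simulated screen: (raw table, truth, preprocessed matrix)."""
    table, truth = c.simulate_ibaq_experiment(default_config)
    matrix = c.preprocess_chain(table)
    return table, truth, matrix


@pytest.fixture(scope="session")
def cohort_run():
    cfg = c.SimulationConfig(seed=11)
    cohort, truth = c.simulate_cohort_expression(cfg)
    return cohort, truth


def toy_protein_table(intensities: dict, n_peptides=None) -> pd.DataFrame:
    """Build a small protein-groups table from {column: values}."""
    n = len(next(iter(intensities.values())))
    return pd.DataFrame({
        "protein_id": [f"P{i}" for i in range(n)],
        "gene_symbol": [f"G{i}" for i in range(n)],
        "n_unique_peptides": n_peptides if n_peptides is not None else [5] * n,
        "is_contaminant": [False] * n,
        "is_reverse": [False] * n,
        **{k: np.asarray(v, dtype=float) for k, v in intensities.items()},
    })


def matrix_from_differences(diffs: np.ndarray) -> preprocess.PreprocessedMatrix:
    """A PreprocessedMatrix whose paired differences equal ``diffs`` exactly."""
    G, n = diffs.shape
    data = {f"gNT_R{k}": np.zeros(G) for k in range(1, n + 1)}
    data.update({f"gAR_R{k}": diffs[:, k - 1] for k in range(1, n + 1)})
    df = pd.DataFrame(
        data, index=pd.Index([f"P{i:04d}" for i in range(G)], name="protein_id")
    )
    return preprocess.PreprocessedMatrix(data=df, n_replicates=n)
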