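import numpy as np
import pandas as pd
import pytest

from mirlink import io, simulate


@pytest.fixture()
def toy_counts() -> io.CountMatrix:
    """3 features x 4 samples, two groups, no structure."""
    values = np.array(
        [[10, 12, 9, 11], [100, 110, 95, 105], [5, 6, 4, 5]]
    )
    return io.CountMatrix(["g1", "g2", "g3"], ["a1", "a2", "b1", "b2"], values)


@pytest.fixture()
def toy_meta() -> pd.DataFrame:
    return pd.DataFrame(
        {"sample_id": ["a1", "a2", "b1", "b2"], "group": ["A", "A", "B", "B"]}
    )


@pytest.fixture(scope="session")
def small_cohort():
    """One simulated paired cohort with planted structure, shared session-wide."""
    config = simulate.SimConfig(seed=7, n_genes=600, n_mirnas=80, n_de_genes=40)
    mrna, mirna, meta, truth = simulate.generate_paired_counts(config)
    evidence = simulate.generate_evidence_fixture(
        truth, n_decoys=30, seed=8, gene_ids=mrna.feature_ids,
        mirna_ids=mirna.feature_ids,
    )
    return mrna, mirna, meta, truth, evidence
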