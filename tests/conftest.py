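import numpy as np
import pandas as pd
import pytest

from degronscan import DegronModel, GateCountTable
from degronscan.seqcore import KD_VECTOR


@pytest.fixture(scope="session")
def kd_model() -> DegronModel:
    """A model whose weights are the Kyte-Doolittle scale.

    Useful because its score of a peptide is sigmoid(GRAVY): hydrophobic
    peptides score as degrons, acidic ones do not.
    """
    return DegronModel(weights=KD_VECTOR.copy())


@pytest.fixture()
def toy_counts() -> GateCountTable:
    """Four peptides with hand-evaluable gate distributions (equal depths)."""
    df = pd.DataFrame({
        "peptide_id": ["all_g1", "all_g4", "uniform", "split"],
        "sequence": ["A" * 17, "C" * 17, "D" * 17, "E" * 17],
        "G1": [100, 0, 25, 10],
        "G2": [0, 0, 25, 0],
        "G3": [0, 0, 25, 0],
        "G4": [0, 100, 25, 30],
    })
    # pad a balancing row so every gate has total depth 160
    balance = pd.DataFrame({
        "peptide_id": ["balance"], "sequence": ["G" * 17],
        "G1": [25], "G2": [135], "G3": [135], "G4": [5],
    })
    return GateCountTable(counts=pd.concat([df, balance], ignore_index=True),
                          strain="toy")


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20220)
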