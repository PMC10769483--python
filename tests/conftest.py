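import numpy as np
import pytest

from mmscore import PotencyMatrix, TargetSpec


@pytest.fixture
def small_affinity_matrix():
    """4 compounds x 5 kinases, one mutant column, some missing pairs."""
    compounds = ["cmpA", "cmpB", "cmpC", "cmpD"]
    kinases = ["T1", "K1", "K2", "K3", "K4(D835Y)"]
    values = np.array(
        [
            [50.0, 5000.0, np.nan, 80.0, 30.0],
            [100.0, 60.0, 900.0, np.nan, np.nan],
            [1000.0, np.nan, 40.0, 2000.0, 10.0],
            [np.nan, 300.0, 300.0, 300.0, 300.0],
        ]
    )
    return PotencyMatrix(
        compounds=compounds,
        kinases=kinases,
        values=values,
        value_kind="affinity",
        mutant_flags=np.array([False, False, False, False, True]),
    )


def orthogonal_binary_matrix(n: int, K: float = 50.0) -> PotencyMatrix:
    """n inhibitors sharing one target (affinity K) plus one private
    off-target each (same K); all other pairs unmeasured."""
    compounds = [f"I{j}" for j in range(n)]
    kinases = ["T"] + [f"O{j}" for j in range(n)]
    values = np.full((n, n + 1), np.nan)
    for j in range(n):
        values[j, 0] = K
        values[j, j + 1] = K
    return PotencyMatrix(compounds, kinases, values, "affinity")


@pytest.fixture
def target_spec():
    return TargetSpec(targets=("T1",))
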