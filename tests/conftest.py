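import numpy as np
import pandas as pd
import pytest

from phosphonorm import SampleDesign, SimulationConfig
from phosphonorm.matrix import IntensityMatrix


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_proteins=400, n_phosphosites=120, seed=7,
                            missing_rate=0.05)


@pytest.fixture(scope="session")
def omics_pair(small_config):
    from phosphonorm import simulate_omics_pair
    return simulate_omics_pair(small_config)


@pytest.fixture(scope="session")
def phospho_experiment(small_config):
    from phosphonorm import simulate_phospho_experiment
    return simulate_phospho_experiment(small_config)


@pytest.fixture
def design_2x3():
    """Two groups (one cell type, two treatments), three replicates each."""
    rows = [{"sample_id": f"beta_{tr}_{r}", "cell_type": "beta",
             "treatment": tr, "replicate": r}
            for tr in ("control", "IFNg") for r in (1, 2, 3)]
    return SampleDesign(pd.DataFrame(rows))


def make_matrix(values, scale="log2", prefix="F"):
    arr = np.asarray(values, dtype=float)
    df = pd.DataFrame(arr,
                      index=[f"{prefix}{i}" for i in range(arr.shape[0])],
                      columns=[f"S{j}" for j in range(arr.shape[1])])
    return IntensityMatrix(df, scale)
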