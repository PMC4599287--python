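import numpy as np
import pandas as pd
import pytest

from allprog.simulate import SimConfig, simulate_bundle


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(seed=11, n_genes=400)


@pytest.fixture(scope="session")
def bundle(small_cfg):
    return simulate_bundle(small_cfg)


@pytest.fixture()
def tiny_matrix():
    """4 genes x 10 samples with hand-checkable structure."""
    ann = pd.Series(
        ["somatic"] * 4 + ["germline"] * 2 + ["es"] + ["placenta"] + ["bm_nonleukemic"] * 2,
        index=[f"s{i}" for i in range(10)],
        name="group",
    )
    data = np.full((4, 10), 5.0)
    data[1, 4] = 5.1  # germline bump above zero-SD somatic baseline
    data[2, 6] = 9.0  # es-predominant
    data[3, :4] = [4.0, 6.0, 5.0, 5.0]  # somatic spread
    matrix = pd.DataFrame(
        data, index=[f"g{i}" for i in range(4)], columns=ann.index
    )
    return matrix, ann
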