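import itertools

import numpy as np
import pandas as pd
import pytest

from dairycnv.synthdata import SimConfig


@pytest.fixture(scope="session")
def small_sim_config():
    """Reduced-scale herd used by several module tests."""
    return SimConfig(
        n_cows=150,
        n_samples=40,
        n_snps=800,
        n_chromosomes=2,
        seed=11,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def clean_dhi_records():
    """Hand-sized DHI table: one compliant cow with 8 monthly tests."""
    rows = []
    for k, dim in enumerate(range(15, 255, 30)):
        rows.append(
            {
                "cow_id": "A", "parity": 1, "afc_months": 25.0, "dim": dim,
                "my": 30.0 + k, "mfp": 3.8, "mfy": 1.1, "mpp": 3.3,
                "mpy": 1.0, "scs": 3.0,
            }
        )
    return pd.DataFrame(rows)


def viterbi_bruteforce(loge, logT, logpi):
    """Exhaustive path enumeration oracle (vectorised over all S^n paths)."""
    n, S = loge.shape
    paths = np.array(list(itertools.product(range(S), repeat=n)), dtype=np.int8)
    score = logpi[paths[:, 0]] + loge[0, paths[:, 0]]
    for i in range(1, n):
        score = score + logT[i - 1, paths[:, i - 1], paths[:, i]] + loge[i, paths[:, i]]
    best = int(np.argmax(score))
    return paths[best], float(score[best])


def path_score(path, loge, logT, logpi):
    n = len(path)
    s = logpi[path[0]] + loge[0, path[0]]
    for i in range(1, n):
        s += logT[i - 1, path[i - 1], path[i]] + loge[i, path[i]]
    return float(s)
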