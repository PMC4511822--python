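import numpy as np
import pandas as pd
import pytest

from mibca import simulate
from mibca.types import ConnectivityMatrix


@pytest.fixture(scope="session")
def parc8():
    return simulate.make_toy_parcellation(8, shape=(24, 24, 24), seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_binary_cm(rng, n=6, p=0.4, directed=False, roi_ids=None):
    vals = (rng.random((n, n)) < p).astype(float)
    if not directed:
        vals = np.triu(vals, 1)
        vals = vals + vals.T
    np.fill_diagonal(vals, 0.0)
    return ConnectivityMatrix(
        values=vals,
        roi_ids=roi_ids or list(range(1, n + 1)),
        directed=directed,
        weight_kind="binary",
    )


def random_roi_table(rng, n_pairs=3):
    rows = []
    for k in range(n_pairs):
        tissue = "subcortical" if k == 0 else "cortical"
        for hemi, lid in (("left", 2 * k + 1), ("right", 2 * k + 2)):
            rows.append((lid, f"region{k:02d}", hemi, tissue))
    df = pd.DataFrame(rows, columns=["label_id", "name", "hemisphere", "tissue_class"])
    return df.sample(frac=1.0, random_state=int(rng.integers(1 << 31)))
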