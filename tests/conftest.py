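import numpy as np
import pytest

import mirpipe as mp


def make_matrix(values, scale="linear", batches=None):
    """Small ExpressionMatrix from a nested list; None entries are missing."""
    arr = np.array(
        [[np.nan if v is None else float(v) for v in row] for row in values]
    )
    n_r, n_c = arr.shape
    sample_ids = [f"s{j + 1}" for j in range(n_c)]
    batch_of = batches or {s: "1" for s in sample_ids}
    return mp.ExpressionMatrix(
        arr, [f"m{i + 1}" for i in range(n_r)], sample_ids, batch_of, scale
    )


@pytest.fixture(scope="session")
def small_study():
    """A fast, fully-featured synthetic study (clear batch effect, MNAR)."""
    cfg = mp.GeneratorConfig(n_mirnas=120, n_batch1=10, n_batch2=14, n_common=5, seed=11)
    return mp.generate_two_batch_study(cfg)


@pytest.fixture(scope="session")
def small_qc(small_study):
    return mp.qc_arrays(small_study.arrays, small_study.batch_of)


@pytest.fixture(scope="session")
def desk_study():
    """The default desk-scale study (300 miRNAs, batches 28/47, 10 common)."""
    return mp.generate_two_batch_study(mp.GeneratorConfig(seed=202))
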