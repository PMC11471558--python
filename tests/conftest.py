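import numpy as np
import pytest

import mosaicvae as mv

# small architecture used throughout unit tests; acceptance runs use a larger one
SMALL_ARCH = dict(d_c=6, d_u=2, enc_hidden=(48, 24), dec_hidden=(24, 48),
                  clf_hidden=(24,), dropout=0.2)


@pytest.fixture(scope="session")
def small_dataset():
    cfg = mv.SimulationConfig(n_cells_per_batch=(150, 150), n_types=3, seed=7,
                              type_separation=6.0,
                              n_features={"ATAC": 80, "RNA": 60, "ADT": 20})
    return mv.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_results(small_dataset):
    """A briefly trained model shared by task-head tests."""
    ds, _ = small_dataset
    arch = mv.Architecture(**SMALL_ARCH)
    return mv.MosaicVAE(ds, arch, mv.LossWeights()).fit(
        epochs=8, lr=1e-3, batch_size=128, seed=0, patience=8)
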