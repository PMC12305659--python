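import numpy as np
import pandas as pd
import pytest

from phenomet import synth


@pytest.fixture(scope="session")
def small_plate():
    """A compact plate with 4 treatments (2 active, 2 null) and ground truth."""
    treatments = ["T01", "T02", "T03", "T04"]
    gt = synth.default_ground_truth(
        treatments, n_features=20, n_moa_classes=1, n_affected=6,
        effect_sd=3.0, active_fraction=0.5, seed=7,
    )
    layout = synth.compact_layout(treatments)
    tables, _ = synth.generate_plate(layout, n_features=20, n_cells_per_well=120,
                                     effects=gt, seed=7)
    return layout, tables, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def toy_profiles():
    """4 bioactivity fingerprints of length 4, values in [0, 1]."""
    return pd.DataFrame(
        [[0.1, 0.9, 0.2, 0.8],
         [0.2, 0.8, 0.1, 0.9],
         [0.9, 0.1, 0.8, 0.2],
         [0.5, 0.5, 0.4, 0.6]],
        index=["S1", "S2", "S3", "S4"],
        columns=[f"f{i}" for i in range(4)],
    )
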