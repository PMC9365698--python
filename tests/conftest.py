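import numpy as np
import pandas as pd
import pytest

from cytolink.interactome import InteractionNetwork
from cytolink.kinetics import CellGeometry, ModelConfig
from cytolink.synthetic import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_screen_config():
    """Zero-noise, zero plate-effect screen with one planted pair."""
    return SimConfig(
        n_proteins=6,
        n_true_pairs=1,
        pair_effect=2.0,
        noise_sd=0.0,
        row_effect_sd=0.0,
        col_effect_sd=0.0,
        seed=7,
    )


@pytest.fixture
def noisy_screen_config():
    return SimConfig(
        n_proteins=50,
        n_true_pairs=10,
        pair_effect=2.0,
        noise_sd=0.1,
        row_effect_sd=0.3,
        col_effect_sd=0.3,
        seed=11,
    )


@pytest.fixture
def toy_network():
    return InteractionNetwork(
        edges=pd.DataFrame(
            {
                "protein_a": ["A", "B", "C"],
                "protein_b": ["B", "C", "C"],
                "kd_molar": [1e-6, 1e-4, 1e-5],
                "provenance": ["screen", "literature", "screen"],
            }
        )
    )


@pytest.fixture
def toy_geometry():
    return CellGeometry(
        table=pd.DataFrame(
            {"radius_um": [4.0, 5.0, 6.0], "blood_frequency": [0.5, 0.2, 0.1]},
            index=pd.Index(["T", "M", "N"], name="cell_type"),
        )
    )


@pytest.fixture
def model_config():
    return ModelConfig()
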