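import numpy as np
import pandas as pd
import pytest

import psea


@pytest.fixture(scope="session")
def zero_noise_sim():
    """Small noiseless mixture: every gene is an exact linear combination."""
    cfg = psea.SimulationConfig(seed=7, n_genes=80, noise_sd_fraction=0.0)
    dataset, truth = psea.simulate_dataset(cfg)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def noisy_sim():
    """Moderate-noise mixture used by several model-level tests."""
    cfg = psea.SimulationConfig(seed=13, n_genes=150, noise_sd_fraction=0.05)
    dataset, truth = psea.simulate_dataset(cfg)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def zero_noise_refs(zero_noise_sim):
    _, dataset, truth = zero_noise_sim
    return psea.build_reference_signals(dataset, truth.markers)


@pytest.fixture(scope="session")
def noisy_refs(noisy_sim):
    _, dataset, truth = noisy_sim
    return psea.build_reference_signals(dataset, truth.markers)


def make_refs(signals: dict[str, np.ndarray], sample_ids=None) -> psea.ReferenceSignals:
    """Hand-built reference signals for unit tests (no normalization applied)."""
    df = pd.DataFrame(signals)
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(len(df))]
    df.index = sample_ids
    return psea.ReferenceSignals(signals=df)


def make_dataset(values: dict[str, np.ndarray], groups: list[str],
                 gene_map: dict[str, str] | None = None) -> psea.ExpressionDataset:
    mat = pd.DataFrame(values).T
    mat.columns = [f"S{i}" for i in range(mat.shape[1])]
    return psea.ExpressionDataset(
        values=mat,
        groups=pd.Series(groups, index=mat.columns),
        gene_map=pd.Series(gene_map or {}, dtype=object),
    )
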