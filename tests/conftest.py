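import numpy as np
import pytest

from ddievent.data_io import DatasetBundle, FeatureMatrix, PairDataset
from ddievent.ddi_net import ModelConfig
from ddievent.synthetic_data import SynthConfig, generate


@pytest.fixture
def tiny_feature_matrix() -> FeatureMatrix:
    values = np.array(
        [
            [1, 0, 1, 0],
            [0, 1, 1, 0],
            [1, 1, 0, 1],
            [0, 0, 0, 0],  # empty profile: 0/0 Jaccard convention applies
        ]
    )
    return FeatureMatrix("toy", ["A", "B", "C", "D"], ["f1", "f2", "f3", "f4"], values)


@pytest.fixture
def tiny_bundle() -> DatasetBundle:
    rng = np.random.default_rng(11)
    drug_ids = [f"D{k}" for k in range(6)]
    mats = [
        FeatureMatrix(
            name,
            drug_ids,
            [f"{name}_f{c}" for c in range(8)],
            (rng.random((6, 8)) < 0.4).astype(int),
        )
        for name in ("modA", "modB")
    ]
    records = [
        (0, 1, 0),
        (0, 2, 1),
        (1, 2, 0),
        (3, 4, 2),
        (2, 3, 1),
        (4, 5, 0),
        (0, 5, 2),
        (1, 4, 1),
    ]
    pairs = PairDataset(drug_ids, records, ["e1", "e2", "e3"])
    return DatasetBundle(mats, pairs)


@pytest.fixture(scope="session")
def fast_config() -> ModelConfig:
    return ModelConfig(hidden_sizes=[32, 16], epochs=12, batch_size=64, seed=0)


def planted_signal_config(seed: int = 5) -> SynthConfig:
    """One signal modality, two collision-heavy noise modalities (so few
    features that drug identity is not recoverable from the noise blocks)."""
    return SynthConfig(
        m=100,
        modality_names=["sig", "noiseA", "noiseB"],
        feature_counts=[300, 8, 8],
        n_groups=4,
        n_events=6,
        n_pairs=1200,
        signal_modalities=["sig"],
        between_noise_prob=0.03,
        seed=seed,
    )


@pytest.fixture(scope="session")
def planted_bundle():
    bundle, truth = generate(planted_signal_config())
    return bundle, truth


@pytest.fixture(scope="session")
def learnable_bundle():
    """All-modalities-signal bundle used by learnability checks."""
    config = SynthConfig(
        m=100,
        modality_names=["modA", "modB"],
        feature_counts=[300, 300],
        n_groups=4,
        n_events=6,
        n_pairs=1200,
        seed=7,
    )
    bundle, truth = generate(config)
    return bundle, truth
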