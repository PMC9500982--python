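import numpy as np
import pytest

import eegcube as ec
from eegcube.architectures import KernelSpec, LayerSpec, ModelSpec


@pytest.fixture(scope="session")
def deap_montage():
    return ec.MontageGrid.deap()


@pytest.fixture(scope="session")
def small_archive():
    """8 short trials with a moderate class effect, for structural tests."""
    cfg = ec.SynthConfig(n_trials_per_subject=8, trial_seconds=4.0,
                         effect_size=1.0, seed=3)
    return ec.generate_dataset(cfg)


def tiny_conv_spec(side: int = 8, depth: int = 8) -> ModelSpec:
    """A minimal conv/BN/pool/dense net for fast training tests."""
    flat = 2 * (depth // 2) * (side // 2) * (side // 2)
    return ModelSpec("tiny", (1, depth, side, side), [
        LayerSpec("conv3d", in_channels=1, out_channels=2,
                  kernel=KernelSpec((3, 3, 3), (1, 1, 1), (1, 1, 1))),
        LayerSpec("batchnorm", in_channels=2, out_channels=2),
        LayerSpec("relu"),
        LayerSpec("maxpool3d", kernel=KernelSpec((2, 2, 2), (2, 2, 2))),
        LayerSpec("flatten"),
        LayerSpec("dense", in_features=flat, out_features=2),
    ])


def random_window_dataset(n: int = 24, depth: int = 8, side: int = 8,
                          seed: int = 0) -> ec.WindowDataset:
    """Random tensors with random binary labels (no montage rendering)."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    tensors = rng.standard_normal((n, depth, side, side)).astype(np.float32)
    lv = rng.integers(0, 2, n)
    la = rng.integers(0, 2, n)
    prov = pd.DataFrame({
        "subject_id": np.zeros(n, dtype=int),
        "trial_id": np.arange(n) // 4,
        "window_index": np.arange(n) % 4,
    })
    return ec.WindowDataset(tensors, lv, la, prov)
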