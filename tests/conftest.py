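import numpy as np
import pytest

from psiscan.datasets_io import LabeledDataset, SequenceWindow
from psiscan.network import ModelConfig


def make_window(residues: str, id: str = "w", label: int = 1) -> SequenceWindow:
    return SequenceWindow(id=id, residues=residues, xi=len(residues) // 2, label=label)


@pytest.fixture
def tiny_dataset() -> LabeledDataset:
    """Ten 11-nt windows, balanced, deterministic."""
    rng = np.random.default_rng(42)
    windows = []
    for i in range(10):
        chars = rng.choice(list("ACGU"), size=11).tolist()
        chars[5] = "U"
        windows.append(
            SequenceWindow(
                id=f"w{i}", residues="".join(chars), xi=5, label=i % 2
            )
        )
    return LabeledDataset(windows, name="tiny")


@pytest.fixture
def small_config() -> ModelConfig:
    """A fast-to-train config for plumbing tests (not the tuned values)."""
    return ModelConfig.uniform(
        height=3,
        n_channels=2,
        filters_per_channel=4,
        input_rows=11,
        input_cols=4,
        dense_units=16,
        dropout_p=0.2,
        batch_size=8,
        max_epochs=3,
        seed=0,
    )
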