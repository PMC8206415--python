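import numpy as np
import pytest

from rcmstrata import (EncoderConfig, SyntheticDatasetConfig, build_encoder,
                       generate_dataset, train_encoder)


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic dataset shared by training-level tests."""
    return generate_dataset(SyntheticDatasetConfig(
        n_stacks=16, subjects=8, n_slices_range=(16, 24),
        image_size=(32, 32), seed=7))


def split_arrays(ds, split):
    idx = ds.split(split)
    return (np.concatenate([ds.stacks[i].slices for i in idx]),
            np.concatenate([ds.labels[i].labels for i in idx]))


@pytest.fixture(scope="session")
def trained_small_encoder(small_dataset):
    """A briefly trained encoder on the small dataset (32x32 slices)."""
    cfg = EncoderConfig(embedding_dim=32, epochs=10, batch_size=16, seed=1)
    enc = build_encoder(cfg)
    tr_x, tr_y = split_arrays(small_dataset, "train")
    va_x, va_y = split_arrays(small_dataset, "val")
    enc, history = train_encoder(enc, tr_x, tr_y, va_x, va_y, cfg)
    return enc, history
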