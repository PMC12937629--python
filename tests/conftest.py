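"""Shared fixtures.

The two expensive fixtures (the 200-step overfit run and the full
phantom pipeline) are session-scoped so capacity, determinism and
integration assertions all reuse a single training run.
"""

from __future__ import annotations

import numpy as np
import pytest

from bonecnn import (
    ArchConfig,
    PhantomSpec,
    TrainConfig,
    build_bone_cnn,
    generate_dataset,
    phantom_tensor_dataset,
    train_model,
)
from bonecnn.cli import end_to_end_smoke


@pytest.fixture(scope="session")
def phantom_manifest(tmp_path_factory):
    """Small on-disk phantom dataset: 6 images per class at 48 px."""
    root = tmp_path_factory.mktemp("phantoms")
    spec = PhantomSpec(image_size=48, seed=7)
    manifest = generate_dataset(6, spec, root)
    return root, manifest, spec


@pytest.fixture(scope="session")
def overfit_run():
    """Default architecture at 64 px trained 200 gradient steps on 32
    phantom images (batch 8, 4 steps/epoch, 50 epochs)."""
    spec = PhantomSpec(image_size=64, seed=0)
    x, y = phantom_tensor_dataset(4, spec)  # 36 images, 9 classes
    keep = np.random.default_rng(0).permutation(len(y))[:32]
    x, y = x[keep], y[keep]
    model = build_bone_cnn(ArchConfig(input_size=64), seed=0)
    config = TrainConfig(max_epochs=50, early_stop_patience=50, seed=0)
    model, history = train_model(model, x, y, x, y, config)
    return model, history, (x, y)


@pytest.fixture(scope="session")
def smoke_run(tmp_path_factory):
    """Full phantom pipeline: 20 images/class at 64 px, 10 epochs."""
    workdir = tmp_path_factory.mktemp("smoke")
    summary = end_to_end_smoke(workdir, n_per_class=20, image_size=64, epochs=10, seed=0)
    return workdir, summary
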