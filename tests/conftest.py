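import numpy as np
import pytest

import uaplab as ul


@pytest.fixture(scope="session")
def tiny_spec():
    """Small, fast task: 2 classes on 16x16 grayscale."""
    return ul.DomainSpec(n_classes=2, n_images=80, image_size=16, channels=1, seed=3)


@pytest.fixture(scope="session")
def tiny_data(tiny_spec):
    return ul.generate_target_dataset(tiny_spec)


@pytest.fixture(scope="session")
def tiny_clf(tiny_data):
    """A quick scratch-trained small CNN on the tiny task."""
    train, test = tiny_data
    cfg = ul.TrainConfig(epochs=2, learning_rate=0.02, seed=3)
    return ul.train_scratch(train, cfg, architecture_id="small", test=test)


@pytest.fixture(scope="session")
def transfer_setup():
    """One-seed transfer pipeline on the default 4-class task: data, pool,
    transfer-trained model. Shared by integration tests."""
    cfg = ul.default_experiment_config(seeds=(0,))
    from dataclasses import replace

    spec = replace(cfg.data_spec, seed=0)
    train, test = ul.generate_target_dataset(spec)
    pool = ul.generate_source_pool(replace(spec, n_images=cfg.pool_size, seed=10_000), cfg.shift)
    backbone = ul.pretrain_backbone(pool, replace(cfg.pretrain_config, seed=0), architecture_id="small")
    model = ul.finetune(backbone, train, replace(cfg.finetune_config, seed=0), test=test)
    return {"config": cfg, "train": train, "test": test, "pool": pool, "model": model, "backbone": backbone}


@pytest.fixture()
def linear_2class():
    """Hand-built linear softmax model on a single pixel: class 1 wins iff x > 0.5."""
    w = np.array([[0.0, 4.0]])  # logits = (0, 4x - 2)
    b = np.array([0.0, -2.0])
    return ul.linear_classifier(w, b, input_shape=(1, 1, 1))
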