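import numpy as np
import pytest

from dreamers import (
    ModelConfig,
    PhantomSpec,
    TrainConfig,
    generate_axis,
    generate_cohort,
    train,
)
from dreamers.pipeline import make_bags, stage_preprocess
from dreamers.training import split_by_animal


@pytest.fixture(scope="session")
def axis():
    return generate_axis(952, 1800, 213)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Desk-scale phantom: 2 classes x 4 treatments x 2 images at 24 x 24."""
    spec = PhantomSpec(height=24, width=24, images_per_cell=2, mice_per_cell=2, seed=11)
    return spec, generate_cohort(spec)


@pytest.fixture(scope="session")
def tiny_pre(tiny_cohort):
    _, cohort = tiny_cohort
    cubes = {c.meta["image_id"]: c for c in cohort.cubes}
    return stage_preprocess(cubes)


@pytest.fixture(scope="session")
def tiny_trained(tiny_cohort, tiny_pre):
    """A model trained on the tiny phantom, plus everything around it."""
    spec, cohort = tiny_cohort
    train_manifest, val_manifest = split_by_animal(cohort.manifest, seed=0)
    train_bags = make_bags(tiny_pre, train_manifest)
    val_bags = make_bags(tiny_pre, val_manifest)
    cfg = ModelConfig(input_dim=len(spec.axis))
    model, history = train(
        cfg, TrainConfig(learning_rate=1e-3, epochs=40, seed=1), train_bags, val_bags
    )
    gt_by_id = {
        c.meta["image_id"]: g for c, g in zip(cohort.cubes, cohort.ground_truths)
    }
    return {
        "spec": spec,
        "cohort": cohort,
        "model": model,
        "history": history,
        "train_manifest": train_manifest,
        "val_manifest": val_manifest,
        "train_bags": train_bags,
        "val_bags": val_bags,
        "gt_by_id": gt_by_id,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
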