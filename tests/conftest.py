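import numpy as np
import pytest

from retinaseg import pipeline, synth
from retinaseg.pipeline import PipelineConfig

E2E_SEED = 1


@pytest.fixture(scope="session")
def synth_dataset():
    """Eight default-condition fixtures split 4 train / 4 test."""
    images = synth.generate_images(8, synth.SyntheticSpec(seed=E2E_SEED))
    return images[:4], images[4:]


@pytest.fixture(scope="session")
def trained_bundle(synth_dataset):
    train, _ = synth_dataset
    return pipeline.train_pipeline(train, PipelineConfig(), seed=E2E_SEED)


@pytest.fixture(scope="session")
def e2e_result(trained_bundle, synth_dataset):
    _, test = synth_dataset
    report, preds = pipeline.evaluate_images(trained_bundle, test)
    return report, preds


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
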