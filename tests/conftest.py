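import pytest
from hypothesis import settings

from lsm_eval import load_study_fixtures
from lsm_eval import synthetic_data as sd

settings.register_profile("repro", derandomize=True, database=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def bundle():
    return load_study_fixtures()


@pytest.fixture(scope="session")
def synth_waterbodies():
    """Labelled synthetic waterbody table at survey scale, with exact
    ground truth (seed 42, n=4000)."""
    cfg = sd.GeneratorConfig(n_waterbodies=4000, random_seed=42)
    frame, truth = sd.gen_waterbodies(cfg)
    features = sd.frame_to_features(frame)
    labels = frame["larvae_present"].tolist()
    return frame, features, labels, truth
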