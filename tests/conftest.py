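import warnings

import numpy as np
import pytest

from vesiscope.imgmodel import PipelineParams


@pytest.fixture(scope="session")
def params():
    return PipelineParams()


@pytest.fixture(scope="session")
def event_classifier():
    """Per-time-point event classifier trained on synthetic movies
    (shared: detection + training dominate the suite's runtime)."""
    from vesiscope.tirf import synthesize_detection_training, train_detection_classifier

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        X, y = synthesize_detection_training(n_movies=60, seed=7)
        return train_detection_classifier(X, y)


@pytest.fixture(scope="session")
def separable_tracks():
    """Ground-truth-matched tracks only (insertion vs microcluster), for
    classifier-accuracy checks on a separable set."""
    from vesiscope.tirf import synthesize_event_training

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tracks, labels = synthesize_event_training(
            n_movies=100, seed=11, include_unmatched=False
        )
    return tracks, labels


@pytest.fixture(scope="session")
def uniform_disk_200():
    """Uniform-intensity disk on a 200x200 grid (spatial-randomness
    reference for the clustering statistics)."""
    yy, xx = np.mgrid[0:200, 0:200]
    mask = (yy - 99.5) ** 2 + (xx - 99.5) ** 2 <= 95**2
    frame = np.where(mask, 50.0, 0.0)
    return frame, mask
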