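"""Shared fixtures.

Heavy artifacts (the desk-scale corpus and the trained network) are
session-scoped so the learning and closed-loop suites share one training run.
"""

from __future__ import annotations

import numpy as np
import pytest

from optoloop import core_cnn, dataset_gen
from optoloop import tissue_sim as ts

# study conditions for the desk-scale corpus: >= 50 accepted simulations,
# one window per sample, eight dihedral augmentations -> >= 400 windows
N_BASE_SAMPLES = 56
CORPUS_SEED = 11
TRAIN_SEED = 0
TRAIN_EPOCHS = 20


@pytest.fixture(scope="session")
def desk_corpus():
    cfg = dataset_gen.GeneratorConfig(windows_per_sample=1)
    return dataset_gen.build_corpus(N_BASE_SAMPLES, seed=CORPUS_SEED, config=cfg)


@pytest.fixture(scope="session")
def trained_model(desk_corpus):
    model, history = core_cnn.train(
        desk_corpus,
        train_cfg=core_cnn.TrainConfig(epochs=TRAIN_EPOCHS, seed=TRAIN_SEED, batch_size=8),
    )
    return model, history


@pytest.fixture(scope="session")
def small_domain():
    """64 x 64 rendition of the 15.36 mm field with the 15 mm disc."""
    return ts.make_domain(64, 240.0, 15.0)


@pytest.fixture(scope="session")
def spiral_movie(small_domain):
    """A pinned homogeneous S1S2 simulation that sustains a spiral."""
    cfg = ts.SimulationConfig(dt_ms=0.1, record_every=60, duration_ms=1250.0, rng_seed=4)
    s12 = ts.S1S2Config()
    events, _ = ts.s1s2_events(small_domain, s12, seed=4)
    return ts.run_protocol(
        small_domain, None, events, cfg,
        prerecord_ms=events[-1].t_on_ms + events[-1].duration_ms + s12.stabilize_ms,
    )


def pinwheel_movie(n=64, frames=24, center=None, omega=0.5, chirality=1):
    """Analytic rigidly rotating pinwheel V = cos(atan2(y-y0, x-x0) - w t)."""
    if center is None:
        center = ((n - 1) / 2.0, (n - 1) / 2.0)
    yy, xx = np.mgrid[:n, :n].astype(float)
    ang = np.arctan2(yy - center[0], xx - center[1])
    t = np.arange(frames)[:, None, None]
    return np.cos(chirality * ang - omega * t).astype(np.float32)
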