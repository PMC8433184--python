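"""Shared fixtures: synthetic chips and trained classifier models.

Everything is generated at test time from seeded simulations; training the
stage classifier is the slow step, so one model per noise level is shared
across the whole session.
"""

from __future__ import annotations

import numpy as np
import pytest

import embryochip as ec
from embryochip.phenotype import EmbryoState as S

TRAIN_SEED = 3
N_PER_CLASS = 300
DEFAULT_NOISE = 3.0


@pytest.fixture(scope="session")
def model_noisefree():
    cfg = ec.SimChipConfig(noise_sigma=0.0, seed=TRAIN_SEED)
    patches, labels = ec.make_training_set(cfg, N_PER_CLASS, seed=TRAIN_SEED)
    return ec.train_classifier(patches, labels, seed=TRAIN_SEED)


@pytest.fixture(scope="session")
def model_noisy():
    cfg = ec.SimChipConfig(noise_sigma=DEFAULT_NOISE, seed=TRAIN_SEED)
    patches, labels = ec.make_training_set(cfg, N_PER_CLASS, seed=TRAIN_SEED)
    return ec.train_classifier(patches, labels, seed=TRAIN_SEED)


@pytest.fixture(scope="session")
def pipeline_config():
    return ec.PipelineConfig()


@pytest.fixture(scope="session")
def mixed_chip_noisefree():
    """Noise-free 6-trap chip covering all five incubator states."""
    cfg = ec.SimChipConfig(noise_sigma=0.0, frame_count=80, seed=21)
    specs = [
        ec.SimEmbryoSpec(state=S.NORMAL, bean_frame=20, twitch_frame=40, hatch_frame=65),
        ec.SimEmbryoSpec(state=S.DEAD),
        ec.SimEmbryoSpec(state=S.EMPTY),
        ec.SimEmbryoSpec(state=S.UNCLEAR, twitch_frame=25, hatch_frame=60),
        ec.SimEmbryoSpec(state=S.LATE_HATCHING, bean_frame=15, twitch_frame=30),
        ec.SimEmbryoSpec(state=S.NORMAL, bean_frame=12, twitch_frame=28, hatch_frame=55),
    ]
    seq, truth, centroids = ec.simulate_chip(cfg, specs)
    return seq, truth, centroids, cfg


def cohort_chips(n_chips: int, per_chip: int, sigma: float, frame_count: int = 100,
                 seed: int = 11):
    """Seeded stream of (sequence, truth, centroids) mixed-state chips."""
    rng = np.random.default_rng(seed)
    for chip in range(n_chips):
        cfg = ec.SimChipConfig(
            n_incubators=per_chip, noise_sigma=sigma,
            frame_count=frame_count, seed=1000 + chip,
        )
        specs = ec.random_embryo_specs(per_chip, frame_count, rng)
        yield ec.simulate_chip(cfg, specs)
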