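"""Shared fixtures.

Expensive artifacts (pre-training runs, the 5-seed mechanism suite) are
session-scoped and shared between module tests and acceptance tests so
the whole suite stays within a desk-scale compute budget.
"""

import numpy as np
import pytest

from pclr.architecture import EncoderConfig
from pclr.experiments import pretrain_tiny, run_mechanism_suite
from pclr.pretrain import ScratchConfig, train_scratch
from pclr.synthetic import CohortParams, generate_cohort

# encoder small enough for seconds-scale training in unit tests
SMALL_ENCODER = EncoderConfig(input_length=128, conv_filter_size=8,
                              channels_per_stage=(4, 4, 8),
                              representation_dim=8, downsample_per_block=4)


@pytest.fixture(scope="session")
def small_cohort():
    """Six patients with 1-3 visits each (includes ineligible patients)."""
    return generate_cohort(6, (1, 3), seed=42)


@pytest.fixture(scope="session")
def clean_params():
    """Noiseless, wander-free, AF-free world at a fixed 60 bpm."""
    return CohortParams(noise_level_range=(0.0, 0.0),
                        wander_amp_range=(0.0, 0.0),
                        af_carrier_fraction=0.0,
                        hr_baseline_range=(60.0, 60.0),
                        hr_visit_jitter_sd=0.0,
                        sex_hr_offset=0.0,
                        sampling_rates=(250,))


@pytest.fixture(scope="session")
def tiny_pretrained():
    """One seeded desk-scale pre-training run (shared, ~40 s)."""
    return pretrain_tiny(seed=1)


@pytest.fixture(scope="session")
def scratch_small():
    """A full 3x3 scratch grid on a tiny learnable problem (shared).

    Labels depend on mean lead-II amplitude, so every grid cell has
    signal to fit; max_epochs is small to keep the 9 runs fast.
    """
    rng = np.random.default_rng(7)
    X = rng.normal(size=(32, 128, 12))
    X[:, :, 1] += rng.normal(0.0, 1.0, size=(32, 1))
    y = (X[:, :, 1].mean(axis=1) > 0).astype(int)
    result = train_scratch(
        X[:24], y[:24], X[24:], y[24:], "classification",
        encoder_config=SMALL_ENCODER,
        scratch_config=ScratchConfig(max_epochs=8, batch_size=16, seed=0))
    return result


@pytest.fixture(scope="session")
def mechanism_suite():
    """The 5-seed mechanism-recovery suite (shared, ~4 min)."""
    return run_mechanism_suite(base_seed=0, n_seeds=5)
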