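"""Shared fixtures.

The expensive session fixture ``trained_bundle`` performs the scaled-down
learning study once (specific network at 17 spokes/frame plus a generic
variable-rate network on the same phantom corpus) and is shared by the
training-efficacy, warm-up and catheter-visibility tests.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "stable",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("stable")

from radrecon.geometry import SequenceParams
from radrecon.network import UNetSpec, build_model
from radrecon.phantom import PhantomConfig, build_dataset, make_corpus_configs
from radrecon.training import TrainConfig, train

# scaled study conditions: 64-matrix phantoms cropped to 48, 128-sample
# readouts (2x oversampling), hidden widths (8, 16, 32)
SCALED_MATRIX = 64
SCALED_CROP = 48
SCALED_NSAMP = 128
SCALED_HIDDEN = (8, 16, 32)
SCALED_RATES = (13, 17, 21, 25, 29, 33)
SCALED_FRAMES = 12
SCALED_EPOCHS = 100


@pytest.fixture(scope="session")
def seq_params():
    return SequenceParams(n_samples=SCALED_NSAMP)


@pytest.fixture(scope="session")
def smooth_phantom():
    """One static, noise-free mid-cycle phantom frame (matrix 64)."""
    from radrecon.phantom import render_frame

    cfg = PhantomConfig(
        view_class="SAX", matrix=SCALED_MATRIX, noise_sd=0.0, seed=3
    )
    return render_frame(cfg, 0.3)


@pytest.fixture(scope="session")
def scaled_corpus(seq_params):
    """Paired dataset at 17 spokes/frame for the scaled study conditions."""
    base = PhantomConfig(matrix=SCALED_MATRIX, n_frames=SCALED_FRAMES)
    configs = make_corpus_configs(
        per_view=4, split_counts=(2, 1, 1), base=base, seed=0
    )
    return build_dataset(
        configs, seq_params, ("specific", 17), seed=1, crop=SCALED_CROP
    )


@pytest.fixture(scope="session")
def trained_bundle(seq_params, scaled_corpus):
    """Scaled-down learning study: specific@17 and generic networks.

    Returns dict with the two trained models, the test split, and the
    training configuration used.
    """
    base = PhantomConfig(matrix=SCALED_MATRIX, n_frames=SCALED_FRAMES)
    configs = make_corpus_configs(
        per_view=4, split_counts=(2, 1, 1), base=base, seed=0
    )
    generic_ds = build_dataset(
        configs, seq_params, ("generic", SCALED_RATES), seed=2, crop=SCALED_CROP
    )
    cfg = TrainConfig(epochs=SCALED_EPOCHS, seed=0, select_best=True)
    specific = build_model(UNetSpec(hidden=SCALED_HIDDEN), seed=0)
    specific, hist_s = train(specific, scaled_corpus, cfg)
    generic = build_model(UNetSpec(hidden=SCALED_HIDDEN), seed=0)
    generic, hist_g = train(generic, generic_ds, cfg)
    return {
        "specific": specific,
        "generic": generic,
        "test": [s for s in scaled_corpus if s.split == "test"],
        "history_specific": hist_s,
        "history_generic": hist_g,
        "config": cfg,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
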