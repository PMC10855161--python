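"""Shared fixtures: small trained runs reused across test modules.

Training is the expensive step, so cohorts and fitted models are built once
per session.  The evaluation-scale architecture (2 heads x 4 hidden) keeps
single-CPU runtimes in seconds-to-minutes while leaving every mechanism
(multi-level attention, evidence heads, fusion, early stopping) exercised.
"""

import numpy as np
import pytest

from trustomics import pipeline, simdata
from trustomics.encoder import EncoderConfig

N_SEEDS = 5
MASK_RATIOS = (0.0, 0.2, 0.4, 0.6, 0.8)


def eval_encoder_config() -> EncoderConfig:
    return EncoderConfig(n_heads=2, hidden=4, head_hidden=32,
                         dropout=0.0, input_dropout=0.8)


def eval_run_config(seed: int, n_classes: int = 3) -> pipeline.RunConfig:
    return pipeline.RunConfig(seed=seed, n_classes=n_classes, epochs=200,
                              patience=30, weight_decay=0.0,
                              encoder=eval_encoder_config())


def planted_spec(seed: int) -> simdata.SimSpec:
    """3 omics x 50 features, K=3, n=300, effect 1.5: the planted cohort."""
    return simdata.SimSpec(seed=seed)


def complementary_spec(seed: int) -> simdata.SimSpec:
    """Each omics only discriminates one class: fusion is essential."""
    return simdata.SimSpec(seed=seed, signal_classes=((0,), (1,), (2,)))


def quick_spec(seed: int) -> simdata.SimSpec:
    """Tiny binary cohort for fast pipeline mechanics tests."""
    return simdata.SimSpec(seed=seed, n_subjects=90, n_classes=2,
                           n_features=(16, 16),
                           module_sizes=((8, 8), (8, 8)),
                           informative_fraction=(0.25, 0.25),
                           effect_size=1.5)


def quick_config(seed: int) -> pipeline.RunConfig:
    return pipeline.RunConfig(
        seed=seed, n_classes=2, epochs=40, patience=40,
        encoder=EncoderConfig(n_heads=2, hidden=3, head_hidden=16,
                              dropout=0.1))


def train_cohort(spec, config, permute_labels=False):
    blocks, labels = simdata.generate_cohort(spec)
    if permute_labels:
        labels = np.random.default_rng(spec.seed + 1000).permutation(labels)
    run = pipeline.train(blocks, labels, config)
    return blocks, labels, run


@pytest.fixture(scope="session")
def quick_run():
    spec = quick_spec(0)
    blocks, labels, run = train_cohort(spec, quick_config(0))
    return spec, blocks, labels, run


@pytest.fixture(scope="session")
def planted_runs():
    out = []
    for seed in range(N_SEEDS):
        spec = planted_spec(seed)
        blocks, labels, run = train_cohort(spec, eval_run_config(seed))
        out.append((spec, blocks, labels, run))
    return out


@pytest.fixture(scope="session")
def complementary_runs():
    out = []
    for seed in range(N_SEEDS):
        spec = complementary_spec(seed)
        blocks, labels, run = train_cohort(spec, eval_run_config(seed))
        out.append((spec, blocks, labels, run))
    return out
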