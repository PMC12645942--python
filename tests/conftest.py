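"""Shared fixtures: simulated datasets at the standard study conditions."""

from __future__ import annotations

import pytest

from pugtail.pipeline import simulate_and_run
from pugtail.prep import PrimerSet
from pugtail.simulate import SimConfig


CLEAN_CFG = SimConfig(
    seed=7,
    ref_lengths=(3000, 2500),
    n_reads=500,
    pug_rate=0.5,
    tail_len_min=10,
    tail_len_max=60,
    antisense_rate=0.2,
    spike_rate=0.05,
    sub_rate=0.0,
    ins_rate=0.0,
    del_rate=0.0,
    anneal_policy="end",
)

NOISY_CFG = SimConfig(
    seed=7,
    ref_lengths=(3000, 2500),
    n_reads=500,
    pug_rate=0.5,
    tail_len_min=10,
    tail_len_max=60,
    antisense_rate=0.2,
    spike_rate=0.05,
    sub_rate=0.03,
    ins_rate=0.01,
    del_rate=0.01,
    anneal_policy="end",
)


@pytest.fixture(scope="session")
def primers() -> PrimerSet:
    return PrimerSet()


@pytest.fixture(scope="session")
def clean_run():
    """Full pipeline on the 500-read error-free dataset (seed 7)."""
    return simulate_and_run(CLEAN_CFG, k=5)


@pytest.fixture(scope="session")
def noisy_run():
    """Full pipeline on the 500-read dataset with Nanopore-like error rates."""
    return simulate_and_run(NOISY_CFG, k=5)


@pytest.fixture(scope="session")
def small_clean_run():
    """A faster 120-read error-free dataset for unit-level checks."""
    cfg = SimConfig(seed=11, n_reads=120, sub_rate=0.0, ins_rate=0.0, del_rate=0.0)
    return simulate_and_run(cfg, k=5)
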