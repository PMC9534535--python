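"""Shared fixtures.

The session-scoped simulation fixtures run the full experiments once and
are reused by every test that needs real network output: three complete
150-image numerosity sweeps under independent master seeds, and one
150-image synthetic-digit sweep.  These take a few minutes combined; all
other fixtures are cheap.
"""

from __future__ import annotations

import numpy as np
import pytest

from numspike import generate_digit_dataset, generate_numerosity_dataset, simulate_dataset
from numspike.pipeline import analyze_trials

NUMEROSITY_SEEDS = (1, 2, 3)


@pytest.fixture(scope="session")
def numerosity_runs():
    """Full numerosity experiments (150 images each) under three master seeds.

    Returns a list of (curves, averages, fits, distribution) tuples.
    """
    runs = []
    for seed in NUMEROSITY_SEEDS:
        dataset = generate_numerosity_dataset(30, seed=seed)
        trials = simulate_dataset(dataset.images, seed=seed)
        runs.append(analyze_trials(trials))
    return runs


@pytest.fixture(scope="session")
def digit_run():
    """One synthetic-digit experiment: 10 classes x 15 images."""
    dataset = generate_digit_dataset(15, seed=1)
    trials = simulate_dataset(dataset.images, seed=1)
    return analyze_trials(trials, log2_shift=1.0)
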