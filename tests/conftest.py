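"""Shared fixtures: brute-force oracles and the small-sample study run."""

from __future__ import annotations

import numpy as np
import pytest

from tssprev.experiment import CutoffGrid, SimulationConfig, run_experiment
from tssprev.metrics import binarize, confusion_from_binary, tss

STUDY_SEED = 1


@pytest.fixture(scope="session")
def default_grid() -> CutoffGrid:
    return CutoffGrid()


def brute_force_tss_curve(labels, probs, cutoffs):
    """Independent oracle: loop over cutoffs, binarize, tabulate, score."""
    out = []
    for c in cutoffs:
        cm = confusion_from_binary(labels, binarize(probs, c))
        out.append((c, tss(cm).tss))
    return out


def brute_force_max_tss(labels, probs, cutoffs):
    curve = brute_force_tss_curve(labels, probs, cutoffs)
    best_c, best_v = None, -np.inf
    for c, v in curve:  # first (smallest) cutoff wins ties
        if v > best_v:
            best_c, best_v = c, v
    return best_v, best_c


@pytest.fixture(scope="session")
def small_sample_study():
    """Full prevalence sweep at N=100: four scenarios, 19 prevalences,
    1000 replicates per cell, fixed seed.  Shared by the U-shape,
    headline-range and quality-ordering checks."""
    config = SimulationConfig(
        sample_sizes=(100,), n_reps=1000, seed=STUDY_SEED,
    )
    return run_experiment(config)


@pytest.fixture(scope="session")
def large_sample_study():
    """Balanced-prevalence cells at N=10000, 200 replicates per scenario,
    used by the large-sample consistency checks."""
    config = SimulationConfig(
        sample_sizes=(10000,), prevalence_grid=(0.5,), n_reps=200,
        seed=STUDY_SEED,
    )
    return run_experiment(config)
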