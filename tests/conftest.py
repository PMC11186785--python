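"""Shared fixtures: a small reference panel, fitted-scale simulator
parameters and a trained stochastic clock, reused across test modules to
keep the suite fast."""

import numpy as np
import pytest

import stochclock as sc

PAPER_GAMMA = 9.25
PAPER_SIGMA = 0.0005
SMALL_LAMBDA_GRID = np.round(np.arange(0, 21) / 1000.0, 4)


@pytest.fixture(scope="session")
def paper_params():
    return sc.SimParams(PAPER_GAMMA, PAPER_SIGMA)


@pytest.fixture(scope="session")
def panel():
    return sc.make_reference_panel(60, 30, 12, seed=5)


@pytest.fixture(scope="session")
def effects(panel):
    return sc.estimate_effects(panel.young, panel.old)


@pytest.fixture(scope="session")
def cohort_ages():
    return np.arange(45, 84, dtype=float)


@pytest.fixture(scope="session")
def train_cohort(panel, effects, paper_params, cohort_ages):
    return sc.generate_cohort(
        panel.young, effects, paper_params, cohort_ages, 3, seed=100
    )


@pytest.fixture(scope="session")
def select_cohort(panel, effects, paper_params, cohort_ages):
    return sc.generate_cohort(
        panel.young, effects, paper_params, cohort_ages, 3, seed=101
    )


@pytest.fixture(scope="session")
def test_cohort(panel, effects, paper_params, cohort_ages):
    return sc.generate_cohort(
        panel.young, effects, paper_params, cohort_ages, 3, seed=102
    )


@pytest.fixture(scope="session")
def stoc_clock(train_cohort, select_cohort):
    return sc.train_clock(
        train_cohort, select_cohort, lambda_grid=SMALL_LAMBDA_GRID
    )
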