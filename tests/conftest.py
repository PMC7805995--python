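"""Shared fixtures: expensive scenario runs are computed once per session."""

from __future__ import annotations

import math

import pytest

from ctrleffort.codec import ResolutionVector
from ctrleffort.harness import (
    ScenarioConfig,
    random_separable_problems,
    run_scenario,
)
from ctrleffort.optimize import minimize_effort

MASTER_SEED = 1
SEPARABLE_SEED = 20260925


@pytest.fixture(scope="session")
def separable_suite():
    """100 seeded monotone separable problems with their search results."""
    problems = random_separable_problems(100, seed=SEPARABLE_SEED)
    results = [
        minimize_effort(p.constraint, ResolutionVector.from_flat(p.r_init))
        for p in problems
    ]
    return list(zip(problems, results))


@pytest.fixture(scope="session")
def headline_reports():
    """The bundled biological-vs-technical comparison, frozen seeds.

    Six scenario runs (STIM/SENS/TORQUE on the pointing and periodic tasks)
    plus the two delay manipulations (muscle SENS without its sensor delay,
    torque pointing with a 30 ms delay added).
    """
    reports = {}
    for task in ("pointing", "periodic"):
        for scen in ("STIM", "SENS", "TORQUE"):
            reports[(task, scen)] = run_scenario(
                ScenarioConfig(scenario=scen, task=task, seed=MASTER_SEED))
    reports[("pointing", "SENS_no_delay")] = run_scenario(
        ScenarioConfig(scenario="SENS", task="pointing", seed=MASTER_SEED,
                       delay=0.0))
    reports[("pointing", "TORQUE_delay")] = run_scenario(
        ScenarioConfig(scenario="TORQUE", task="pointing", seed=MASTER_SEED,
                       delay=0.03))
    return reports
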