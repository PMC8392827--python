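"""Shared fixtures.

The full-budget particle-swarm identifications are the expensive part of
the suite (tens of seconds each), so they are run once per session here
and shared between the identification tests and the acceptance tests.
All seeds are fixed; every fixture is deterministic.
"""

import numpy as np
import pytest

from fermkin import (
    PSOConfig,
    identify_stage1,
    identify_stage2,
    identify_two_stage,
    reference_constant_dataset,
    reference_step_dataset,
)
from fermkin.datasets import REFERENCE_INIT, REFERENCE_KINETICS

STAGE1_SEEDS = (101, 102, 103, 104, 105)
STAGE2_SEEDS = (201, 202, 203, 204, 205)
NOISY_SEEDS = (301, 302, 303, 304, 305)


@pytest.fixture(scope="session")
def stage1_noiseless_runs():
    """Five full-budget stage-1 identifications on the noiseless
    constant-22 degC reference dataset."""
    ds = reference_constant_dataset()
    return [
        identify_stage1(ds, REFERENCE_INIT, PSOConfig(seed=s)) for s in STAGE1_SEEDS
    ]


@pytest.fixture(scope="session")
def stage2_noiseless_runs():
    """Five full-budget stage-2 identifications on the noiseless step
    dataset (22 -> 27 degC at 3 h), fundamental constants held at truth."""
    ds = reference_step_dataset(3.0)
    return [
        identify_stage2(ds, REFERENCE_KINETICS, REFERENCE_INIT, PSOConfig(seed=s))
        for s in STAGE2_SEEDS
    ]


@pytest.fixture(scope="session")
def stage1_noisy_runs():
    """Stage-1 identifications on datasets with 2%-of-range sensor noise
    (fresh noise realisation per seed)."""
    sd = 0.02 * float(np.ptp(reference_constant_dataset().co2))
    runs = []
    for s in NOISY_SEEDS:
        ds = reference_constant_dataset(seed=s, noise_sd=sd)
        runs.append(identify_stage1(ds, REFERENCE_INIT, PSOConfig(seed=s)))
    return runs


@pytest.fixture(scope="session")
def two_stage_run():
    """One full two-stage identification on the reference dataset pair."""
    return identify_two_stage(
        reference_constant_dataset(), reference_step_dataset(3.0),
        REFERENCE_INIT, PSOConfig(seed=401), PSOConfig(seed=402),
    )
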