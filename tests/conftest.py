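"""Shared fixtures: tiny hand-built chains and session-scoped synthetic runs."""

from __future__ import annotations

import pandas as pd
import pytest

from condelscan.pipeline import Screen, ScreenConfig
from condelscan.synthetic_data import SimulationConfig, simulate_dataset

@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """The noise-free default synthetic bundle plus a completed screen."""
    out = tmp_path_factory.mktemp("bundle_default")
    bundle = simulate_dataset(SimulationConfig(seed=1), out)
    screen = Screen(ScreenConfig.from_yaml(bundle.screen_config))
    return bundle, screen


@pytest.fixture(scope="session")
def violation_run(tmp_path_factory):
    """Bundle planting one locus with 1 and one with 2 outgroup violations.

    Uses 19 outgroups so that a tolerated single violation still leaves 18
    conserved outgroups (above the 17-outgroup conservation floor) and the
    violation filter itself, not the conservation depth, decides the
    two-violation locus.
    """
    out = tmp_path_factory.mktemp("bundle_violation")
    cfg = SimulationConfig(seed=1, n_outgroups=19, violations={3: 1, 7: 2})
    bundle = simulate_dataset(cfg, out)
    screen = Screen(ScreenConfig.from_yaml(bundle.screen_config))
    return bundle, screen


@pytest.fixture(scope="session")
def default_candidates(default_run):
    _, screen = default_run
    return screen.candidates


@pytest.fixture()
def truth_frame(default_run) -> pd.DataFrame:
    bundle, _ = default_run
    return bundle.truth
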