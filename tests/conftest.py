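"""Shared fixtures: a small synthetic study built once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from shorewatch.detection import DetectionLimits
from shorewatch.synthetic import (SyntheticScenario, default_platforms,
                                  simulate_dataset)


@pytest.fixture(scope="session")
def small_scenario() -> SyntheticScenario:
    """A reduced schedule (16 days, 12 scans/day) for fast pipeline tests."""
    return SyntheticScenario(seed=42, days=16, scans_per_day=12)


@pytest.fixture(scope="session")
def small_study(small_scenario):
    sightings, scans, env, truth = simulate_dataset(small_scenario)
    return {"sightings": sightings, "scans": scans, "env": env,
            "truth": truth, "platforms": default_platforms()}


@pytest.fixture(scope="session")
def true_limits(small_study) -> DetectionLimits:
    """Detection limits equal to the scenario's true inflection radii."""
    truth = small_study["truth"]
    return DetectionLimits({
        (p.id, sp, ss): r
        for p in small_study["platforms"]
        for sp, radii in truth["inflection_radii"].items()
        for ss, r in radii.items()})
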