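"""Shared fixtures: the reference distance matrix, reading builders and one
session-scoped simulated cohort that several aggregate-level tests reuse."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import pigwalk as pw

#: location short-hands used when building synthetic reading sequences
LOCS = ("trough", "drinker1", "drinker2", "drinker3", "playing_device")


def make_readings(
    locations: list[str],
    day: str = "2023-01-02",
    animal_id: str = "p1",
    pen_id: str = "pen1",
    start_s: int = 6 * 3600,
    step_s: int = 60,
) -> pd.DataFrame:
    """One animal-day of readings: one reading per entry of *locations*,
    spaced *step_s* seconds apart starting at *start_s* seconds of day."""
    base = pd.Timestamp(day)
    ts = [base + pd.Timedelta(seconds=start_s + i * step_s) for i in range(len(locations))]
    return pd.DataFrame(
        {
            "timestamp": ts,
            "animal_id": animal_id,
            "location_id": locations,
            "pen_id": pen_id,
        }
    )


@pytest.fixture(scope="session")
def table2() -> pw.DistanceMatrix:
    """The bundled five-location center-to-center distance matrix."""
    return pw.bundled_layout().distance_matrix()


@pytest.fixture(scope="session")
def default_cohort():
    """A full default cohort (25 pigs x 120 days, fixed seed) run through
    the whole pipeline once; reused by every test that only reads it."""
    scenario = pw.SimScenario(seed=7)
    truth = pw.simulate_trajectories(scenario)
    readings = pw.detect_cohort(truth, scenario)
    daily, hourly = pw.compute_all(readings, scenario.layout, scenario.cohort_meta())
    return {
        "scenario": scenario,
        "truth": truth,
        "readings": readings,
        "daily": daily,
        "hourly": hourly,
    }


def random_sequence(rng: np.random.Generator, length: int) -> list[str]:
    return [LOCS[i] for i in rng.integers(0, len(LOCS), size=length)]


def brute_force_vwd(locations: list[str], matrix: pw.DistanceMatrix) -> float:
    """Independent oracle: sum pairwise distances over the raw, uncollapsed
    sequence (same-location steps contribute d(x, x) = 0)."""
    return float(
        sum(matrix.distance(a, b) for a, b in zip(locations[:-1], locations[1:]))
    )
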