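"""Synthetic barn: a semi-Markov visit simulator with a detection layer.

The simulator generates what the analysis assumes real data look like: each
pig alternates between a *rest* state (anywhere in the pen not covered by an
antenna) and timed visits to the antenna-equipped locations.  It is a
behavioral caricature, not a fitted model — no distributional form for pig
visits has been published — but it reproduces the structural features the
pipeline must handle:

* 1 Hz potential detections while inside a reading area, thinned by a
  per-location sensitivity (high at the trough, lowest at the drinkers);
* a feeding-driven diurnal rhythm: six daily feedings between 06:00 and
  22:00 raise activity in the hour after each feeding starts, with a
  broader elevated period in the late afternoon and evening;
* a nocturnal rest phase (22:00-06:00) with strongly suppressed activity;
* declining activity across the fattening period (per-stage multipliers);
* stable between-animal differences (per-pig activity multipliers);
* optional lameness episodes that cut a pig's activity for some days and
  leave locomotion-score entries on twice-weekly inspection dates.

Movement between locations is instantaneous at the reading level: the VWD
metric only sees presence inside reading areas, so transit time is folded
into the rest dwell.  Each trajectory starts and ends in rest, so no visit
spans midnight.

Randomness: a single root seed spawns one substream per (pig, day) for the
trajectory and an independent one for the detection thinning, so experiments
that vary sensitivities reuse bit-identical trajectories (paired designs).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import DistanceMatrix
from .io import PenLayout, CohortMeta, bundled_layout, normalize_readings

SECONDS_PER_DAY = 86_400

_DEFAULT_SENSITIVITY = {
    "trough": 0.9,
    "drinker1": 0.6,
    "drinker2": 0.6,
    "drinker3": 0.6,
    "playing_device": 0.75,
}
# where a departing pig heads; troughs dominate, drinkers are brief stops
_DEFAULT_LOCATION_WEIGHTS = {
    "trough": 0.35,
    "drinker1": 0.15,
    "drinker2": 0.15,
    "drinker3": 0.15,
    "playing_device": 0.20,
}
# mean visit dwell, seconds
_DEFAULT_DWELL_MEAN_S = {
    "trough": 60.0,
    "drinker1": 15.0,
    "drinker2": 15.0,
    "drinker3": 15.0,
    "playing_device": 30.0,
}


def synthetic_pen_layout() -> PenLayout:
    """The reference pen with its published distance matrix plus a frozen
    synthetic planar embedding (matrix wins; the embedding only exists so
    the simulated pen is geometrically consistent)."""
    ref = resources.files("pigwalk.data").joinpath("synthetic_pen_coords.json")
    coords = json.loads(ref.read_text(encoding="utf-8"))["locations"]
    coords = {k: (float(x), float(y)) for k, (x, y) in coords.items()}
    return PenLayout(coordinates=coords, matrix=bundled_layout().matrix)


@dataclass(frozen=True)
class LamenessEvent:
    """One injected lameness episode.

    The pig's activity rate is multiplied by ``activity_factor`` from
    ``onset_day`` (fattening day, 1-based) for ``duration_days`` days, and
    locomotion scores are recorded on twice-weekly inspection days during
    the episode (score 2 in the first week, 1 afterwards).
    """

    pig: int
    onset_day: int
    activity_factor: float = 0.3
    duration_days: int = 14


@dataclass
class SimScenario:
    """Configuration of one simulated fattening cohort.

    Rates and dwell constants are deliberately part of the scenario, not
    buried in code: defaults put daily VWD roughly in the 10-800 m band
    with cohort means of a few hundred meters per day early in fattening.
    """

    n_pigs: int = 25
    n_days: int = 120
    pen_id: str = "pen1"
    start_date: date = date(2023, 1, 2)  # a Monday; inspections Mon + Thu
    #: feeding start hours (six liquid-feed distributions, 06:00-22:00)
    feeding_hours: tuple[int, ...] = (6, 9, 12, 15, 18, 22)
    #: nocturnal rest window [start, end) in hours, wrapping midnight
    rest_window: tuple[int, int] = (22, 6)
    #: hours of the broad late-afternoon/evening activity elevation
    evening_hours: tuple[int, ...] = (17, 18, 19, 20, 21)
    #: per-location probability that a present pig is read in a given second
    sensitivity: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_SENSITIVITY)
    )
    location_weights: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_LOCATION_WEIGHTS)
    )
    dwell_mean_s: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_DWELL_MEAN_S)
    )
    #: rest-state departure rate (per second) before modulation
    base_departure_rate: float = 8.0e-4
    #: rate multipliers: hour after a feeding starts / evening block / rest
    feeding_boost: float = 1.6
    evening_boost: float = 1.8
    rest_suppression: float = 0.1
    #: probability of chaining straight into another visit without resting
    chain_prob: float = 0.15
    #: lognormal sigma of the per-pig activity multiplier (unit mean)
    pig_sigma: float = 0.35
    #: activity multiplier per fattening stage
    stage_multipliers: tuple[float, ...] = (1.0, 0.8, 0.6, 0.5)
    stage_boundaries: tuple[int, ...] = (30, 60, 90)
    lameness_events: tuple[LamenessEvent, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for loc, s in self.sensitivity.items():
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"sensitivity[{loc!r}] = {s} outside [0, 1]")
        if any(m < 0 for m in self.stage_multipliers):
            raise ValueError("stage multipliers must be nonnegative")
        if any(not 0 <= h < 24 for h in self.feeding_hours):
            raise ValueError("feeding hours must lie in [0, 24)")
        if len(self.stage_multipliers) != len(self.stage_boundaries) + 1:
            raise ValueError(
                "need one stage multiplier per stage "
                f"({len(self.stage_boundaries) + 1})"
            )

    # -- derived pieces -------------------------------------------------

    @property
    def layout(self) -> PenLayout:
        return synthetic_pen_layout()

    @property
    def locations(self) -> tuple[str, ...]:
        return tuple(self.location_weights)

    def cohort_meta(self) -> CohortMeta:
        return CohortMeta({self.pen_id: self.start_date})

    def animal_ids(self) -> list[str]:
        return [f"pig{i + 1:03d}" for i in range(self.n_pigs)]

    def stage_multiplier(self, fattening_day: int) -> float:
        idx = int(np.searchsorted(self.stage_boundaries, fattening_day))
        return self.stage_multipliers[idx]

    def lameness_multiplier(self, pig: int, fattening_day: int) -> float:
        m = 1.0
        for ev in self.lameness_events:
            if ev.pig == pig and ev.onset_day <= fattening_day < ev.onset_day + ev.duration_days:
                m *= ev.activity_factor
        return m

    def pig_multipliers(self) -> np.ndarray:
        """Per-pig activity multipliers, lognormal with unit mean; drawn
        from their own substream so trajectories are unaffected by n_pigs
        bookkeeping elsewhere."""
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 999_983]))
        if self.pig_sigma == 0:
            return np.ones(self.n_pigs)
        mu = -0.5 * self.pig_sigma**2  # unit-mean lognormal
        return rng.lognormal(mu, self.pig_sigma, size=self.n_pigs)

    def hour_intensity(self) -> np.ndarray:
        """Relative departure intensity per hour of day (before per-pig,
        per-stage and lameness modulation)."""
        intensity = np.ones(24)
        for h in self.feeding_hours:
            intensity[h] *= self.feeding_boost
        for h in self.evening_hours:
            intensity[h] *= self.evening_boost
        lo, hi = self.rest_window
        hours = np.arange(24)
        in_rest = (hours >= lo) | (hours < hi) if lo > hi else (lo <= hours) & (hours < hi)
        intensity[in_rest] *= self.rest_suppression
        return intensity

    def to_json(self) -> str:
        d = asdict(self)
        d["start_date"] = self.start_date.isoformat()
        return json.dumps(d, indent=2, default=list)


@dataclass
class GroundTruth:
    """True behavior behind a simulated reading stream.

    ``daily``: one row per (animal, date) with the true center-path length
    in meters (sum of matrix distances over the pig's actual visit
    sequence, detected or not) and the visit count.  ``visits``: the full
    visit log (location, entry and exit second of day).  The true path
    length is an upper bound on any VWD computed from a detected subset.
    """

    daily: pd.DataFrame
    visits: pd.DataFrame


def _trajectory_rng(scenario: SimScenario, pig: int, day: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([scenario.seed, pig, day, 0]))


def _detection_rng(scenario: SimScenario, pig: int, day: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([scenario.seed, pig, day, 1]))


def simulate_day(
    scenario: SimScenario,
    pig: int,
    day: int,
    rng: np.random.Generator | None = None,
    pig_multiplier: float | None = None,
) -> tuple[pd.DataFrame, float]:
    """Simulate one pig's visit trajectory for one day.

    Parameters
    ----------
    scenario, pig, day
        Scenario plus 0-based pig and day indices (day 0 is fattening
        day 1).
    rng
        Trajectory substream; derived from the scenario seed when omitted.
    pig_multiplier
        This pig's activity multiplier; drawn from the scenario when
        omitted.

    Returns
    -------
    visits, true_path_m
        Visit log (columns ``location_id``, ``entry_s``, ``exit_s``;
        seconds of day, integer, ``[entry, exit)``) and the true
        center-path length over the visit sequence in meters.

    Notes
    -----
    Rest-state departures follow an inhomogeneous exponential clock with a
    piecewise-constant (hourly) rate; visit dwells are exponential, rounded
    to whole seconds (min 1 s); after a visit the pig chains directly to a
    different location with probability ``chain_prob``, otherwise it
    returns to rest.  The day starts and ends in rest.
    """
    if rng is None:
        rng = _trajectory_rng(scenario, pig, day)
    if pig_multiplier is None:
        pig_multiplier = float(scenario.pig_multipliers()[pig])
    fattening_day = day + 1
    mult = (
        pig_multiplier
        * scenario.stage_multiplier(fattening_day)
        * scenario.lameness_multiplier(pig, fattening_day)
    )
    rates = scenario.base_departure_rate * mult * scenario.hour_intensity()
    # cumulative hazard at hour boundaries 0..24
    cum_haz = np.r_[0.0, np.cumsum(rates * 3600.0)]
    boundaries = np.arange(25) * 3600.0

    def hazard_at(t: float) -> float:
        h = min(int(t // 3600), 23)
        return cum_haz[h] + rates[h] * (t - boundaries[h])

    def time_at_hazard(target: float) -> float:
        if target >= cum_haz[-1]:
            return float(SECONDS_PER_DAY)
        h = int(np.searchsorted(cum_haz, target, side="right")) - 1
        if rates[h] == 0:
            return boundaries[h + 1]
        return boundaries[h] + (target - cum_haz[h]) / rates[h]

    locs = list(scenario.location_weights)
    weights = np.array([scenario.location_weights[loc] for loc in locs], dtype=float)
    weights = weights / weights.sum()
    cum_w = np.cumsum(weights)
    dwell_means = np.array([scenario.dwell_mean_s[loc] for loc in locs])

    visit_loc: list[int] = []
    visit_entry: list[int] = []
    visit_exit: list[int] = []

    t = 0.0
    while True:
        target = hazard_at(t) + rng.standard_exponential()
        t = time_at_hazard(target)
        if t >= SECONDS_PER_DAY:
            break
        k = int(np.searchsorted(cum_w, rng.random(), side="right"))
        while True:
            entry = int(t)
            dwell = max(1, int(round(rng.exponential(dwell_means[k]))))
            exit_ = min(entry + dwell, SECONDS_PER_DAY)
            if exit_ > entry:
                visit_loc.append(k)
                visit_entry.append(entry)
                visit_exit.append(exit_)
            t = float(exit_)
            if t >= SECONDS_PER_DAY or rng.random() >= scenario.chain_prob:
                break
            # chain: hop directly to one of the other locations
            others = np.flatnonzero(np.arange(len(locs)) != k)
            w = weights[others] / weights[others].sum()
            k = int(others[np.searchsorted(np.cumsum(w), rng.random(), side="right")])

    matrix = scenario.layout.distance_matrix().reindex(locs)
    codes = np.array(visit_loc, dtype=int)
    true_path = float(matrix.values[codes[:-1], codes[1:]].sum()) if len(codes) > 1 else 0.0
    visits = pd.DataFrame(
        {
            "location_id": [locs[k] for k in visit_loc],
            "entry_s": np.array(visit_entry, dtype=np.int64),
            "exit_s": np.array(visit_exit, dtype=np.int64),
        }
    )
    return visits, true_path


def apply_detection(
    visits: pd.DataFrame,
    scenario: SimScenario,
    rng: np.random.Generator,
    sensitivity: Mapping[str, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Thin one day's visit log into detected seconds.

    Every whole second a pig spends inside a reading area (``[entry_s,
    exit_s)``) is independently detected with the location's sensitivity.
    One uniform draw is consumed per visit-second in visit order, so two
    calls with the same *rng* state and different sensitivities detect
    nested subsets of the same seconds (the coupling behind paired
    sensitivity experiments).

    Returns
    -------
    seconds, locations
        Detected seconds of day (int64) and the matching location ids.
    """
    sens = dict(scenario.sensitivity if sensitivity is None else sensitivity)
    sec_list: list[np.ndarray] = []
    loc_list: list[np.ndarray] = []
    for loc, entry, exit_ in zip(
        visits["location_id"], visits["entry_s"], visits["exit_s"]
    ):
        n = int(exit_ - entry)
        u = rng.random(n)
        hit = u < sens[loc]
        if hit.any():
            secs = np.arange(entry, exit_, dtype=np.int64)[hit]
            sec_list.append(secs)
            loc_list.append(np.full(len(secs), loc, dtype=object))
    if not sec_list:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=object)
    return np.concatenate(sec_list), np.concatenate(loc_list)


def simulate_trajectories(scenario: SimScenario) -> GroundTruth:
    """Simulate all pig-day trajectories of a cohort (no detection layer)."""
    ids = scenario.animal_ids()
    mults = scenario.pig_multipliers()
    day_rows = []
    visit_frames = []
    for pig in range(scenario.n_pigs):
        for day in range(scenario.n_days):
            visits, true_path = simulate_day(
                scenario, pig, day, pig_multiplier=float(mults[pig])
            )
            d = scenario.start_date + timedelta(days=day)
            day_rows.append(
                (ids[pig], pd.Timestamp(d), day + 1, true_path, len(visits))
            )
            if not visits.empty:
                v = visits.copy()
                v.insert(0, "date", pd.Timestamp(d))
                v.insert(0, "animal_id", ids[pig])
                visit_frames.append(v)
    daily = pd.DataFrame(
        day_rows,
        columns=["animal_id", "date", "fattening_day", "true_path_m", "n_visits"],
    )
    visits = (
        pd.concat(visit_frames, ignore_index=True)
        if visit_frames
        else pd.DataFrame(columns=["animal_id", "date", "location_id", "entry_s", "exit_s"])
    )
    return GroundTruth(daily=daily, visits=visits)


def detect_cohort(
    truth: GroundTruth,
    scenario: SimScenario,
    sensitivity: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Run the detection layer over a cohort's trajectories.

    Detection substreams depend only on (seed, pig, day), never on the
    sensitivities, so calling this twice on the same trajectories with
    different sensitivities yields paired (nested) reading sets.
    """
    ids = {a: i for i, a in enumerate(scenario.animal_ids())}
    parts_ts: list[np.ndarray] = []
    parts_loc: list[np.ndarray] = []
    parts_animal: list[np.ndarray] = []
    for (animal, d), group in truth.visits.groupby(["animal_id", "date"], sort=True):
        day = (d.date() - scenario.start_date).days
        rng = _detection_rng(scenario, ids[animal], day)
        secs, locs = apply_detection(group, scenario, rng, sensitivity)
        if len(secs):
            base = np.datetime64(d, "s")
            parts_ts.append(base + secs.astype("timedelta64[s]"))
            parts_loc.append(locs)
            parts_animal.append(np.full(len(secs), animal, dtype=object))
    if not parts_ts:
        return pd.DataFrame(columns=["timestamp", "animal_id", "location_id", "pen_id"])
    readings = pd.DataFrame(
        {
            "timestamp": pd.DatetimeIndex(np.concatenate(parts_ts)),
            "animal_id": np.concatenate(parts_animal),
            "location_id": np.concatenate(parts_loc),
            "pen_id": scenario.pen_id,
        }
    )
    return normalize_readings(readings)


def _inspection_days(scenario: SimScenario) -> np.ndarray:
    """Fattening days (1-based) on which locomotion is scored: twice a
    week, Mondays and Thursdays."""
    days = np.arange(1, scenario.n_days + 1)
    weekday = np.array(
        [(scenario.start_date + timedelta(days=int(d) - 1)).weekday() for d in days]
    )
    return days[(weekday == 0) | (weekday == 3)]


def lameness_health_records(scenario: SimScenario) -> pd.DataFrame:
    """Locomotion-score rows generated by the scenario's lameness events:
    score 2 during the first week of an episode, 1 afterwards, on the
    twice-weekly inspection days that fall inside the episode."""
    ids = scenario.animal_ids()
    rows = []
    obs_days = _inspection_days(scenario)
    for ev in scenario.lameness_events:
        for d in obs_days:
            if ev.onset_day <= d < ev.onset_day + ev.duration_days:
                score = 2 if d < ev.onset_day + 7 else 1
                rows.append(
                    (
                        ids[ev.pig],
                        pd.Timestamp(scenario.start_date + timedelta(days=int(d) - 1)),
                        score,
                    )
                )
    return pd.DataFrame(rows, columns=["animal_id", "date", "locomotion_score"]).sort_values(
        ["animal_id", "date"]
    ).reset_index(drop=True)


@dataclass
class SimResult:
    """Everything a simulated cohort produces."""

    readings: pd.DataFrame
    truth: GroundTruth
    health: pd.DataFrame
    scenario: SimScenario


def simulate_cohort(scenario: SimScenario) -> SimResult:
    """Simulate a cohort end to end: trajectories, detection, health rows.

    Fully reproducible for a given scenario seed; the readings table uses
    the same CSV schema the pipeline ingests.
    """
    truth = simulate_trajectories(scenario)
    readings = detect_cohort(truth, scenario)
    health = lameness_health_records(scenario)
    return SimResult(readings=readings, truth=truth, health=health, scenario=scenario)
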