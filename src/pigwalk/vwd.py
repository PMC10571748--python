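"""Virtual walking distance (VWD).

One antenna reading proves an animal was inside that antenna's reading area
at that second.  Two consecutive readings at *different* antennas prove it
covered at least the center-to-center distance between them.  Summing those
distances over the visiting order within a calendar day gives the virtual
walking distance: a lower-bound activity proxy, not the true distance walked
(pigs also move where no antenna sees them).

Rules of the computation:

* Runs of consecutive readings at the same antenna contribute nothing
  (d(x, x) = 0), so the reading stream is first collapsed to the sequence of
  distinct-location visits.
* Each calendar day is scored in isolation; no transition spans midnight.
  The nocturnal rest phase makes cross-midnight moves rare, and a day's sum
  should reflect that day's movement only.
* A single detection counts: there is no minimum visit duration, because a
  lone reading of a pig passing by is still proof of presence.
* A day with no readings is *missing*, never zero.
* Each transition's distance is credited to the hour in which the animal
  first appears at the destination antenna (the arrival hour) — the earliest
  second at which the movement is known to be complete.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as _date

import numpy as np
import pandas as pd

from .geometry import DistanceMatrix
from .io import CohortMeta, PenLayout

HOUR_COLUMNS = [f"h{h:02d}" for h in range(24)]

DAILY_COLUMNS = [
    "animal_id",
    "pen_id",
    "date",
    "fattening_day",
    "vwd_m",
    "n_readings",
    "n_transitions",
]


@dataclass(frozen=True)
class DailyVWD:
    """One animal-day: summed transition distance and bookkeeping counts."""

    animal_id: str
    date: _date
    vwd_m: float
    n_readings: int
    n_transitions: int
    fattening_day: int | None = None


@dataclass(frozen=True)
class HourlyVWD:
    """One animal-day's distance split into 24 hour bins ([h:00, h+1:00))."""

    animal_id: str
    date: _date
    bins: np.ndarray  # 24 nonnegative floats summing to the day's vwd_m

    def total(self) -> float:
        return float(self.bins.sum())


def collapse_runs(readings: pd.DataFrame) -> pd.DataFrame:
    """Collapse consecutive same-location readings into visits.

    Parameters
    ----------
    readings
        Time-sorted readings of one animal-day with columns ``timestamp``
        and ``location_id``.

    Returns
    -------
    DataFrame with one row per visit — ``location_id``, ``t_first``,
    ``t_last`` (first and last detection of the run) — in visiting order; no
    two consecutive rows share a location.
    """
    if readings.empty:
        return pd.DataFrame(columns=["location_id", "t_first", "t_last"])
    loc = readings["location_id"].to_numpy()
    ts = readings["timestamp"].to_numpy()
    starts = np.flatnonzero(np.r_[True, loc[1:] != loc[:-1]])
    ends = np.r_[starts[1:], len(loc)] - 1
    return pd.DataFrame(
        {"location_id": loc[starts], "t_first": ts[starts], "t_last": ts[ends]}
    )


def _transition_distances(
    visits: pd.DataFrame, matrix: DistanceMatrix
) -> np.ndarray:
    idx = matrix.index()
    try:
        codes = np.array([idx[loc] for loc in visits["location_id"]])
    except KeyError as e:
        raise KeyError(f"location {e.args[0]!r} absent from distance matrix") from None
    if len(codes) < 2:
        return np.empty(0)
    return matrix.values[codes[:-1], codes[1:]]


def daily_vwd(readings: pd.DataFrame, matrix: DistanceMatrix) -> DailyVWD:
    """Virtual walking distance of one animal on one calendar date.

    ``vwd_m`` is the sum of matrix distances over consecutive collapsed
    visits; a day spent at a single location scores 0 m with 0 transitions.
    All readings must share one animal and one date.
    """
    if readings.empty:
        raise ValueError("daily_vwd needs at least one reading; absent days are missing, not zero")
    animals = readings["animal_id"].unique()
    dates = readings["timestamp"].dt.normalize().unique()
    if len(animals) != 1 or len(dates) != 1:
        raise ValueError("daily_vwd expects readings of exactly one animal-day")
    visits = collapse_runs(readings)
    dists = _transition_distances(visits, matrix)
    return DailyVWD(
        animal_id=animals[0],
        date=pd.Timestamp(dates[0]).date(),
        vwd_m=float(dists.sum()),
        n_readings=len(readings),
        n_transitions=len(dists),
    )


def hourly_vwd(readings: pd.DataFrame, matrix: DistanceMatrix) -> HourlyVWD:
    """Split one animal-day's VWD into 24 hour bins.

    Each transition's distance lands in the hour bin of the arriving
    visit's first detection; the bins sum to the daily total exactly.
    """
    day = daily_vwd(readings, matrix)  # validates the input
    visits = collapse_runs(readings)
    dists = _transition_distances(visits, matrix)
    bins = np.zeros(24)
    if len(dists):
        arrival_hours = pd.DatetimeIndex(visits["t_first"].iloc[1:]).hour.to_numpy()
        np.add.at(bins, arrival_hours, dists)
    return HourlyVWD(animal_id=day.animal_id, date=day.date, bins=bins)


def compute_all(
    readings: pd.DataFrame,
    layout: PenLayout,
    meta: CohortMeta,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-animal daily and hourly VWD tables for a whole reading stream.

    Parameters
    ----------
    readings
        Normalized reading stream (sorted, de-duplicated) covering any
        number of animals, pens and days.
    layout
        Pen layout whose distance matrix covers every location present.
    meta
        Fattening-period start date per pen; ``fattening_day`` is
        ``1 + (date - start)``, so the move-in day is fattening day 1.

    Returns
    -------
    daily, hourly
        ``daily`` has one row per (animal, date) with at least one reading,
        columns :data:`DAILY_COLUMNS`; ``hourly`` has the same rows keyed
        (animal_id, date) with columns ``h00`` … ``h23``.  Both are sorted
        by (animal_id, date).
    """
    matrix = layout.distance_matrix()
    if readings.empty:
        daily = pd.DataFrame(columns=DAILY_COLUMNS)
        hourly = pd.DataFrame(columns=["animal_id", "date"] + HOUR_COLUMNS)
        return daily, hourly

    df = readings.sort_values(
        ["animal_id", "timestamp", "location_id"], kind="mergesort"
    )
    idx = matrix.index()
    loc_codes = df["location_id"].map(idx)
    if loc_codes.isna().any():
        missing = sorted(df.loc[loc_codes.isna(), "location_id"].unique())
        raise KeyError(f"location(s) absent from distance matrix: {missing}")
    loc = loc_codes.to_numpy(dtype=np.int64)

    animal_codes, animal_labels = pd.factorize(df["animal_id"], sort=True)
    days = df["timestamp"].to_numpy().astype("datetime64[D]")
    day_ints = days.astype(np.int64)
    day_span = day_ints.max() - day_ints.min() + 1
    group = animal_codes * day_span + (day_ints - day_ints.min())
    gid, group_keys = pd.factorize(group)  # appearance order == sorted order
    n_groups = len(group_keys)

    # collapse same-location runs within each animal-day
    new_group = np.r_[True, gid[1:] != gid[:-1]]
    keep = new_group | np.r_[True, loc[1:] != loc[:-1]]
    cgid = gid[keep]
    cloc = loc[keep]
    cts = df["timestamp"].to_numpy()[keep]

    trans = np.flatnonzero(cgid[1:] == cgid[:-1]) + 1  # arrival rows
    dist = matrix.values[cloc[trans - 1], cloc[trans]]
    tgid = cgid[trans]

    vwd = np.bincount(tgid, weights=dist, minlength=n_groups)
    n_trans = np.bincount(tgid, minlength=n_groups)
    n_read = np.bincount(gid, minlength=n_groups)

    first_of_group = np.flatnonzero(new_group)
    g_animal = animal_labels[animal_codes[first_of_group]]
    g_day = days[first_of_group]
    g_pen = df["pen_id"].to_numpy()[first_of_group]

    starts = np.array(
        [np.datetime64(meta.start_of(p), "D") for p in pd.unique(g_pen)]
    )
    start_map = dict(zip(pd.unique(g_pen), starts))
    fat_day = np.array(
        [(d - start_map[p]).astype(int) + 1 for d, p in zip(g_day, g_pen)]
    )

    daily = pd.DataFrame(
        {
            "animal_id": g_animal,
            "pen_id": g_pen,
            "date": g_day,
            "fattening_day": fat_day,
            "vwd_m": vwd,
            "n_readings": n_read,
            "n_transitions": n_trans,
        }
    )

    hours = pd.DatetimeIndex(cts[trans]).hour.to_numpy()
    hbins = np.zeros((n_groups, 24))
    np.add.at(hbins, (tgid, hours), dist)
    hourly = pd.DataFrame(hbins, columns=HOUR_COLUMNS)
    hourly.insert(0, "date", g_day)
    hourly.insert(0, "animal_id", g_animal)

    order = np.lexsort((g_day, g_animal))
    daily = daily.iloc[order].reset_index(drop=True)
    hourly = hourly.iloc[order].reset_index(drop=True)
    daily["date"] = pd.to_datetime(daily["date"])
    hourly["date"] = pd.to_datetime(hourly["date"])
    return daily, hourly
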