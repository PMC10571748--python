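"""Readers, writers and shared domain containers.

The pipeline's working containers are plain :class:`pandas.DataFrame` objects
with documented schemas (the column-name constants below); the structured
inputs — pen layout and cohort metadata — get small dataclasses.  All files
are UTF-8 CSV (or JSON for the layout) with ISO 8601 timestamps at 1 s
resolution, the native cadence of the readers: each antenna registers a tag
at most once per second.

Timestamps are naive local clock time throughout; the barn has no timezone
and daylight-saving handling is out of scope (documented limitation).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import date
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .geometry import DistanceMatrix, distance_matrix_from_coords, matrix_from_frame

logger = logging.getLogger(__name__)

#: readings CSV schema, in canonical column order
READING_COLUMNS = ["timestamp", "animal_id", "location_id", "pen_id"]
#: health CSV schema
HEALTH_COLUMNS = ["animal_id", "date", "locomotion_score"]
#: admissible locomotion scores (0 sound … 3 reluctant to walk)
LOCOMOTION_SCORES = (0, 1, 2, 3)

#: tolerance (m) above which an explicit matrix is reported as inconsistent
#: with coordinate-derived distances
LAYOUT_CONSISTENCY_TOL = 0.05


class PigwalkIOError(ValueError):
    """Malformed input file."""


@dataclass
class PenLayout:
    """Registry of antenna locations in one pen.

    At least one of *coordinates* (2-D antenna centers, meters) or *matrix*
    (explicit pairwise distances) must be given.  When both are present the
    explicit matrix is authoritative — a surveyed matrix beats coordinates
    digitised from a floor plan.
    """

    coordinates: dict[str, tuple[float, float]] | None = None
    matrix: DistanceMatrix | None = None

    def __post_init__(self) -> None:
        if self.coordinates is None and self.matrix is None:
            raise ValueError("layout needs coordinates or an explicit matrix")
        if len(self.locations) < 2:
            raise ValueError("layout needs at least two locations")
        if self.coordinates is not None and self.matrix is not None:
            if set(self.coordinates) != set(self.matrix.locations):
                raise ValueError(
                    "coordinate and matrix location sets disagree"
                )

    @property
    def locations(self) -> tuple[str, ...]:
        if self.matrix is not None:
            return self.matrix.locations
        return tuple(self.coordinates)  # type: ignore[arg-type]

    def distance_matrix(self) -> DistanceMatrix:
        """The effective distance matrix (explicit wins over derived)."""
        if self.matrix is not None:
            return self.matrix
        return distance_matrix_from_coords(self.coordinates)


@dataclass(frozen=True)
class CohortMeta:
    """Per-pen fattening-period start dates (move-in day = fattening day 1)."""

    start_dates: Mapping[str, date] = field(default_factory=dict)

    def start_of(self, pen_id: str) -> date:
        try:
            return self.start_dates[pen_id]
        except KeyError:
            raise KeyError(f"pen {pen_id!r} has no fattening start date") from None


def normalize_readings(df: pd.DataFrame) -> pd.DataFrame:
    """Sort by (animal_id, timestamp, location_id) and drop exact duplicate
    triples.  Ingestion through this function is idempotent."""
    out = df.loc[:, READING_COLUMNS].copy()
    out = out.drop_duplicates(subset=["animal_id", "timestamp", "location_id"])
    out = out.sort_values(
        ["animal_id", "timestamp", "location_id"], kind="mergesort"
    ).reset_index(drop=True)
    return out


def read_readings(path: str | Path, layout: PenLayout) -> pd.DataFrame:
    """Load an RFID reading stream.

    Parameters
    ----------
    path
        CSV with header columns ``timestamp, animal_id, location_id, pen_id``.
    layout
        Active pen layout; rows whose ``location_id`` is not registered
        there are rejected (counted in the log, not raised — a mistyped
        antenna id in a multi-month stream should not kill the run).

    Returns
    -------
    DataFrame sorted by (animal_id, timestamp, location_id) with exact
    duplicate detections removed.

    Raises
    ------
    PigwalkIOError
        On a missing column, an unparseable timestamp (reported with its
        line number) or sub-second timestamps.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in READING_COLUMNS if c not in df.columns]
    if missing:
        raise PigwalkIOError(f"{path}: missing required column(s) {missing}")

    ts = pd.to_datetime(df["timestamp"], format="ISO8601", errors="coerce")
    bad = np.flatnonzero(ts.isna().to_numpy())
    if bad.size:
        lines = ", ".join(str(i + 2) for i in bad[:10])  # +2: header + 1-based
        raise PigwalkIOError(
            f"{path}: {bad.size} unparseable timestamp(s) at line(s) {lines}"
        )
    if (ts != ts.dt.floor("s")).any():
        raise PigwalkIOError(f"{path}: timestamps must have whole-second resolution")
    df = df.assign(timestamp=ts)

    known = set(layout.locations)
    unknown = ~df["location_id"].isin(known)
    if unknown.any():
        rejected = df.loc[unknown, "location_id"].value_counts()
        logger.warning(
            "%s: rejected %d row(s) with unknown location_id: %s",
            path,
            int(unknown.sum()),
            dict(rejected),
        )
        df = df.loc[~unknown]
    return normalize_readings(df)


def _matrix_from_mapping(block: Mapping[str, Mapping[str, float]]) -> DistanceMatrix:
    locs = list(block)
    frame = pd.DataFrame(0.0, index=locs, columns=locs)
    for a, row in block.items():
        for b, v in row.items():
            if b not in frame.columns:
                raise PigwalkIOError(
                    f"distance_matrix entry {a!r}->{b!r} references unknown id"
                )
            frame.loc[a, b] = float(v)
    vals = frame.to_numpy()
    # a triangular mapping is accepted; one-sided entries are mirrored
    lower_missing = (vals == 0) & (vals.T != 0)
    vals[lower_missing] = vals.T[lower_missing]
    if not np.array_equal(vals, vals.T):
        raise PigwalkIOError("distance_matrix block is asymmetric")
    return matrix_from_frame(pd.DataFrame(vals, index=locs, columns=locs))


def read_layout(path: str | Path) -> PenLayout:
    """Load a pen layout from JSON.

    The file carries ``locations`` (id → [x, y] meters), ``distance_matrix``
    (id × id meters, triangular accepted) or both.  With both present the
    explicit matrix wins; a warning is logged if any coordinate-derived
    distance differs from it by more than 0.05 m.
    """
    with open(path, encoding="utf-8") as fh:
        cfg = json.load(fh)
    coords = cfg.get("locations")
    if coords is not None:
        coords = {loc: (float(xy[0]), float(xy[1])) for loc, xy in coords.items()}
    matrix = None
    if "distance_matrix" in cfg:
        matrix = _matrix_from_mapping(cfg["distance_matrix"])
    if coords is None and matrix is None:
        raise PigwalkIOError(
            f"{path}: layout needs a 'locations' and/or 'distance_matrix' block"
        )
    if coords is not None and matrix is not None:
        derived = distance_matrix_from_coords(coords).reindex(matrix.locations)
        dev = np.abs(derived.values - matrix.values)
        if dev.max() > LAYOUT_CONSISTENCY_TOL:
            i, j = np.unravel_index(np.argmax(dev), dev.shape)
            logger.warning(
                "%s: explicit matrix disagrees with coordinates by up to "
                "%.3f m (d(%s, %s)); using the explicit matrix",
                path,
                float(dev.max()),
                matrix.locations[i],
                matrix.locations[j],
            )
    return PenLayout(coordinates=coords, matrix=matrix)


def bundled_layout() -> PenLayout:
    """The five-location reference pen (trough, three drinkers, playing
    device) with its published center-to-center distance matrix."""
    ref = resources.files("pigwalk.data").joinpath("table2_layout.json")
    with resources.as_file(ref) as p:
        return read_layout(p)


def read_health(path: str | Path) -> pd.DataFrame:
    """Load locomotion-score observations.

    CSV with columns ``animal_id, date, locomotion_score``; scores must be
    integers 0–3 (0 = no signs of lameness, 3 = reluctant to walk).  Returns
    records sorted by (animal_id, date).
    """
    df = pd.read_csv(path, dtype={"animal_id": str})
    missing = [c for c in HEALTH_COLUMNS if c not in df.columns]
    if missing:
        raise PigwalkIOError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        return df.loc[:, HEALTH_COLUMNS].assign(
            date=pd.Series(dtype="datetime64[ns]"),
            locomotion_score=pd.Series(dtype=int),
        )
    df["date"] = pd.to_datetime(df["date"], errors="coerce")
    if df["date"].isna().any():
        bad = np.flatnonzero(df["date"].isna().to_numpy())[:10] + 2
        raise PigwalkIOError(
            f"{path}: unparseable date(s) at line(s) {list(bad)}"
        )
    score = pd.to_numeric(df["locomotion_score"], errors="coerce")
    ok = score.isin(LOCOMOTION_SCORES)
    if not ok.all():
        bad = np.flatnonzero(~ok.to_numpy())[:10] + 2
        raise PigwalkIOError(
            f"{path}: locomotion_score outside 0-3 at line(s) {list(bad)}"
        )
    df["locomotion_score"] = score.astype(int)
    return (
        df.loc[:, HEALTH_COLUMNS]
        .sort_values(["animal_id", "date"], kind="mergesort")
        .reset_index(drop=True)
    )


def write_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as CSV with header, preserving column order.

    Floats are written at full repr precision so that a write/read
    round-trip reproduces distances to well below 1e-9 m.
    """
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    rows.to_csv(path, index=False)


def read_table(path: str | Path, parse_dates: list[str] | None = None) -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    return pd.read_csv(path, dtype={c: str for c in ("animal_id", "pen_id")},
                       parse_dates=parse_dates or [])
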