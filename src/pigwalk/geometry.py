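"""Inter-antenna distance matrices.

The activity measure downstream is a sum of center-to-center Euclidean
distances between consecutively visited antenna reading areas, so the
distance matrix is the one piece of pen geometry the pipeline needs.  It can
be built from planar antenna center coordinates or supplied directly (barns
are usually surveyed with a tape measure, not a CAD model).

A valid matrix must be a metric: symmetric, zero on the diagonal,
nonnegative, and satisfying the triangle inequality.  The triangle
inequality is what guarantees that dropping detections can only shorten the
computed path, so it is checked exhaustively rather than assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: slack absorbing float roundoff in metric checks, in meters
TRIANGLE_TOL = 1e-9


@dataclass(frozen=True)
class DistanceMatrix:
    """Pairwise center-to-center distances between pen locations, in meters.

    Parameters
    ----------
    locations
        Location identifiers, in index order.
    values
        Square array of distances; ``values[i, j]`` is the distance between
        ``locations[i]`` and ``locations[j]``.
    """

    locations: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        n = len(self.locations)
        if vals.shape != (n, n):
            raise ValueError(
                f"distance matrix shape {vals.shape} does not match "
                f"{n} locations"
            )
        if len(set(self.locations)) != n:
            raise ValueError("duplicate location ids in distance matrix")
        object.__setattr__(self, "locations", tuple(self.locations))
        object.__setattr__(self, "values", vals)

    def distance(self, a: str, b: str) -> float:
        """Distance in meters between locations *a* and *b*."""
        idx = self.index()
        return float(self.values[idx[a], idx[b]])

    def index(self) -> dict[str, int]:
        return {loc: i for i, loc in enumerate(self.locations)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.locations), columns=list(self.locations)
        )

    def reindex(self, locations: Sequence[str]) -> "DistanceMatrix":
        """Return a sub-matrix restricted/reordered to *locations*."""
        idx = self.index()
        missing = [loc for loc in locations if loc not in idx]
        if missing:
            raise KeyError(f"locations not in distance matrix: {missing}")
        sel = np.array([idx[loc] for loc in locations])
        return DistanceMatrix(tuple(locations), self.values[np.ix_(sel, sel)])


@dataclass
class ValidationReport:
    """Result of checking a distance matrix against the metric axioms.

    ``violations`` holds one human-readable entry per failed check; an empty
    list means the matrix is a metric (within :data:`TRIANGLE_TOL`).
    """

    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:  # truthy iff valid
        return self.ok


def distance_matrix_from_coords(
    coords: Mapping[str, tuple[float, float]],
) -> DistanceMatrix:
    """Build the pairwise Euclidean distance matrix from 2-D antenna centers.

    Parameters
    ----------
    coords
        Mapping of location id to ``(x, y)`` center coordinates in meters,
        in a common planar pen frame.

    Raises
    ------
    ValueError
        If a coordinate is missing or not a finite 2-vector.
    """
    locations = tuple(coords)
    if len(locations) < 2:
        raise ValueError("need at least two locations to build a matrix")
    pts = np.empty((len(locations), 2), dtype=float)
    for i, loc in enumerate(locations):
        xy = coords[loc]
        if xy is None:
            raise ValueError(f"location {loc!r} has no coordinates")
        xy = np.asarray(xy, dtype=float)
        if xy.shape != (2,) or not np.all(np.isfinite(xy)):
            raise ValueError(f"location {loc!r}: coordinates must be finite (x, y)")
        pts[i] = xy
    diff = pts[:, None, :] - pts[None, :, :]
    vals = np.sqrt((diff**2).sum(axis=-1))
    return DistanceMatrix(locations, vals)


def validate_matrix(m: DistanceMatrix) -> ValidationReport:
    """Check symmetry, zero diagonal, nonnegativity, finiteness and the
    triangle inequality (exhaustively, over all unordered triples).

    Violations are collected and reported, never raised: a survey error in a
    hand-measured matrix should be diagnosable in one pass.
    """
    report = ValidationReport()
    vals = m.values
    locs = m.locations
    n = len(locs)

    bad = np.argwhere(~np.isfinite(vals))
    for i, j in bad:
        report.violations.append(f"non-finite entry d({locs[i]}, {locs[j]})")
    if bad.size:
        return report  # remaining checks are meaningless

    for i, j in np.argwhere(vals < 0):
        report.violations.append(
            f"negative distance d({locs[i]}, {locs[j]}) = {vals[i, j]:g}"
        )
    for (i,) in np.argwhere(np.diag(vals) != 0):
        report.violations.append(
            f"nonzero diagonal d({locs[i]}, {locs[i]}) = {vals[i, i]:g}"
        )
    asym = np.argwhere(vals != vals.T)
    for i, j in asym[asym[:, 0] < asym[:, 1]]:
        report.violations.append(
            f"asymmetry d({locs[i]}, {locs[j]}) = {vals[i, j]:g} != "
            f"d({locs[j]}, {locs[i]}) = {vals[j, i]:g}"
        )

    for i, j, k in combinations(range(n), 3):
        # three inequalities per unordered triple
        for a, b, c in ((i, j, k), (j, k, i), (k, i, j)):
            if vals[a, b] > vals[a, c] + vals[c, b] + TRIANGLE_TOL:
                report.violations.append(
                    f"triangle violation: d({locs[a]}, {locs[b]}) = "
                    f"{vals[a, b]:g} > d({locs[a]}, {locs[c]}) + "
                    f"d({locs[c]}, {locs[b]}) = {vals[a, c] + vals[c, b]:g}"
                )
    return report


def matrix_from_frame(frame: pd.DataFrame) -> DistanceMatrix:
    """Build a :class:`DistanceMatrix` from a labelled square DataFrame."""
    if list(frame.index) != list(frame.columns):
        raise ValueError("distance matrix rows and columns must carry the same ids")
    return DistanceMatrix(tuple(frame.index), frame.to_numpy(dtype=float))
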