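"""Cohort summary layers over the daily and hourly VWD tables.

Fattening periods are binned into four stages (days 1-30, 31-60, 61-90 and
>90).  Stage means come in two variants that answer different questions:

``all_days``
    mean over every observed pig-day in the stage — weights animals by how
    many days they contributed;
``per_pig_means``
    mean of the per-animal stage means — one vote per animal, regardless of
    coverage.

The two coincide exactly on balanced data and diverge toward the
over-represented animals otherwise.  All means are unweighted arithmetic
means over days with at least one reading; a reading-free day is missing
data, not zero activity, and is excluded.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .vwd import HOUR_COLUMNS

logger = logging.getLogger(__name__)

#: stage labels in fattening order
STAGES = ("d1_30", "d31_60", "d61_90", "d_gt90")
#: upper fattening-day bounds of the first three stages (closed bins)
DEFAULT_STAGE_BOUNDARIES = (30, 60, 90)

VARIANTS = ("all_days", "per_pig_means")


def stage_labels(boundaries: tuple[int, ...] = DEFAULT_STAGE_BOUNDARIES) -> list[str]:
    """Human-readable labels for the stage bins defined by *boundaries*."""
    if list(boundaries) != sorted(set(boundaries)) or boundaries[0] < 1:
        raise ValueError("stage boundaries must be strictly increasing positive integers")
    labels = []
    lo = 1
    for b in boundaries:
        labels.append(f"d{lo}_{b}")
        lo = b + 1
    labels.append(f"d_gt{boundaries[-1]}")
    return labels


def assign_stage(
    fattening_day: int | np.ndarray | pd.Series,
    boundaries: tuple[int, ...] = DEFAULT_STAGE_BOUNDARIES,
) -> str | pd.Series:
    """Map fattening day(s) (1-based) to a stage label.

    Boundaries are inclusive upper bounds: with the defaults, day 30 is
    still ``d1_30`` and day 31 opens ``d31_60``; everything past the last
    boundary is ``d_gt90``.
    """
    labels = stage_labels(boundaries)
    scalar = np.isscalar(fattening_day)
    days = pd.Series(np.atleast_1d(fattening_day), dtype=int)
    if (days < 1).any():
        raise ValueError("fattening_day must be >= 1")
    cut = pd.cut(
        days,
        bins=[0, *boundaries, np.inf],
        labels=labels,
        right=True,
    ).astype(pd.CategoricalDtype(labels, ordered=True))
    return cut.iloc[0] if scalar else cut


def stage_means(
    daily: pd.DataFrame,
    variant: str = "all_days",
    boundaries: tuple[int, ...] = DEFAULT_STAGE_BOUNDARIES,
) -> pd.DataFrame:
    """Mean daily VWD per fattening stage.

    Returns one row per stage with columns ``stage``, ``variant``,
    ``mean_vwd_m`` and ``n`` (``n`` counts pig-days for ``all_days`` and
    animals for ``per_pig_means``; stages with no data get n = 0 and a
    missing mean).
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    labels = stage_labels(boundaries)
    df = daily.assign(stage=assign_stage(daily["fattening_day"], boundaries))
    if variant == "all_days":
        g = df.groupby("stage", observed=False)["vwd_m"].agg(["mean", "size"])
        g["size"] = df.groupby("stage", observed=False)["vwd_m"].count()
    else:
        per_pig = (
            df.groupby(["animal_id", "stage"], observed=False)["vwd_m"]
            .mean()
            .reset_index()
        )
        g = per_pig.groupby("stage", observed=False)["vwd_m"].agg(["mean", "count"])
        g.columns = ["mean", "size"]
    out = pd.DataFrame(
        {
            "stage": labels,
            "variant": variant,
            "mean_vwd_m": g["mean"].reindex(labels).to_numpy(),
            "n": g["size"].reindex(labels).fillna(0).astype(int).to_numpy(),
        }
    )
    return out


def pig_summaries(
    daily: pd.DataFrame,
    boundaries: tuple[int, ...] = DEFAULT_STAGE_BOUNDARIES,
) -> pd.DataFrame:
    """Per-animal summary: mean/min/max daily VWD, days observed, and the
    mean within each fattening stage (missing where the animal has no data
    in that stage)."""
    if daily.empty:
        raise ValueError("pig_summaries needs a nonempty daily table")
    labels = stage_labels(boundaries)
    df = daily.assign(stage=assign_stage(daily["fattening_day"], boundaries))
    base = df.groupby("animal_id")["vwd_m"].agg(
        mean_vwd_m="mean", min_vwd_m="min", max_vwd_m="max", days_observed="count"
    )
    per_stage = (
        df.groupby(["animal_id", "stage"], observed=False)["vwd_m"]
        .mean()
        .unstack("stage")
        .reindex(columns=labels)
    )
    per_stage.columns = [f"mean_{s}" for s in labels]
    out = base.join(per_stage).reset_index()
    return out.sort_values("animal_id", kind="mergesort").reset_index(drop=True)


def hourly_profile(
    hourly: pd.DataFrame,
    daily: pd.DataFrame,
    boundaries: tuple[int, ...] = DEFAULT_STAGE_BOUNDARIES,
) -> pd.DataFrame:
    """Mean hour-of-day activity profile, per stage and overall.

    For each stage (and for all pig-days pooled, labelled ``overall``), bin
    h is the mean over pig-days of that day's bin-h distance.  The hourly
    and daily tables must describe exactly the same animal-days.
    """
    merged = hourly.merge(
        daily[["animal_id", "date", "fattening_day"]],
        on=["animal_id", "date"],
        how="outer",
        indicator=True,
    )
    if (merged["_merge"] != "both").any():
        raise ValueError("hourly and daily tables cover different animal-days")
    merged = merged.drop(columns="_merge")
    labels = stage_labels(boundaries)
    merged["stage"] = assign_stage(merged["fattening_day"], boundaries)
    by_stage = merged.groupby("stage", observed=False)[HOUR_COLUMNS].mean()
    overall = merged[HOUR_COLUMNS].mean().to_frame("overall").T
    prof = pd.concat([by_stage.reindex(labels), overall])
    prof.index.name = "stage"
    return prof.reset_index()


def overlay_health(daily: pd.DataFrame, health: pd.DataFrame) -> pd.DataFrame:
    """Annotate per-pig daily VWD series with locomotion scores.

    Left-join on (animal_id, date): days without an observation keep a
    missing score (scores are sparse — animals are typically inspected
    twice a week — and are never imputed between observation days).  Health
    rows that match no observed animal-day are logged and dropped.
    """
    out = daily.merge(
        health[["animal_id", "date", "locomotion_score"]]
        if not health.empty
        else pd.DataFrame(columns=["animal_id", "date", "locomotion_score"]),
        on=["animal_id", "date"],
        how="left",
    )
    out["locomotion_score"] = out["locomotion_score"].astype("Int64")
    if not health.empty:
        matched = health.merge(
            daily[["animal_id", "date"]], on=["animal_id", "date"], how="left",
            indicator=True,
        )
        n_unmatched = int((matched["_merge"] == "left_only").sum())
        if n_unmatched:
            logger.warning(
                "%d health record(s) match no observed animal-day and were "
                "left out of the overlay",
                n_unmatched,
            )
    return out.sort_values(["animal_id", "date"], kind="mergesort").reset_index(drop=True)
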