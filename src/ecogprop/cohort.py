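"""Cohort aggregation and the study-level statistical comparisons.

Takes per-session event tables (one row per event, with animal, group,
week, type, correlation profile and cluster label) and produces

* per recording-day summaries: counts per event type, counts per
  cluster label, percent of seizures propagated, propagated seizures
  per day;
* per-animal propagation: the mean over that animal's sessions of the
  session-level percent propagated (sessions with zero seizures
  contribute nothing, avoiding 0/0);
* per-group means ± SD and the cluster-fraction table;
* percent reductions between group means;
* two-sample Kolmogorov–Smirnov comparison of correlation
  distributions and the χ² test of group × cluster association;
* weekly geometric-median tracks of (r_1mm, r_2mm), excluding any
  recording day with fewer than ten seizures (one 24-h recording per
  week, so day-level and week-level exclusion coincide).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import geometric_median
from .io import CHANNEL_ROLES  # noqa: F401  (re-exported context)


class ZeroMarginError(ValueError):
    """A contingency-table row or column sums to zero."""


def percent_reduction(a: float, b: float) -> float:
    """100 × (a − b) / a: the percent drop from a to b."""
    if a == 0:
        raise ValueError("baseline is zero; reduction undefined")
    return 100.0 * (a - b) / a


def ks_two_sample(sample_a, sample_b) -> tuple[float, float]:
    """Two-sample KS: (D, asymptotic p).

    D is the supremum absolute difference of the empirical CDFs; the
    p-value uses the asymptotic Kolmogorov distribution with the
    standard effective-n correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def chi2_association(table) -> tuple[float, int, float]:
    """Pearson χ² test of association on a counts table.

    Returns (X², degrees of freedom, p).  Expected counts come from the
    row/column margins; a zero margin raises :class:`ZeroMarginError`.
    """
    T = np.asarray(table, dtype=float)
    if T.ndim != 2:
        raise ValueError("table must be 2-D")
    if (T.sum(axis=0) == 0).any() or (T.sum(axis=1) == 0).any():
        raise ZeroMarginError("zero row or column margin")
    chi2, p, dof, _ = stats.chi2_contingency(T, correction=False)
    return float(chi2), int(dof), float(p)


# ---------------------------------------------------------------------------
# summaries


def summarize_cohort(events: pd.DataFrame, session_days: float = 1.0) -> dict:
    """Aggregate an event table into the study's summary tables.

    ``session_days`` is each recording session's length in days (24-h
    sessions → 1.0); per-day rates scale counts by it.  Returns a dict
    with ``daily`` (one row per animal × week), ``per_animal``,
    ``per_group`` and ``cluster_fractions`` DataFrames; all empty when
    the input is empty.
    """
    if len(events) == 0:
        empty = pd.DataFrame()
        return {
            "daily": empty,
            "per_animal": empty,
            "per_group": empty,
            "cluster_fractions": empty,
        }
    required = {"animal_id", "group", "week", "type", "cluster_label"}
    missing = required - set(events.columns)
    if missing:
        raise ValueError(f"event table lacks columns {sorted(missing)}")

    daily_rows = []
    for (animal, group, week), g in events.groupby(
        ["animal_id", "group", "week"], sort=True
    ):
        row: dict = {"animal_id": animal, "group": group, "week": week}
        for etype in ("seizure", "polyspike", "interictal_spike"):
            sub = g[g["type"] == etype]
            row[f"n_{etype}"] = len(sub)
            for lab in ("propagated", "attenuated", "nonpropagated"):
                row[f"n_{etype}_{lab}"] = int((sub["cluster_label"] == lab).sum())
        n_seiz = row["n_seizure"]
        n_prop = row["n_seizure_propagated"]
        row["percent_propagated"] = 100.0 * n_prop / n_seiz if n_seiz else np.nan
        row["seizures_per_day"] = n_seiz / session_days
        row["propagated_per_day"] = n_prop / session_days
        daily_rows.append(row)
    daily = pd.DataFrame(daily_rows)

    # per-animal: mean of *session-level* percent propagated
    per_animal = (
        daily.groupby(["animal_id", "group"])
        .agg(
            percent_propagated=("percent_propagated", "mean"),
            seizures_per_day=("seizures_per_day", "mean"),
            propagated_per_day=("propagated_per_day", "mean"),
            n_sessions=("week", "count"),
        )
        .reset_index()
    )
    per_group = (
        per_animal.groupby("group")
        .agg(
            percent_propagated_mean=("percent_propagated", "mean"),
            percent_propagated_sd=("percent_propagated", "std"),
            seizures_per_day_mean=("seizures_per_day", "mean"),
            seizures_per_day_sd=("seizures_per_day", "std"),
            propagated_per_day_mean=("propagated_per_day", "mean"),
            propagated_per_day_sd=("propagated_per_day", "std"),
            n_animals=("animal_id", "count"),
        )
        .reset_index()
    )

    cf = cluster_fraction_table(events)
    return {
        "daily": daily,
        "per_animal": per_animal,
        "per_group": per_group,
        "cluster_fractions": cf,
    }


def cluster_fraction_table(
    events: pd.DataFrame, event_type: str = "seizure"
) -> pd.DataFrame:
    """Rows = groups, columns = cluster labels, values = % of events."""
    sub = events[events["type"] == event_type]
    if len(sub) == 0:
        return pd.DataFrame()
    counts = (
        sub.groupby(["group", "cluster_label"]).size().unstack(fill_value=0)
    )
    for lab in ("propagated", "attenuated", "nonpropagated"):
        if lab not in counts.columns:
            counts[lab] = 0
    counts = counts[["propagated", "attenuated", "nonpropagated"]]
    frac = 100.0 * counts.div(counts.sum(axis=1), axis=0)
    frac.columns = [f"pct_{c}" for c in frac.columns]
    out = pd.concat([counts, frac], axis=1).reset_index()
    return out


# ---------------------------------------------------------------------------
# weekly centroid tracks


@dataclass
class WeeklyTrackPoint:
    week: int
    median_r1: float
    median_r2: float
    n_seizures: int
    included: bool


def weekly_track(
    profiles: pd.DataFrame, min_seizures: int = 10
) -> list[WeeklyTrackPoint]:
    """Geometric-median (r_1mm, r_2mm) per week for one animal.

    Weeks (one 24-h recording day each) with fewer than ``min_seizures``
    seizures are flagged excluded; output is ordered by week.
    """
    required = {"week", "r_1mm", "r_2mm"}
    missing = required - set(profiles.columns)
    if missing:
        raise ValueError(f"profiles lack columns {sorted(missing)}")
    points = []
    for week, g in profiles.groupby("week", sort=True):
        pts = g[["r_1mm", "r_2mm"]].to_numpy(dtype=float)
        med = geometric_median(pts)
        points.append(
            WeeklyTrackPoint(
                week=int(week),
                median_r1=float(med[0]),
                median_r2=float(med[1]),
                n_seizures=len(pts),
                included=len(pts) >= min_seizures,
            )
        )
    return points


def weekly_track_table(points: list[WeeklyTrackPoint]) -> pd.DataFrame:
    return pd.DataFrame([vars(p) for p in points])
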