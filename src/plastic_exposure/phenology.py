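"""Breeding / non-breeding classification of tracked months from
distance-to-colony statistics, with smoothing to a single season of each
type and reconciliation against published breeding schedules.

A month is non-breeding when the tracked birds were, on average, further
from the colony than the population's across-month mean, or when no pooled
location came within the colony-attendance radius (200 km by default — the
typical geolocator position error, so a bird "at the colony" cannot be
distinguished from one 200 km away).

Labels are strings: "breeding", "non-breeding" or "untracked".
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geo import great_circle_km
from .tracks import ColonyRecord

BREEDING = "breeding"
NON_BREEDING = "non-breeding"
UNTRACKED = "untracked"

ATTENDANCE_RADIUS_KM = 200.0

PHENOLOGY_COLUMNS = [
    "population_id",
    "month",
    "n_locations",
    "mean_colony_distance",
    "min_colony_distance",
    "label",
    "label_source",
]


def monthly_colony_stats(points: pd.DataFrame, colony: ColonyRecord) -> pd.DataFrame:
    """Per-month mean and minimum distance to the colony over all pooled
    locations (all individuals, all years). Returns one row per calendar
    month; untracked months carry NaN distances."""
    out = pd.DataFrame(
        {
            "population_id": colony.population_id,
            "month": np.arange(1, 13),
            "n_locations": 0,
            "mean_colony_distance": np.nan,
            "min_colony_distance": np.nan,
            "label": UNTRACKED,
            "label_source": "",
        }
    )
    if len(points) == 0:
        return out
    dist = great_circle_km(
        points["longitude"].to_numpy(),
        points["latitude"].to_numpy(),
        colony.colony_lon,
        colony.colony_lat,
    )
    month = pd.to_datetime(points["date_time"], utc=True).dt.month.to_numpy()
    for m in range(1, 13):
        sel = month == m
        if sel.any():
            out.loc[m - 1, "n_locations"] = int(sel.sum())
            out.loc[m - 1, "mean_colony_distance"] = float(np.mean(dist[sel]))
            out.loc[m - 1, "min_colony_distance"] = float(np.min(dist[sel]))
    return out


def classify_months(
    stats: pd.DataFrame, attendance_radius: float = ATTENDANCE_RADIUS_KM
) -> pd.DataFrame:
    """Label tracked months by the distance-to-colony rule.

    The grand mean is the unweighted mean of the tracked monthly means. A
    month is non-breeding iff its mean exceeds the grand mean (strictly)
    or its minimum distance is >= the attendance radius; otherwise
    breeding. Untracked months keep the "untracked" label.
    """
    out = stats.copy()
    tracked = out["mean_colony_distance"].notna()
    if not tracked.any():
        return out
    grand_mean = float(out.loc[tracked, "mean_colony_distance"].mean())
    far = out["mean_colony_distance"] > grand_mean
    absent = out["min_colony_distance"] >= attendance_radius
    out.loc[tracked, "label"] = np.where(
        (far | absent)[tracked], NON_BREEDING, BREEDING
    )
    out.loc[tracked, "label_source"] = "distance_rule"
    return out


def _runs(labels: list[str]) -> int:
    """Number of cyclic runs in a label sequence."""
    n = len(labels)
    if n == 0:
        return 0
    changes = sum(labels[i] != labels[(i + 1) % n] for i in range(n))
    return max(changes, 1) if changes else 1


def smooth_labels(labels: pd.Series) -> pd.Series:
    """Enforce a single breeding and a single non-breeding season.

    Operates on the cyclic calendar (December adjoins January), skipping
    untracked months. Two stages:

    1. Isolated-month flips: any tracked month whose two tracked cyclic
       neighbours share the opposite label is re-classified, sweeping in
       calendar order with in-place updates until a fixed point (each flip
       merges runs, so this terminates).
    2. If more than one run of either label remains, replace the labelling
       with the cyclic two-arc labelling (one contiguous arc per label)
       that disagrees with the stage-1 labels in the fewest months; ties
       go to the arc placement encountered first scanning from January.

    Stage 2 is a no-op whenever stage 1 already yields one season of each
    type, which is the usual case for central-place foragers.
    """
    labels = labels.copy()
    months = [m for m in labels.index if labels[m] != UNTRACKED]
    vals = [labels[m] for m in months]
    n = len(vals)
    if n <= 2 and len(set(vals)) <= 1:
        return labels
    # stage 1: flip isolated months to fixed point
    changed = True
    guard = 0
    while changed and guard < 24:
        changed = False
        guard += 1
        for i in range(n):
            prev_v = vals[(i - 1) % n]
            next_v = vals[(i + 1) % n]
            if prev_v == next_v and vals[i] != prev_v:
                vals[i] = prev_v
                changed = True
    # stage 2: collapse to one arc per label if needed
    if len(set(vals)) == 2 and _runs(vals) > 2:
        best = None
        for start in range(n):
            for length in range(1, n):
                cand = [NON_BREEDING] * n
                for k in range(length):
                    cand[(start + k) % n] = BREEDING
                cost = sum(c != v for c, v in zip(cand, vals))
                if best is None or cost < best[0]:
                    best = (cost, cand)
        vals = best[1]
    for m, v in zip(months, vals):
        labels[m] = v
    return labels


def reconcile_with_published(
    published: pd.Series,
    inferred: pd.Series,
    min_distance: pd.Series,
    attendance_radius: float = ATTENDANCE_RADIUS_KM,
) -> pd.DataFrame:
    """Merge a published breeding schedule with the distance-rule labels.

    Published labels win, except that a published breeding month in which
    no tracked bird came within the attendance radius is overridden to the
    distance-rule label (the tracked birds demonstrably did not attend the
    colony). Months missing from the published schedule take the inferred
    label. Returns a frame with final ``label`` and ``label_source``.
    """
    if published.index.has_duplicates:
        raise ValueError("published schedule has duplicate month entries")
    months = inferred.index
    final = []
    source = []
    for m in months:
        pub = published.get(m, None)
        if pub is None or (isinstance(pub, float) and np.isnan(pub)) or pub == "":
            final.append(inferred[m])
            source.append("distance_rule")
        elif (
            pub == BREEDING
            and not np.isnan(min_distance.get(m, np.nan))
            and min_distance[m] >= attendance_radius
        ):
            final.append(NON_BREEDING)
            source.append("reconciled")
        else:
            final.append(pub if inferred[m] != UNTRACKED else inferred[m])
            source.append("published" if inferred[m] != UNTRACKED else "")
    return pd.DataFrame({"label": final, "label_source": source}, index=months)


def population_phenology(
    points: pd.DataFrame,
    colony: ColonyRecord,
    published: pd.Series | None = None,
    attendance_radius: float = ATTENDANCE_RADIUS_KM,
) -> pd.DataFrame:
    """Full phenology pipeline for one population: stats -> classify ->
    smooth -> (optionally) reconcile with a published schedule."""
    stats = monthly_colony_stats(points, colony)
    stats = classify_months(stats, attendance_radius)
    labels = pd.Series(stats["label"].to_numpy(), index=stats["month"].to_numpy())
    labels = smooth_labels(labels)
    stats["label"] = labels.to_numpy()
    if published is not None:
        min_dist = pd.Series(
            stats["min_colony_distance"].to_numpy(), index=stats["month"].to_numpy()
        )
        merged = reconcile_with_published(published, labels, min_dist, attendance_radius)
        stats["label"] = merged["label"].to_numpy()
        tracked = stats["label"] != UNTRACKED
        stats.loc[tracked, "label_source"] = merged["label_source"].to_numpy()[
            tracked.to_numpy()
        ]
    return stats


def read_schedules_csv(path) -> dict[str, pd.Series]:
    """Published schedules keyed by population (or species) id: CSV with
    columns id, month, label."""
    df = pd.read_csv(path)
    out = {}
    for key, sub in df.groupby("id"):
        out[str(key)] = pd.Series(
            sub["label"].to_numpy(), index=sub["month"].to_numpy(dtype=int)
        )
    return out
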