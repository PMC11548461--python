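"""Thematic summaries of decoded, annotated fixes.

Three products: activity budgets (per-state fix proportions within arbitrary
key combinations such as hour x season x herd type), daily movement metrics
(distance and time per state per animal-day), and transhumance phase
segmentation (departure/return dates, multi-day stops and duration
clusters) from daily track centroids.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point

from .geo import LocalProjection

BUDGET_KEYS = ("hour", "season", "herd_type", "diel", "unit")


def activity_budget(fixes: pd.DataFrame, keys=("hour",),
                    state_col: str = "state") -> pd.DataFrame:
    """Per-state proportions of fixes within every key combination.

    Returns one row per key combination with ``n_<state>`` counts,
    ``p_<state>`` proportions and a ``total``; proportions in a row sum to 1.
    Empty combinations simply do not appear (counts are retained so callers
    can verify conservation: totals sum to len(fixes)).
    """
    bad = [k for k in keys if k not in fixes.columns and k != "hour"]
    if bad:
        raise ValueError(f"missing budget keys: {bad}")
    df = fixes.copy()
    if "hour" in keys and "hour" not in df.columns:
        df["hour"] = pd.DatetimeIndex(df["timestamp"]).hour
    states = sorted(df[state_col].unique())
    counts = (
        df.groupby(list(keys), observed=True)[state_col]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=states, fill_value=0)
    )
    total = counts.sum(axis=1)
    out = counts.add_prefix("n_")
    for s in states:
        out[f"p_{s}"] = counts[s] / total
    out["total"] = total
    return out.reset_index()


def daily_metrics(fixes: pd.DataFrame, daytime_only: bool = True,
                  interval_h: float = 0.5, state_col: str = "state",
                  step_col: str = "step_m") -> pd.DataFrame:
    """Distance (m) and time (h) per state per animal-day.

    Time per state is ``interval_h`` x the fix count in that state; distance
    per state sums the step lengths whose originating fix is in that state.
    Days missing fixes are kept and flagged ``partial``.
    """
    df = fixes.copy()
    df["date"] = pd.DatetimeIndex(df["timestamp"]).date
    if daytime_only and "diel" in df.columns:
        df = df[df["diel"] == "day"]
    expected = int(round(24 / interval_h))
    rows = []
    for (animal, date), grp in df.groupby(["animal_id", "date"]):
        rec: dict = {"animal_id": animal, "date": date,
                     "herd_type": grp["herd_type"].iloc[0]
                     if "herd_type" in grp.columns else ""}
        for state, sub in grp.groupby(state_col):
            rec[f"t_{state}_h"] = interval_h * len(sub)
            rec[f"d_{state}_m"] = float(sub[step_col].fillna(0.0).sum())
        rec["n_fixes"] = len(grp)
        rec["partial"] = len(grp) < (expected if not daytime_only else 1)
        rows.append(rec)
    out = pd.DataFrame(rows).fillna(0.0)
    return out


def mean_daily_metrics(metrics: pd.DataFrame) -> pd.DataFrame:
    """Average the per-day metrics by herd type (the field study's Table-style
    summary of daily distance and time per state)."""
    value_cols = [c for c in metrics.columns if c.startswith(("t_", "d_"))]
    return metrics.groupby("herd_type")[value_cols].mean().reset_index()


@dataclass
class Stop:
    centroid_lat: float
    centroid_lon: float
    start: dt.date
    end: dt.date  # inclusive

    @property
    def duration_days(self) -> int:
        return (self.end - self.start).days + 1


@dataclass
class PhaseRecord:
    """Transhumance chronology for one herd."""

    herd_id: str
    departure: dt.date | None
    return_date: dt.date | None
    stops: list[Stop] = field(default_factory=list)
    phases: list[tuple[str, dt.date, dt.date]] = field(default_factory=list)
    cluster_means: list[float] = field(default_factory=list)
    cluster_labels: list[int] = field(default_factory=list)


@dataclass
class StopParams:
    stop_radius_km: float = 2.0
    min_stop_days: int = 3
    persistence_days: int = 2
    n_clusters: int = 3
    seed: int = 0


def cluster_durations(durations, n_clusters: int, seed: int = 0):
    """Seeded 1-D k-means over stop durations: (means, labels).

    Uses best-of-50 restarts, so small instances reach the global optimum.
    """
    from sklearn.cluster import KMeans

    durations = np.asarray(durations, dtype=float).reshape(-1, 1)
    k = min(n_clusters, len(durations))
    if k == 0:
        return [], []
    km = KMeans(n_clusters=k, n_init=50, random_state=seed).fit(durations)
    order = np.argsort(km.cluster_centers_.ravel())
    remap = np.empty_like(order)
    remap[order] = np.arange(k)
    means = sorted(float(c) for c in km.cluster_centers_.ravel())
    return means, [int(remap[l]) for l in km.labels_]


def daily_centroids(track: pd.DataFrame) -> pd.DataFrame:
    """Mean daily position, computed on a local planar frame."""
    proj = LocalProjection(float(track["lat"].mean()), float(track["lon"].mean()))
    x, y = proj.forward(track["lat"].to_numpy(), track["lon"].to_numpy())
    df = pd.DataFrame({"date": pd.DatetimeIndex(track["timestamp"]).date,
                       "x": x, "y": y})
    cent = df.groupby("date", sort=True)[["x", "y"]].mean().reset_index()
    lat, lon = proj.inverse(cent["x"].to_numpy(), cent["y"].to_numpy())
    cent["lat"], cent["lon"] = lat, lon
    return cent


def detect_stops_and_phases(track: pd.DataFrame, home_area,
                            params: StopParams | None = None,
                            herd_id: str = "") -> PhaseRecord:
    """Segment one herd's track into home / journey phases and stops.

    Departure is the first day of a run of at least ``persistence_days``
    whose daily centroid lies outside ``home_area``; stops are maximal runs
    of at least ``min_stop_days`` whose centroids stay within
    ``stop_radius_km`` of the running stop centroid; the return date is the
    first day back inside the home area after the furthest stop.  Stop
    durations are clustered by seeded 1-D k-means.  A herd that never leaves
    the home area yields a record with no departure (a resident herd).
    """
    params = params or StopParams()
    cent = daily_centroids(track)
    if cent.empty:
        return PhaseRecord(herd_id=herd_id, departure=None, return_date=None)
    inside = np.array([home_area.covers(Point(lo, la))
                       for la, lo in zip(cent["lat"], cent["lon"])])
    dates = list(cent["date"])

    departure = None
    for i in range(len(dates)):
        win = inside[i:i + params.persistence_days]
        if len(win) == params.persistence_days and not win.any():
            departure = dates[i]
            dep_idx = i
            break
    if departure is None:
        return PhaseRecord(herd_id=herd_id, departure=None, return_date=None,
                           phases=[("home", dates[0], dates[-1])])

    # stops: greedy runs of days within stop_radius of the running centroid
    proj = LocalProjection(float(cent["lat"].iloc[0]), float(cent["lon"].iloc[0]))
    xs, ys = proj.forward(cent["lat"].to_numpy(), cent["lon"].to_numpy())
    radius_m = params.stop_radius_km * 1000.0
    stops: list[Stop] = []
    i = dep_idx
    while i < len(dates):
        cx, cy, count = xs[i], ys[i], 1
        j = i + 1
        while j < len(dates):
            if np.hypot(xs[j] - cx * 1.0, ys[j] - cy * 1.0) <= radius_m:
                cx = (cx * count + xs[j]) / (count + 1)
                cy = (cy * count + ys[j]) / (count + 1)
                count += 1
                j += 1
            else:
                break
        if count >= params.min_stop_days and not inside[i:j].any():
            lat_c, lon_c = proj.inverse(np.array([cx]), np.array([cy]))
            stops.append(Stop(float(lat_c[0]), float(lon_c[0]),
                              dates[i], dates[j - 1]))
        i = j if j > i + 1 else i + 1

    # return: first day back inside home after the furthest stop
    return_date = None
    if stops:
        home_x, home_y = proj.forward(
            np.array([cent["lat"].iloc[0]]), np.array([cent["lon"].iloc[0]])
        )
        far_stop = max(
            stops,
            key=lambda s: np.hypot(*np.subtract(
                proj.forward(np.array([s.centroid_lat]), np.array([s.centroid_lon])),
                (home_x, home_y),
            )).item(),
        )
        far_end_idx = dates.index(far_stop.end)
        for k in range(far_end_idx, len(dates)):
            if inside[k]:
                return_date = dates[k]
                break

    means, labels = cluster_durations(
        [s.duration_days for s in stops], params.n_clusters, params.seed
    )

    phases: list[tuple[str, dt.date, dt.date]] = []
    if dep_idx > 0:
        phases.append(("home", dates[0], dates[dep_idx - 1]))
    if stops:
        far = max(range(len(stops)), key=lambda k: stops[k].duration_days)
        agro = 0
        for k, s in enumerate(stops):
            if s is far_stop:
                name = "pastoral"
            else:
                agro += 1
                name = f"agropastoral-{agro}"
            phases.append((name, s.start, s.end))
    if return_date is not None:
        phases.append(("home", return_date, dates[-1]))

    return PhaseRecord(
        herd_id=herd_id,
        departure=departure,
        return_date=return_date,
        stops=stops,
        phases=phases,
        cluster_means=means,
        cluster_labels=labels,
    )
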