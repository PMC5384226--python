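"""Time-course metabolomics preparation.

Three steps precede model integration:

1. :func:`impute_missing` — k-nearest-neighbour imputation of missing
   concentrations (distance-weighted over co-observed time points, k = 5 by
   default), the standard treatment for metabolomics missingness.
2. :func:`discretize_states` — split the time axis into contiguous windows
   within which concentration trajectories are approximately linear
   ("metabolic states").  Metabolite profiles are Z-scored, projected onto
   the first principal component over time points, and the PC1 score series
   is segmented by exhaustive least-squares change-point search; the number
   of segments is chosen by a scree-style elbow rule unless pinned by the
   caller.
3. :func:`estimate_rates` — per-metabolite ordinary-least-squares slope of
   concentration against time within a window, with a two-sided 95%
   t-interval [b1, b2].  A metabolite whose interval crosses zero is deemed
   to be at steady state (not significant).

All internal rates are per hour; ingest converts day-resolved data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.impute import KNNImputer

from ufba.errors import DataError

REQUIRED_COLUMNS = ("metabolite_id", "compartment", "time", "replicate", "concentration")

#: Hours per supported time unit at ingest.
_TIME_UNIT_HOURS = {"h": 1.0, "hour": 1.0, "hours": 1.0, "day": 24.0, "days": 24.0, "d": 24.0}


@dataclass
class TimeCourseDataset:
    """Replicate concentration measurements over time.

    ``data`` holds one row per (metabolite, time, replicate) with columns
    ``metabolite_id, compartment, time, replicate, concentration``; a
    missing measurement is a NaN concentration.  ``units`` declares the
    concentration unit (e.g. ``mmol/L`` or ``mmol/gDW``); times are hours.
    ``id_map`` optionally maps assay metabolite ids onto model ids.
    """

    data: pd.DataFrame
    units: str = "mmol/L"
    id_map: dict = field(default_factory=dict)

    def __post_init__(self):
        df = self.data
        missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing_cols:
            raise DataError(f"time-course table lacks columns {missing_cols}")
        df = df.copy()
        df["time"] = df["time"].astype(float)
        df["concentration"] = df["concentration"].astype(float)
        if (df["time"] < 0).any():
            raise DataError("negative time values")
        if df["time"].nunique() < 2:
            raise DataError("need at least 2 distinct time points")
        keys = df[["metabolite_id", "time", "replicate"]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0].tolist()
            raise DataError(f"duplicate (metabolite, time, replicate) key: {dup}")
        observed = df["concentration"].dropna()
        if not np.isfinite(observed).all():
            raise DataError("non-finite concentration values")
        self.data = df.reset_index(drop=True)

    @property
    def times(self) -> np.ndarray:
        return np.sort(self.data["time"].unique())

    @property
    def metabolites(self) -> list[str]:
        return sorted(self.data["metabolite_id"].unique())

    def model_id(self, metabolite_id: str) -> str:
        return self.id_map.get(metabolite_id, metabolite_id)

    def wide(self) -> pd.DataFrame:
        """Metabolite × (time, replicate) concentration matrix."""
        return self.data.pivot_table(
            index="metabolite_id",
            columns=["time", "replicate"],
            values="concentration",
            dropna=False,
        )

    def profile(self) -> pd.DataFrame:
        """Replicate-averaged metabolite × time matrix (NaN-aware mean)."""
        return self.data.pivot_table(
            index="metabolite_id", columns="time", values="concentration"
        )

    @classmethod
    def from_csv(cls, path, units: str = "mmol/L", time_unit: str = "h",
                 id_map: dict | None = None) -> "TimeCourseDataset":
        """Load a CSV with the documented columns, converting times to hours."""
        path = Path(path)
        try:
            df = pd.read_csv(path)
        except Exception as exc:
            raise DataError(f"failed to read time-course CSV {path}: {exc}") from exc
        missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing_cols:
            raise DataError(f"{path}: missing columns {missing_cols}")
        if "missing" in df.columns:
            flagged = df["missing"].astype(bool)
            df.loc[flagged, "concentration"] = np.nan
            df = df.drop(columns=["missing"])
        try:
            factor = _TIME_UNIT_HOURS[time_unit.lower()]
        except KeyError:
            raise DataError(f"unknown time unit {time_unit!r}")
        df["time"] = df["time"].astype(float) * factor
        return cls(data=df, units=units, id_map=dict(id_map or {}))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


@dataclass(frozen=True)
class MetabolicStateWindow:
    """A contiguous block of time points within which trajectories are
    treated as linear.  1-based ``index``; ``times`` are the member time
    points (hours)."""

    index: int
    t_start: float
    t_end: float
    times: tuple

    def __post_init__(self):
        if len(self.times) < 3:
            raise DataError("a metabolic-state window needs >= 3 time points")


@dataclass(frozen=True)
class RateEstimate:
    """OLS slope of one metabolite's concentration vs time in one state,
    with the two-sided 95% confidence interval [b1, b2].  ``significant``
    is True iff the interval does not cross zero."""

    metabolite_id: str
    state_index: int
    slope: float
    b1: float
    b2: float
    significant: bool
    compartment: str | None = None

    def __post_init__(self):
        if not (self.b1 - 1e-12 <= self.slope <= self.b2 + 1e-12):
            raise DataError(
                f"{self.metabolite_id}: slope {self.slope} outside CI "
                f"[{self.b1}, {self.b2}]"
            )


def apply_pool_splits(data: TimeCourseDataset, splits: dict) -> TimeCourseDataset:
    """Split assay-unresolved metabolite pools into individual metabolites.

    ``splits`` maps a pooled id to ``{individual_id: ratio}``; ratios must
    sum to 1.  Each pooled measurement row is replaced by one row per
    individual metabolite carrying ``ratio * concentration``.
    """
    df = data.data
    frames = [df[~df["metabolite_id"].isin(splits)]]
    for pool_id, ratios in splits.items():
        total = sum(ratios.values())
        if abs(total - 1.0) > 1e-9:
            raise DataError(f"split ratios for {pool_id!r} sum to {total}, not 1")
        pool_rows = df[df["metabolite_id"] == pool_id]
        if pool_rows.empty:
            continue
        for met_id, ratio in ratios.items():
            rows = pool_rows.copy()
            rows["metabolite_id"] = met_id
            rows["concentration"] = rows["concentration"] * ratio
            frames.append(rows)
    return replace(data, data=pd.concat(frames, ignore_index=True))


def impute_missing(data: TimeCourseDataset, k: int = 5) -> TimeCourseDataset:
    """Fill missing concentrations by distance-weighted k-nearest-neighbour
    imputation over metabolite profiles.

    Nearness between two metabolites is the Euclidean distance over their
    co-observed (time, replicate) coordinates; each hole is filled with the
    1/distance-weighted average of the k nearest metabolites observed at
    that coordinate.  Non-missing entries are never touched.

    Raises :class:`DataError` if ``k < 1`` or some metabolite has no
    observed value at all (nothing to impute from).
    """
    if k < 1:
        raise DataError("k must be >= 1")
    wide = data.wide()
    all_missing = wide.index[wide.isna().all(axis=1)]
    if len(all_missing):
        raise DataError(
            f"metabolite(s) with zero non-missing entries: {list(all_missing)}"
        )
    if not wide.isna().any().any():
        return data
    n_neighbors = min(k, max(1, wide.shape[0] - 1))
    imputer = KNNImputer(n_neighbors=n_neighbors, weights="distance")
    filled = pd.DataFrame(
        imputer.fit_transform(wide.values), index=wide.index, columns=wide.columns
    )
    long = filled.stack(["time", "replicate"], future_stack=True).rename("imputed").reset_index()
    df = data.data.merge(long, on=["metabolite_id", "time", "replicate"], how="left")
    df["concentration"] = df["concentration"].fillna(df["imputed"])
    df = df.drop(columns=["imputed"])
    return replace(data, data=df)


def _segment_cost(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """cost[i, j] = SSE of a straight-line fit to points i..j inclusive."""
    n = len(t)
    cost = np.full((n, n), np.inf)
    for i in range(n):
        for j in range(i + 1, n):
            tt, yy = t[i : j + 1], y[i : j + 1]
            tm, ym = tt.mean(), yy.mean()
            sxx = np.sum((tt - tm) ** 2)
            sxy = np.sum((tt - tm) * (yy - ym))
            syy = np.sum((yy - ym) ** 2)
            cost[i, j] = syy - (sxy**2 / sxx if sxx > 0 else 0.0)
    return cost


def _best_partition(cost: np.ndarray, n_segments: int, min_pts: int):
    """Dynamic program: minimal total SSE partition of 0..n-1 into
    ``n_segments`` contiguous segments of >= min_pts points each.
    Returns (sse, breakpoints) where breakpoints are segment start indices."""
    n = cost.shape[0]
    # dp[s][j] = best SSE covering points 0..j with s segments
    dp = np.full((n_segments + 1, n), np.inf)
    back = np.zeros((n_segments + 1, n), dtype=int)
    for j in range(min_pts - 1, n):
        dp[1, j] = cost[0, j]
    for s in range(2, n_segments + 1):
        for j in range(s * min_pts - 1, n):
            # segment s covers i..j
            for i in range((s - 1) * min_pts, j - min_pts + 2):
                val = dp[s - 1, i - 1] + cost[i, j]
                if val < dp[s, j]:
                    dp[s, j] = val
                    back[s, j] = i
    if not np.isfinite(dp[n_segments, n - 1]):
        raise DataError(
            f"cannot split {n} time points into {n_segments} windows of >= {min_pts} points"
        )
    starts = []
    j = n - 1
    for s in range(n_segments, 0, -1):
        i = back[s, j] if s > 1 else 0
        starts.append(i)
        j = i - 1
    return float(dp[n_segments, n - 1]), sorted(starts)


def discretize_states(
    data: TimeCourseDataset,
    n_states: int | None = None,
    min_points: int = 3,
    max_states: int = 5,
) -> list[MetabolicStateWindow]:
    """Partition the time axis into linearized metabolic-state windows.

    Replicate-averaged profiles are Z-scored per metabolite (zero-variance
    metabolites are dropped from the PCA but kept for regression), the time
    points are projected onto the first principal component, and the PC1
    score series is segmented by an exhaustive least-squares change-point
    search.  With ``n_states`` given, exactly that many windows are
    returned; otherwise the segment count is chosen by a scree-style elbow
    rule over 1..``max_states``.

    The returned windows partition the measured time points, are ordered,
    non-overlapping, and each holds at least ``min_points`` time points.
    The procedure is invariant under uniform time translation.
    """
    profile = data.profile()
    times = profile.columns.to_numpy(dtype=float)
    order = np.argsort(times)
    times = times[order]
    n = len(times)
    if n < 3:
        raise DataError("need at least 3 time points to discretize states")
    if n_states is not None and n < min_points * n_states:
        raise DataError(
            f"{n} time points cannot support {n_states} states of >= {min_points} points"
        )
    values = profile.to_numpy()[:, order]
    if np.isnan(values).any():
        raise DataError("impute missing values before discretizing states")
    sd = values.std(axis=1, ddof=0)
    keep = sd > 0
    if not keep.any():
        # every profile flat: one window
        scores = np.zeros(n)
    else:
        z = (values[keep] - values[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
        scores = PCA(n_components=1).fit_transform(z.T).ravel()
    cost = _segment_cost(times, scores)

    if n_states is not None:
        _, starts = _best_partition(cost, n_states, min_points)
    else:
        # scree-style elbow: an extra segment is accepted only if it both
        # halves the remaining SSE and explains >= 10% of the total PC1
        # variance.  A genuine slope change removes nearly all of the
        # single-line SSE (itself of the order of the total variance);
        # residual noise removes a vanishing fraction.
        kmax = min(max_states, n // min_points)
        starts = [0]
        sst = float(np.sum((scores - scores.mean()) ** 2))
        prev_sse = cost[0, n - 1]
        for kk in range(2, kmax + 1):
            if prev_sse <= 1e-12:
                break
            try:
                sse, cand = _best_partition(cost, kk, min_points)
            except DataError:
                break
            if sse > 0.5 * prev_sse or (prev_sse - sse) < 0.1 * sst:
                break
            starts, prev_sse = cand, sse
    bounds = starts + [n]
    windows = []
    for w, (a, b) in enumerate(zip(bounds[:-1], bounds[1:]), start=1):
        member = tuple(times[a:b])
        windows.append(
            MetabolicStateWindow(index=w, t_start=member[0], t_end=member[-1], times=member)
        )
    return windows


def estimate_rates(
    data: TimeCourseDataset,
    window: MetabolicStateWindow,
    alpha: float = 0.05,
) -> list[RateEstimate]:
    """Per-metabolite OLS rate of change within one state window.

    All replicate measurements inside the window are pooled as independent
    observations.  The two-sided (1 − alpha) confidence interval uses the
    t distribution with n − 2 degrees of freedom; a perfect fit yields a
    zero-width interval.  A metabolite is significant iff the interval does
    not contain zero.  Rates carry the dataset's concentration unit per
    hour.
    """
    if not 0 < alpha < 1:
        raise DataError("alpha must be in (0, 1)")
    member = set(window.times)
    sub = data.data[data.data["time"].isin(member)]
    out: list[RateEstimate] = []
    for met_id, grp in sub.groupby("metabolite_id", sort=True):
        grp = grp.dropna(subset=["concentration"])
        t = grp["time"].to_numpy(dtype=float)
        y = grp["concentration"].to_numpy(dtype=float)
        if len(t) < 3:
            raise DataError(f"{met_id}: fewer than 3 observations in window {window.index}")
        tm = t.mean()
        sxx = np.sum((t - tm) ** 2)
        if sxx <= 0:
            raise DataError(f"{met_id}: zero time-variance in window {window.index}")
        slope = np.sum((t - tm) * (y - y.mean())) / sxx
        intercept = y.mean() - slope * tm
        resid = y - (intercept + slope * t)
        dof = len(t) - 2
        sse = float(np.sum(resid**2))
        se = np.sqrt(sse / dof / sxx) if dof > 0 else 0.0
        if se > 0:
            half = stats.t.ppf(1 - alpha / 2, dof) * se
        else:
            half = 0.0
        b1, b2 = slope - half, slope + half
        compartment = grp["compartment"].iloc[0] if "compartment" in grp else None
        out.append(
            RateEstimate(
                metabolite_id=met_id,
                state_index=window.index,
                slope=float(slope),
                b1=float(b1),
                b2=float(b2),
                significant=not (b1 <= 0.0 <= b2),
                compartment=compartment,
            )
        )
    return out
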