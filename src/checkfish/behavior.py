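"""Trajectory analysis: locomotion, zone-visit detection and A-F ranking.

A trajectory is the time-stamped head position of one animal in one
session.  The analyses here turn trajectories into

* path lengths (locomotor sensitization curves),
* zone-visit events (a visit is an entry followed by a confirmed dwell,
  so that "merely passing by" does not count),
* per-animal A-F zone rankings over days 1-10, which align idiosyncratic
  spatial patterns so animals with different preferred locations can be
  pooled,
* standardized visit rates that make the 50-min daily sessions comparable
  with the two 5-min probe sessions (A1/A2) on day 11.

Visit rule (deterministic operationalization of "entered and interacted"):
an event opens at an outside-to-inside transition of the head point, is
confirmed when the span of inside samples reaches ``min_dwell`` seconds,
and closes when the head moves beyond radius + ``hysteresis``.  The
hysteresis band prevents boundary flicker from splitting one interaction
into several events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .arena import ZONE_ORDER, ArenaSpec, Zone, build_zones

__all__ = [
    "Trajectory",
    "VisitEvent",
    "VisitDetector",
    "path_length",
    "detect_visits",
    "count_visits",
    "rank_zones",
    "pooled_zone_matrix",
    "standardize_sessions",
    "sensitization_summary",
    "zone_dominance",
]

GROUPS = ("QNP", "control")
SESSIONS = ("daily", "A1", "A2")


class TrajectoryError(ValueError):
    """Raised for malformed trajectories (non-monotone time, out of arena)."""


@dataclass
class Trajectory:
    """Head positions of one animal in one session.

    ``t`` is strictly increasing (seconds); ``x``/``y`` are cm within
    ``[0, side]``; at least two samples are required.
    """

    animal_id: str
    group: str
    day: int
    session: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    arena: ArenaSpec = field(default_factory=ArenaSpec)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise TrajectoryError("t, x, y must have equal length")
        if len(self.t) < 2:
            raise TrajectoryError("a trajectory needs at least 2 samples")
        if not np.all(np.diff(self.t) > 0):
            bad = int(np.argmax(np.diff(self.t) <= 0)) + 1
            raise TrajectoryError(f"time not strictly increasing at sample {bad}")
        s = self.arena.side
        if np.any((self.x < 0) | (self.x > s) | (self.y < 0) | (self.y > s)):
            bad = int(np.argmax((self.x < 0) | (self.x > s) | (self.y < 0) | (self.y > s)))
            raise TrajectoryError(
                f"sample {bad} at ({self.x[bad]:.2f}, {self.y[bad]:.2f}) lies outside the arena"
            )
        if self.group not in GROUPS:
            raise TrajectoryError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.session not in SESSIONS:
            raise TrajectoryError(f"session must be one of {SESSIONS}, got {self.session!r}")

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class VisitEvent:
    zone_id: str
    t_enter: float
    t_exit: float

    @property
    def duration(self) -> float:
        return self.t_exit - self.t_enter


def path_length(traj: Trajectory) -> float:
    """Total path length in cm: the sum of Euclidean step lengths."""
    return float(np.hypot(np.diff(traj.x), np.diff(traj.y)).sum())


class VisitDetector(BaseEstimator, TransformerMixin):
    """Stateless transformer turning trajectories into zone-visit events.

    Parameters
    ----------
    min_dwell : float
        Minimum span (s) of inside samples for an entry to count as a
        visit rather than a pass-through.  Default 0.5 s.
    hysteresis : float
        Extra radial margin (cm) the head must exceed before the visit
        closes.  Default 2 cm.
    """

    def __init__(self, min_dwell: float = 0.5, hysteresis: float = 2.0):
        self.min_dwell = min_dwell
        self.hysteresis = hysteresis

    def fit(self, X=None, y=None) -> "VisitDetector":
        if self.min_dwell < 0 or self.hysteresis < 0:
            raise ValueError("min_dwell and hysteresis must be non-negative")
        return self

    def transform(self, traj: Trajectory, zones: Optional[Sequence[Zone]] = None) -> List[VisitEvent]:
        return self.detect(traj, zones)

    def detect(self, traj: Trajectory, zones: Optional[Sequence[Zone]] = None) -> List[VisitEvent]:
        """Run the entry/dwell/exit state machine over one trajectory.

        Zones are disjoint by construction, so at most one zone can
        contain the head at a time and events never overlap.
        """
        self.fit()
        if zones is None:
            zones = build_zones(traj.arena)
        t = traj.t
        n = len(t)
        # n_samples x n_zones distance matrix; zones are few so this is cheap.
        dist = np.stack([z.distance(traj.x, traj.y) for z in zones], axis=1)
        radius = np.array([z.radius for z in zones])
        inside = dist <= radius
        beyond = dist > radius + self.hysteresis

        # Frame index of the (single) zone containing each sample, else -1.
        zone_at = np.where(inside.any(axis=1), inside.argmax(axis=1), -1)

        events: List[VisitEvent] = []
        i = 0
        while i < n:
            zi = zone_at[i]
            if zi < 0:
                i += 1
                continue
            # Event opened at sample i; find the close (first sample beyond
            # radius + hysteresis) and the last inside sample before it.
            later = beyond[i + 1 :, zi]
            off = int(np.argmax(later)) if later.any() else len(later)
            j = i + 1 + off  # exit sample index, == n if never closed
            in_evt = inside[i:j, zi]
            last_inside = i + int(np.flatnonzero(in_evt)[-1])
            inside_span = t[last_inside] - t[i]
            if inside_span >= self.min_dwell:
                t_exit = t[j] if j < n else t[n - 1]
                events.append(VisitEvent(zones[zi].zone_id, float(t[i]), float(t_exit)))
            i = j
        return events


def detect_visits(
    traj: Trajectory,
    zones: Optional[Sequence[Zone]] = None,
    min_dwell: float = 0.5,
    hysteresis: float = 2.0,
) -> List[VisitEvent]:
    """Functional wrapper over :class:`VisitDetector`."""
    return VisitDetector(min_dwell=min_dwell, hysteresis=hysteresis).detect(traj, zones)


def count_visits(
    trajectories: Iterable[Trajectory],
    min_dwell: float = 0.5,
    hysteresis: float = 2.0,
) -> pd.DataFrame:
    """Zone-visit table: one row per (animal, day, session, zone).

    Every zone appears for every analysed session, with zero counts where
    no visit occurred, so downstream ranking never misses a zone.
    """
    detector = VisitDetector(min_dwell=min_dwell, hysteresis=hysteresis)
    rows = []
    for traj in trajectories:
        zones = build_zones(traj.arena)
        events = detector.detect(traj, zones)
        counts = {zid: 0 for zid in ZONE_ORDER}
        for ev in events:
            counts[ev.zone_id] += 1
        for zid in ZONE_ORDER:
            rows.append(
                {
                    "animal_id": traj.animal_id,
                    "group": traj.group,
                    "day": traj.day,
                    "session": traj.session,
                    "zone_id": zid,
                    "visits": counts[zid],
                }
            )
    return pd.DataFrame(rows)


def rank_zones(visits: pd.DataFrame, days: Sequence[int] = range(1, 11)) -> pd.DataFrame:
    """Per-animal A-F ranking of zones by total visits over the given days.

    Visits are summed over ``days`` separately for each animal; zones are
    then labelled A (most visited) through F (least visited).  Ties are
    broken by the fixed zone enumeration order.

    Returns a frame with columns ``animal_id, zone_id, rank``.
    """
    days = list(days)
    sub = visits[visits["day"].isin(days)]
    rows = []
    for animal, g in sub.groupby("animal_id", sort=True):
        present_days = set(g["day"].unique())
        missing = sorted(set(days) - present_days)
        if missing:
            raise ValueError(f"animal {animal}: no visit data for days {missing}")
        totals = g.groupby("zone_id")["visits"].sum()
        if set(totals.index) != set(ZONE_ORDER):
            missing_z = sorted(set(ZONE_ORDER) - set(totals.index))
            raise ValueError(f"animal {animal}: missing zones {missing_z}")
        order = sorted(ZONE_ORDER, key=lambda z: (-totals[z], ZONE_ORDER.index(z)))
        for label, zid in zip("ABCDEF", order):
            rows.append({"animal_id": animal, "zone_id": zid, "rank": label})
    return pd.DataFrame(rows)


def apply_rank_map(visits: pd.DataFrame, rank_map: pd.DataFrame) -> pd.DataFrame:
    """Attach the per-animal A-F rank label to each visit-count row."""
    return visits.merge(rank_map, on=["animal_id", "zone_id"], how="left", validate="m:1")


def pooled_zone_matrix(
    visits: pd.DataFrame, rank_map: pd.DataFrame, group: Optional[str] = None
) -> pd.DataFrame:
    """Group-level mean (and SEM) visits per day per rank label A-F.

    Ranking aligns the idiosyncratic spatial patterns, so pooling is over
    rank labels, not physical zones.
    """
    ranked = apply_rank_map(visits, rank_map)
    if group is not None:
        ranked = ranked[ranked["group"] == group]
    out = (
        ranked.groupby(["group", "day", "session", "rank"])["visits"]
        .agg(mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan,
             n="count")
        .reset_index()
    )
    return out


def standardize_sessions(
    day10: pd.DataFrame,
    a1: pd.DataFrame,
    a2: pd.DataFrame,
    day10_length_min: float = 50.0,
    probe_length_min: float = 5.0,
) -> pd.DataFrame:
    """Convert day-10 and day-11 A1/A2 visit counts to a common rate.

    The daily sessions last 50 min while the day-11 probes last 5 min, so
    day-10 counts are divided by the duration ratio (10) and the probe
    counts pass through unchanged; the common unit is visits per 5 min.
    """
    if day10_length_min <= 0 or probe_length_min <= 0:
        raise ValueError("session lengths must be positive")
    scale = day10_length_min / probe_length_min
    frames = []
    for df, sess, factor in ((day10, "day10", scale), (a1, "A1", 1.0), (a2, "A2", 1.0)):
        if df.empty:
            raise ValueError(f"empty visit table for session {sess}")
        got = set(df["session"].unique())
        expect = {"daily"} if sess == "day10" else {sess}
        if got != expect:
            raise ValueError(f"session labels {sorted(got)} do not match expected {sorted(expect)}")
        out = df.copy()
        out["rate_per_5min"] = out["visits"] / factor
        out["session"] = sess
        frames.append(out)
    return pd.concat(frames, ignore_index=True)


def sensitization_summary(path_lengths: pd.DataFrame) -> pd.DataFrame:
    """Per-group per-day locomotion summary and day-over-day growth.

    Parameters
    ----------
    path_lengths : DataFrame
        Columns ``animal_id, group, day, path_cm`` (one row per animal-day;
        build with :func:`path_length` over the daily sessions).

    Returns a frame with per (group, day) mean and SEM path length and the
    ratio of the day's mean to the group's day-1 mean.  A zero day-1 mean
    yields NaN ratios with a warning (degenerate, e.g. stationary animals).
    """
    req = {"animal_id", "group", "day", "path_cm"}
    if not req.issubset(path_lengths.columns):
        raise ValueError(f"path_lengths must have columns {sorted(req)}")
    out = (
        path_lengths.groupby(["group", "day"])["path_cm"]
        .agg(mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan,
             n="count")
        .reset_index()
        .sort_values(["group", "day"])
    )
    ratios = []
    for grp, g in out.groupby("group"):
        base = g.loc[g["day"] == g["day"].min(), "mean"].iloc[0]
        if base == 0:
            warnings.warn(f"group {grp}: day-1 mean path length is 0; ratios undefined (NaN)")
            ratios.append(pd.Series(np.nan, index=g.index))
        else:
            ratios.append(g["mean"] / base)
    out["ratio_to_day1"] = pd.concat(ratios)
    return out


def zone_dominance(
    visits: pd.DataFrame,
    rank_map: pd.DataFrame,
    group: str,
    days: Sequence[int],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test, per day, whether rank-A visits exceed every other rank.

    For each requested day, zone-A counts are compared against each of
    B-F across animals with one-sided paired t-tests; the day is called
    dominant when all five comparisons reject at ``alpha``.  Mirrors the
    per-day zone contrasts used on the checking data.
    """
    from scipy import stats as sps

    ranked = apply_rank_map(visits, rank_map)
    ranked = ranked[(ranked["group"] == group) & (ranked["day"].isin(list(days)))]
    rows = []
    for day, g in ranked.groupby("day"):
        wide = g.pivot_table(index="animal_id", columns="rank", values="visits", aggfunc="sum")
        a = wide["A"].to_numpy(float)
        pmax = 0.0
        for other in "BCDEF":
            b = wide[other].to_numpy(float)
            if np.allclose(a, b):
                p = 1.0
            else:
                p = float(sps.ttest_rel(a, b, alternative="greater").pvalue)
            pmax = max(pmax, p)
        rows.append({"day": day, "max_p_vs_others": pmax, "dominant": pmax < alpha})
    return pd.DataFrame(rows).sort_values("day").reset_index(drop=True)
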