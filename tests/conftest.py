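"""Shared fixtures and independent brute-force oracles.

The oracles here are deliberately naive per-frame/pure-python re-statements
of the documented rules, kept independent of the vectorised implementations
they check.
"""

from __future__ import annotations

import math
from fractions import Fraction
from typing import List, Sequence, Tuple

import numpy as np
import pytest

from checkfish.arena import ArenaSpec, Zone, build_zones
from checkfish.behavior import Trajectory


@pytest.fixture(scope="session")
def arena() -> ArenaSpec:
    return ArenaSpec()


@pytest.fixture(scope="session")
def zones(arena) -> Tuple[Zone, ...]:
    return build_zones(arena)


def brute_force_visits(
    traj: Trajectory,
    zones: Sequence[Zone],
    min_dwell: float = 0.5,
    hysteresis: float = 2.0,
) -> List[Tuple[str, float, float]]:
    """Naive per-frame state machine over every sample.

    Implements the documented visit rule directly: open at an
    outside-to-inside transition, track the last sample within the zone
    radius, close at the first sample beyond radius + hysteresis, and
    keep the event when the span of inside samples reaches min_dwell.
    """
    t, xs, ys = traj.t, traj.x, traj.y
    events = []
    state = None  # [zone_index, enter_sample, last_inside_sample]
    for i in range(len(t)):
        px, py = xs[i], ys[i]
        if state is not None:
            zi, i0, last_in = state
            z = zones[zi]
            d = math.hypot(px - z.anchor[0], py - z.anchor[1])
            if d > z.radius + hysteresis:
                if t[last_in] - t[i0] >= min_dwell:
                    events.append((z.zone_id, float(t[i0]), float(t[i])))
                state = None
            elif d <= z.radius:
                state[2] = i
        if state is None:
            for zi, z in enumerate(zones):
                d = math.hypot(px - z.anchor[0], py - z.anchor[1])
                if d <= z.radius:
                    state = [zi, i, i]
                    break
    if state is not None:
        zi, i0, last_in = state
        if t[last_in] - t[i0] >= min_dwell:
            events.append((zones[zi].zone_id, float(t[i0]), float(t[-1])))
    return events


def brute_force_path_length(traj: Trajectory) -> float:
    """Per-step summation oracle for the path length."""
    total = 0.0
    for i in range(1, len(traj.t)):
        total += math.hypot(traj.x[i] - traj.x[i - 1], traj.y[i] - traj.y[i - 1])
    return total


def brute_force_similarity(n_neg: int, n_e1: int, n_e2: int, n_double: int) -> Fraction:
    """Exact-rational similarity score from the 2x2 table of counts."""
    n = n_neg + n_e1 + n_e2 + n_double
    p1 = Fraction(n_e1 + n_double, n)
    p2 = Fraction(n_e2 + n_double, n)
    pd = Fraction(n_double, n)
    return (pd - p1 * p2) / (min(p1, p2) - p1 * p2)


def random_walk_trajectory(
    seed: int,
    arena: ArenaSpec,
    n: int = 1500,
    dt: float = 0.04,
    step: float = 1.5,
) -> Trajectory:
    """A zone-agnostic correlated random walk that wanders the whole arena,
    biased to spend time near corners and objects so visits occur."""
    rng = np.random.default_rng(seed)
    anchors = list(arena.corners.values()) + [tuple(c) for c in arena.object_centers]
    x = np.empty(n)
    y = np.empty(n)
    pos = np.array([rng.uniform(0, arena.side), rng.uniform(0, arena.side)])
    heading = rng.uniform(0, 2 * np.pi)
    target = np.array(anchors[rng.integers(len(anchors))], float)
    for i in range(n):
        if rng.random() < 0.01:
            target = np.array(anchors[rng.integers(len(anchors))], float)
        to_t = math.atan2(target[1] - pos[1], target[0] - pos[0])
        heading += 0.4 * math.sin(to_t - heading) + rng.normal(0, 0.5)
        pos = pos + step * np.array([math.cos(heading), math.sin(heading)])
        pos = np.clip(pos, 0.0, arena.side)
        x[i], y[i] = pos
    return Trajectory("rw", "control", 1, "daily", np.arange(n) * dt, x, y, arena)
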