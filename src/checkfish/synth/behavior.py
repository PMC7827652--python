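"""Bout-based open-field trajectory simulator.

Movement is modelled as a sequence of bouts: a goal-directed segment
towards a target point followed by a dwell near the target.  The two arms
differ in how targets are chosen and how kinematics evolve across days:

* QNP arm -- each animal is assigned (deterministically from the seed and
  its index) one preferred corner and one preferred object; with
  probability ``home_zone_attraction`` a bout targets the preferred pair,
  alternating corner and object, which produces the idiosyncratic
  corner-object looping characteristic of drug-induced checking.  Movement
  speed grows and dwells shrink by ``sensitization_factor`` per day, so
  the expected daily path length scales as ``base x factor**(day-1)``
  (locomotor sensitization).
* control arm -- targets are unstructured (uniform interior points with a
  mild wall-following bias) and kinematics drift only by
  ``control_drift_factor`` per day (default 1.03, a slight nonsignificant
  increase; set 1.0 for perfectly flat locomotion).

Day 11 adds two 300-s probe sessions labelled A1 and A2 for every animal.
All randomness flows from a single seed through per-animal child streams,
so identical configs give bit-identical output and each animal's pattern
is stable across days.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, List, Tuple

import numpy as np

from ..arena import ZONE_ORDER, ArenaSpec
from ..behavior import Trajectory

__all__ = ["BehaviorSimConfig", "simulate_trajectories", "iter_trajectories"]


class SimConfigurationError(ValueError):
    """Raised for invalid simulator configurations."""


@dataclass
class BehaviorSimConfig:
    """Study-design and kinematic parameters of the trajectory simulator.

    Defaults mirror the study conditions: 15 QNP and 14 control animals,
    10 daily 50-min arena exposures recorded at 25 Hz in a 95-cm arena,
    plus two 5-min probe sessions on day 11.
    """

    n_qnp: int = 15
    n_control: int = 14
    n_days: int = 10
    session_length: float = 3000.0  # s (50 min)
    probe_length: float = 300.0  # s, day-11 A1/A2 sessions
    frame_rate: float = 25.0  # Hz
    arena: ArenaSpec = field(default_factory=ArenaSpec)
    base_speed: float = 8.0  # cm/s, day-1 goal-directed movement speed
    max_speed: float = 60.0  # cm/s hard kinematic cap
    sensitization_factor: float = 1.15  # per-day multiplicative growth, QNP arm
    control_drift_factor: float = 1.03  # per-day drift, control arm (1.03**9 ~ 1.3)
    home_zone_attraction: float = 0.75  # P(bout targets the preferred pair), QNP arm
    wall_bias: float = 0.3  # P(control bout targets a wall-adjacent point)
    dwell_mean: float = 4.0  # s, mean dwell at target on day 1
    position_noise: float = 0.03  # cm, per-frame tracking jitter
    include_day11: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_qnp < 0 or self.n_control < 0 or self.n_qnp + self.n_control == 0:
            raise SimConfigurationError("need at least one animal")
        if self.n_days <= 0:
            raise SimConfigurationError("n_days must be positive")
        if self.frame_rate <= 0:
            raise SimConfigurationError("frame_rate must be positive")
        if not 0.0 <= self.home_zone_attraction <= 1.0:
            raise SimConfigurationError("home_zone_attraction must be in [0, 1]")
        if self.sensitization_factor < 1.0:
            raise SimConfigurationError("sensitization_factor must be >= 1 for the QNP arm")
        if self.base_speed <= 0 or self.max_speed <= 0 or self.session_length <= 0:
            raise SimConfigurationError("speeds and session length must be positive")
        if self.dwell_mean < 0 or self.position_noise < 0:
            raise SimConfigurationError("dwell_mean and position_noise must be non-negative")


def _animal_streams(config: BehaviorSimConfig) -> List[np.random.Generator]:
    n = config.n_qnp + config.n_control
    return [np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(n)]


def preferred_zone_pair(config: BehaviorSimConfig, animal_index: int) -> Tuple[str, str]:
    """The idiosyncratic (corner, object) pair of a QNP animal.

    A deterministic function of (seed, animal index), so the per-animal
    pattern is identical on every day and every call.
    """
    ss = np.random.SeedSequence(config.seed).spawn(config.n_qnp + config.n_control)[animal_index]
    rng = np.random.default_rng(ss.spawn(1)[0])
    corner = ZONE_ORDER[int(rng.integers(4))]
    obj = ZONE_ORDER[4 + int(rng.integers(2))]
    return corner, obj


def _zone_anchor(arena: ArenaSpec, zone_id: str) -> Tuple[float, float]:
    if zone_id.startswith("corner"):
        return arena.corners[zone_id]
    return tuple(map(float, arena.object_centers[int(zone_id[-1]) - 1]))


def _session_positions(
    rng: np.random.Generator,
    config: BehaviorSimConfig,
    group: str,
    day: int,
    n_frames: int,
    pref: Tuple[str, str],
) -> Tuple[np.ndarray, np.ndarray]:
    """Fill one session with bout-structured movement."""
    arena = config.arena
    side = arena.side
    margin = 3.0
    factor = (
        config.sensitization_factor if group == "QNP" else config.control_drift_factor
    ) ** (day - 1)
    speed = min(config.base_speed * factor, config.max_speed)
    dwell_mean = config.dwell_mean / factor
    dt = 1.0 / config.frame_rate

    x = np.empty(n_frames)
    y = np.empty(n_frames)
    # Animals start in a corner facing the wall.
    start_corner = arena.corners[ZONE_ORDER[int(rng.integers(4))]]
    cx = np.clip(start_corner[0], margin, side - margin)
    cy = np.clip(start_corner[1], margin, side - margin)
    filled = 0
    next_pref = 0  # alternates corner/object for preferred-pair bouts

    while filled < n_frames:
        # --- choose a bout target ---
        if group == "QNP" and rng.random() < config.home_zone_attraction:
            zone_id = pref[next_pref]
            next_pref = 1 - next_pref
            ax, ay = _zone_anchor(arena, zone_id)
            # A point near the anchor, pulled inside the arena.
            tx = np.clip(ax + rng.normal(0, 3.0), margin, side - margin)
            ty = np.clip(ay + rng.normal(0, 3.0), margin, side - margin)
        elif group != "QNP" and rng.random() < config.wall_bias:
            # Wall-following: a point close to a random wall.
            along = rng.uniform(margin, side - margin)
            near = rng.uniform(margin, margin + 5.0)
            wall = int(rng.integers(4))
            tx, ty = [(along, near), (along, side - near), (near, along), (side - near, along)][wall]
        else:
            tx = rng.uniform(margin, side - margin)
            ty = rng.uniform(margin, side - margin)

        # --- goal-directed travel segment ---
        dist = float(np.hypot(tx - cx, ty - cy))
        # ceil keeps the per-frame displacement at or below speed * dt
        n_travel_full = max(1, int(np.ceil(dist / speed / dt)))
        n_travel = min(n_travel_full, n_frames - filled)
        frac = np.arange(1, n_travel + 1) / n_travel_full
        x[filled : filled + n_travel] = cx + frac * (tx - cx)
        y[filled : filled + n_travel] = cy + frac * (ty - cy)
        filled += n_travel
        cx, cy = tx, ty
        if filled >= n_frames:
            break

        # --- dwell at the target ---
        n_dwell = int(round(rng.exponential(dwell_mean) / dt))
        n_dwell = min(n_dwell, n_frames - filled)
        if n_dwell > 0:
            x[filled : filled + n_dwell] = cx
            y[filled : filled + n_dwell] = cy
            filled += n_dwell

    if config.position_noise > 0:
        x += rng.normal(0, config.position_noise, n_frames)
        y += rng.normal(0, config.position_noise, n_frames)
    np.clip(x, 0.0, side, out=x)
    np.clip(y, 0.0, side, out=y)
    return x, y


def iter_trajectories(config: BehaviorSimConfig) -> Iterator[Trajectory]:
    """Yield trajectories one at a time (animal-major, day-minor order).

    Streaming form of :func:`simulate_trajectories`; a full cohort at the
    default 25 Hz x 50 min is large, and most consumers (visit counting,
    path length) reduce each trajectory immediately.
    """
    streams = _animal_streams(config)
    dt = 1.0 / config.frame_rate
    n_total = config.n_qnp + config.n_control
    for idx in range(n_total):
        group = "QNP" if idx < config.n_qnp else "control"
        animal_id = f"{group}_{idx:02d}"
        rng = streams[idx]
        pref = preferred_zone_pair(config, idx)
        sessions = [(d, "daily", config.session_length) for d in range(1, config.n_days + 1)]
        if config.include_day11:
            day11 = config.n_days + 1
            sessions += [(day11, "A1", config.probe_length), (day11, "A2", config.probe_length)]
        for day, session, length in sessions:
            n_frames = int(round(length * config.frame_rate))
            x, y = _session_positions(rng, config, group, day, n_frames, pref)
            t = np.arange(n_frames) * dt
            yield Trajectory(
                animal_id=animal_id,
                group=group,
                day=day,
                session=session,
                t=t,
                x=x,
                y=y,
                arena=config.arena,
            )


def simulate_trajectories(config: BehaviorSimConfig) -> List[Trajectory]:
    """Generate the full cohort of trajectories as a list."""
    return list(iter_trajectories(config))
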