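"""Arena geometry: the square open field and its six checking zones.

The open field is a square box (default 95 x 95 cm) containing two fixed
objects.  The salient locations for stereotypical checking are the four
corners and the two objects.  Each location is covered by a zone:

* object zones -- discs of radius ``object_zone_radius`` (default 10 cm)
  centred on the object,
* corner zones -- quarter discs of radius ``corner_zone_radius`` (default
  15 cm) anchored at the corner vertex (the intersection with the arena
  square is automatic for points inside the arena).

Coordinates use the arena's SW corner as origin, x east, y north, in cm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np

__all__ = ["ArenaSpec", "Zone", "ZONE_ORDER", "build_zones"]

#: Fixed zone enumeration order; also the documented tie-break order for
#: the A-F ranking.
ZONE_ORDER: Tuple[str, ...] = (
    "corner_NW",
    "corner_NE",
    "corner_SW",
    "corner_SE",
    "object_1",
    "object_2",
)


class ArenaConfigurationError(ValueError):
    """Raised when an arena specification describes overlapping or
    out-of-bounds zones."""


def _default_object_centers() -> Tuple[Tuple[float, float], Tuple[float, float]]:
    # Two objects at arbitrary but fixed interior locations, mirroring a
    # symmetric placement on the arena's horizontal midline.
    return ((95.0 / 3.0, 47.5), (2.0 * 95.0 / 3.0, 47.5))


@dataclass(frozen=True)
class ArenaSpec:
    """Dimensions and zone geometry of the object-enriched open field.

    Parameters
    ----------
    side : float
        Side of the square floor in cm (default 95).
    wall_height : float
        Wall height in cm; metadata only, not used geometrically.
    object_centers : tuple of (x, y)
        Centres of the two fixed objects, cm, strictly inside the arena.
    object_zone_radius : float
        Radius of the circular object zones, cm (default 10).
    corner_zone_radius : float
        Radius of the quadri-circular corner zones, cm (default 15).
    """

    side: float = 95.0
    wall_height: float = 50.0
    object_centers: Tuple[Tuple[float, float], Tuple[float, float]] = field(
        default_factory=_default_object_centers
    )
    object_zone_radius: float = 10.0
    corner_zone_radius: float = 15.0

    def __post_init__(self) -> None:
        if not (0 < self.object_zone_radius < self.side / 2):
            raise ArenaConfigurationError(
                f"object_zone_radius must be in (0, side/2), got {self.object_zone_radius}"
            )
        if not (0 < self.corner_zone_radius < self.side / 2):
            raise ArenaConfigurationError(
                f"corner_zone_radius must be in (0, side/2), got {self.corner_zone_radius}"
            )
        if len(self.object_centers) != 2:
            raise ArenaConfigurationError("exactly two object centers are required")
        for cx, cy in self.object_centers:
            if not (0 < cx < self.side and 0 < cy < self.side):
                raise ArenaConfigurationError(
                    f"object center ({cx}, {cy}) is not strictly inside the arena"
                )
        # Pairwise disjointness is validated by build_zones at construction.
        build_zones(self, _validate_only=True)

    @property
    def corners(self) -> dict:
        s = self.side
        return {
            "corner_NW": (0.0, s),
            "corner_NE": (s, s),
            "corner_SW": (0.0, 0.0),
            "corner_SE": (s, 0.0),
        }


@dataclass(frozen=True)
class Zone:
    """A circular (object) or quarter-circular (corner) checking zone.

    Membership is a Euclidean distance test against the anchor; corner
    zones are additionally clipped to the arena square, which is automatic
    for points inside the arena.
    """

    zone_id: str
    anchor: Tuple[float, float]
    radius: float
    kind: str  # "corner" | "object"

    def distance(self, x, y) -> np.ndarray:
        return np.hypot(np.asarray(x, float) - self.anchor[0], np.asarray(y, float) - self.anchor[1])

    def contains(self, x, y) -> np.ndarray:
        """Vectorised membership test for in-arena points."""
        return self.distance(x, y) <= self.radius


def build_zones(arena: ArenaSpec, _validate_only: bool = False) -> Tuple[Zone, ...]:
    """Construct the six zones of an arena in the fixed enumeration order.

    Raises
    ------
    ArenaConfigurationError
        If any pair of zones overlaps (anchor distance < sum of radii).
    """
    zones = []
    for zid, anchor in arena.corners.items():
        zones.append(Zone(zid, anchor, arena.corner_zone_radius, "corner"))
    for i, center in enumerate(arena.object_centers, start=1):
        zones.append(Zone(f"object_{i}", tuple(map(float, center)), arena.object_zone_radius, "object"))
    zones.sort(key=lambda z: ZONE_ORDER.index(z.zone_id))

    for i in range(len(zones)):
        for j in range(i + 1, len(zones)):
            a, b = zones[i], zones[j]
            d = float(np.hypot(a.anchor[0] - b.anchor[0], a.anchor[1] - b.anchor[1]))
            if d < a.radius + b.radius:
                raise ArenaConfigurationError(
                    f"zones {a.zone_id} and {b.zone_id} overlap "
                    f"(anchor distance {d:.2f} < {a.radius + b.radius:.2f})"
                )
    if _validate_only:
        return ()
    return tuple(zones)
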