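"""Humphrey 24-2 test-point geometry in visual-field coordinates.

Coordinates live in visual-field space (not retinal space): ``x_deg`` is
horizontal eccentricity, positive to the right of fixation; ``y_deg`` is
vertical eccentricity, positive superior.  All 24-2 locations are odd
multiples of 3 degrees on a 6-degree grid, so each point represents a
6 x 6 = 36 deg^2 cell of the visual field.

Two frames are used throughout the package:

* the **common binocular frame** — the 52 locations with ``|x| <= 21`` that
  both eyes can test, on which integrated fields and all outcome scoring
  are defined;
* the **eye-native frame** — the 52 locations actually measured in one eye:
  the common frame plus the two nasal-extension points at ``|x| = 27``,
  minus the two points falling on that eye's physiological blind spot
  (15 degrees temporal, ``y = +/-3``).

The left eye's native grid is the mirror image (``x -> -x``) of the right
eye's.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, NamedTuple, Sequence

Eye = Literal["OD", "OS"]
Side = Literal["left", "right"]
Quadrant = Literal["UL", "UR", "LL", "LR"]

#: Visual-field area represented by one 24-2 test point, in deg^2.
POINT_AREA_DEG2 = 36.0

EYES: tuple[Eye, ...] = ("OD", "OS")
VISITS: tuple[str, ...] = ("baseline", "week12")
SIDES: tuple[Side, ...] = ("left", "right")
QUADRANTS: tuple[Quadrant, ...] = ("UL", "UR", "LL", "LR")


class FieldLocation(NamedTuple):
    """One 24-2 test point (degrees of visual field)."""

    x_deg: int
    y_deg: int

    @property
    def ring(self) -> int:
        """Chebyshev eccentricity ring index: 0 for |x|,|y| <= 3 up to 4 at 27."""
        return (max(abs(self.x_deg), abs(self.y_deg)) - 3) // 6


# Half-width of each 24-2 row (|x| of the outermost point), by |y|.
_ROW_HALF_WIDTH = {21: 9, 15: 15, 9: 21, 3: 21}


def _build_common_frame() -> tuple[FieldLocation, ...]:
    locs = []
    for y in (21, 15, 9, 3, -3, -9, -15, -21):
        half = _ROW_HALF_WIDTH[abs(y)]
        for x in range(-half, half + 1, 6):
            locs.append(FieldLocation(x, y))
    return tuple(locs)


_COMMON_FRAME = _build_common_frame()
_COMMON_SET = frozenset(_COMMON_FRAME)


def common_frame_locations() -> list[FieldLocation]:
    """The 52 common-frame locations, row-major (superior to inferior, left to right)."""
    return list(_COMMON_FRAME)


def point_area_deg2() -> float:
    """Area of visual field represented by one 24-2 point (36 deg^2)."""
    return POINT_AREA_DEG2


def native_locations(eye: Eye) -> list[FieldLocation]:
    """The 52 locations measured in one eye, in deterministic row-major order.

    For the right eye (OD) the nasal visual field is to the left of fixation:
    the grid extends to (-27, +/-3) and omits the blind-spot points at
    (+15, +/-3).  The left eye (OS) is the mirror image.
    """
    if eye not in EYES:
        raise ValueError(f"unknown eye code {eye!r}; expected one of {EYES}")
    # OD: nasal extension at x=-27, blind spot at x=+15.
    nasal_x, blind_x = (-27, 15) if eye == "OD" else (27, -15)
    locs = [
        loc for loc in _COMMON_FRAME
        if not (loc.x_deg == blind_x and abs(loc.y_deg) == 3)
    ]
    locs.extend([FieldLocation(nasal_x, 3), FieldLocation(nasal_x, -3)])
    locs.sort(key=lambda p: (-p.y_deg, p.x_deg))
    return locs


def in_common_frame(loc: FieldLocation) -> bool:
    return loc in _COMMON_SET


def is_valid_grid_point(x: int, y: int) -> bool:
    """True if (x, y) are odd multiples of 3 (any 24-2 frame point candidate)."""
    return x % 2 != 0 and y % 2 != 0 and x % 3 == 0 and y % 3 == 0


@dataclass(frozen=True)
class RegionSpec:
    """A scoring region of the common binocular frame.

    Construct via the classmethods: :meth:`whole`, :meth:`hemifield`,
    :meth:`quadrant` or :meth:`mask`.
    """

    kind: str
    side: Side | None = None
    quad: Quadrant | None = None
    locations: tuple[FieldLocation, ...] = field(default=())

    @classmethod
    def whole(cls) -> "RegionSpec":
        return cls(kind="whole")

    @classmethod
    def hemifield(cls, side: Side) -> "RegionSpec":
        if side not in SIDES:
            raise ValueError(f"unknown hemifield side {side!r}")
        return cls(kind="hemifield", side=side)

    @classmethod
    def quadrant(cls, quad: Quadrant) -> "RegionSpec":
        if quad not in QUADRANTS:
            raise ValueError(f"unknown quadrant {quad!r}")
        return cls(kind="quadrant", quad=quad)

    @classmethod
    def mask(cls, locations: Sequence[FieldLocation]) -> "RegionSpec":
        locs = tuple(FieldLocation(*p) for p in locations)
        bad = [p for p in locs if p not in _COMMON_SET]
        if bad:
            raise ValueError(f"mask locations outside the common frame: {bad}")
        return cls(kind="mask", locations=locs)

    def members(self) -> list[FieldLocation]:
        return region_members(self)

    def __len__(self) -> int:
        return len(self.members())

    def __contains__(self, loc: FieldLocation) -> bool:
        return loc in set(self.members())


def _quadrant_test(quad: Quadrant, loc: FieldLocation) -> bool:
    horiz = loc.x_deg < 0 if quad[1] == "L" else loc.x_deg > 0
    vert = loc.y_deg > 0 if quad[0] == "U" else loc.y_deg < 0
    return horiz and vert


def region_members(region: RegionSpec) -> list[FieldLocation]:
    """Resolve a region to its common-frame locations (deterministic order)."""
    if region.kind == "whole":
        return list(_COMMON_FRAME)
    if region.kind == "hemifield":
        sign = -1 if region.side == "left" else 1
        return [p for p in _COMMON_FRAME if sign * p.x_deg > 0]
    if region.kind == "quadrant":
        return [p for p in _COMMON_FRAME if _quadrant_test(region.quad, p)]
    if region.kind == "mask":
        return list(region.locations)
    raise ValueError(f"unknown region kind {region.kind!r}")


def hemifield_of(loc: FieldLocation) -> Side:
    return "left" if loc.x_deg < 0 else "right"


def quadrant_of(loc: FieldLocation) -> Quadrant:
    v = "U" if loc.y_deg > 0 else "L"
    h = "L" if loc.x_deg < 0 else "R"
    return v + h  # type: ignore[return-value]
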