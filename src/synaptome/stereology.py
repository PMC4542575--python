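"""Unbiased 3D counting brick for synaptic profiles.

Serial-section electron microscopy (e.g. FIB/SEM) yields a stack of
aligned images in which segmented synaptic profiles appear as 3D objects.
Counting them without bias against object size uses the 3D extension of
the unbiased counting frame: a brick bound by three acceptance planes
(top, left, front) and three exclusion planes (right, bottom, back). An
object is counted when it lies inside the brick or touches only
acceptance planes; touching or crossing any exclusion plane disqualifies
it, and exclusion dominates on conflict.

Coordinates are right-handed with x to the right, y downward and z into
the stack, so the acceptance planes sit at the minimum coordinate of each
axis and the exclusion planes at the maximum. The counting domain is the
half-open box [min, max) per axis, which makes the rule exact: an
axis-aligned object is included if and only if its maximum corner falls
inside the half-open box. Tiling a region with bricks under this
convention assigns every object to exactly one brick, the property that
makes the estimator unbiased.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

__all__ = [
    "CountingBrick",
    "SynapticProfile3D",
    "BrickCounts",
    "DensityEstimate",
    "classify_profile",
    "count_brick",
    "estimate_density",
    "tile_bricks",
    "load_profiles",
    "save_profiles",
    "ASYMMETRIC",
    "SYMMETRIC",
]

ASYMMETRIC = "asym"
SYMMETRIC = "sym"

Vec3 = tuple[float, float, float]


@dataclass(frozen=True)
class CountingBrick:
    """A 3D counting frame.

    ``frame_width`` x ``frame_height`` (um) is the in-section counting
    frame; depth is ``n_sections`` x ``section_thickness`` (um). ``origin``
    is the acceptance corner (minimum x, y, z). ``shrinkage`` holds
    per-axis linear correction factors that multiply the stored dimensions
    before any classification or volume computation; the default (1, 1, 1)
    means dimensions are already corrected.
    """

    frame_width: float
    frame_height: float
    n_sections: int
    section_thickness: float
    origin: Vec3 = (0.0, 0.0, 0.0)
    shrinkage: Vec3 = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.frame_width <= 0 or self.frame_height <= 0:
            raise ValueError("frame dimensions must be > 0")
        if self.n_sections <= 0 or self.section_thickness <= 0:
            raise ValueError("n_sections and section_thickness must be > 0")
        if any(s <= 0 for s in self.shrinkage):
            raise ValueError("shrinkage factors must be > 0")

    @property
    def depth(self) -> float:
        return self.n_sections * self.section_thickness

    @property
    def size(self) -> Vec3:
        """Shrinkage-corrected extent per axis (um)."""
        sx, sy, sz = self.shrinkage
        return (self.frame_width * sx, self.frame_height * sy, self.depth * sz)

    @property
    def lo(self) -> Vec3:
        return self.origin

    @property
    def hi(self) -> Vec3:
        return tuple(o + s for o, s in zip(self.origin, self.size))  # type: ignore[return-value]

    @property
    def volume(self) -> float:
        w, h, d = self.size
        return w * h * d


@dataclass(frozen=True)
class SynapticProfile3D:
    """One segmented synaptic profile: type label plus axis-aligned extent.

    ``min_corner``/``max_corner`` bound the 3D reconstruction of the
    synaptic membrane densities across serial sections (um). A zero-extent
    profile (a point) is legal and is classified by point-in-box
    membership.
    """

    id: str
    type: Literal["asym", "sym"]
    min_corner: Vec3
    max_corner: Vec3

    def __post_init__(self) -> None:
        if self.type not in (ASYMMETRIC, SYMMETRIC):
            raise ValueError(
                f"profile {self.id!r}: type must be {ASYMMETRIC!r} or "
                f"{SYMMETRIC!r}, got {self.type!r}"
            )
        for a, b in zip(self.min_corner, self.max_corner):
            if a > b:
                raise ValueError(
                    f"profile {self.id!r}: min corner exceeds max corner"
                )


def classify_profile(
    profile: SynapticProfile3D, brick: CountingBrick
) -> bool:
    """True when the profile is counted by this brick.

    A profile is included iff it overlaps the brick and touches no
    exclusion plane (the maximum-coordinate faces). Under the half-open
    counting domain this reduces to the profile's maximum corner lying in
    [lo, hi) on every axis: crossing only acceptance (minimum) faces keeps
    it included, while touching any exclusion face — or lying wholly
    outside — excludes it.
    """
    lo = brick.lo
    hi = brick.hi
    return all(
        lo[i] <= profile.max_corner[i] < hi[i] for i in range(3)
    )


@dataclass(frozen=True)
class BrickCounts:
    """Per-type counts inside one brick, with the brick volume (um^3)."""

    n_asym: int
    n_sym: int
    volume: float
    included_ids: tuple[str, ...] = ()
    excluded_ids: tuple[str, ...] = ()


def count_brick(
    profiles: Iterable[SynapticProfile3D], brick: CountingBrick
) -> BrickCounts:
    """Partition profiles by the counting rule and tally per type."""
    profiles = list(profiles)
    seen: set[str] = set()
    for p in profiles:
        if p.id in seen:
            raise ValueError(f"duplicate profile id {p.id!r}")
        seen.add(p.id)
    included = [p for p in profiles if classify_profile(p, brick)]
    excluded_ids = tuple(p.id for p in profiles if p.id not in {q.id for q in included})
    return BrickCounts(
        n_asym=sum(1 for p in included if p.type == ASYMMETRIC),
        n_sym=sum(1 for p in included if p.type == SYMMETRIC),
        volume=brick.volume,
        included_ids=tuple(p.id for p in included),
        excluded_ids=excluded_ids,
    )


@dataclass(frozen=True)
class DensityEstimate:
    """Volumetric synapse densities (per um^3) and the asymmetric fraction.

    ``asym_fraction`` is None when no profiles were counted.
    """

    total: float
    asym: float
    sym: float
    asym_fraction: float | None


def estimate_density(counts: BrickCounts) -> DensityEstimate:
    """Convert brick counts into volumetric densities."""
    if counts.volume <= 0:
        raise ValueError(f"brick volume must be > 0, got {counts.volume}")
    n = counts.n_asym + counts.n_sym
    frac = counts.n_asym / n if n > 0 else None
    return DensityEstimate(
        total=n / counts.volume,
        asym=counts.n_asym / counts.volume,
        sym=counts.n_sym / counts.volume,
        asym_fraction=frac,
    )


def tile_bricks(
    region_min: Vec3,
    region_max: Vec3,
    frame_width: float,
    frame_height: float,
    n_sections: int,
    section_thickness: float,
) -> list[CountingBrick]:
    """Tile a region with non-overlapping counting bricks.

    The region extent must be a positive integer multiple of the brick
    extent on every axis (to within 1e-9 relative). Adjacent bricks share
    faces; the half-open counting domain guarantees each interior point —
    and each object — belongs to exactly one brick.
    """
    size = (frame_width, frame_height, n_sections * section_thickness)
    counts = []
    for axis in range(3):
        extent = region_max[axis] - region_min[axis]
        if extent <= 0:
            raise ValueError(f"region extent must be > 0 on axis {axis}")
        ratio = extent / size[axis]
        n = round(ratio)
        if n < 1 or abs(ratio - n) > 1e-9 * max(1.0, abs(ratio)):
            raise ValueError(
                f"region extent {extent} on axis {axis} is not a multiple "
                f"of brick extent {size[axis]}"
            )
        counts.append(n)
    bricks = []
    for i in range(counts[0]):
        for j in range(counts[1]):
            for k in range(counts[2]):
                origin = (
                    region_min[0] + i * size[0],
                    region_min[1] + j * size[1],
                    region_min[2] + k * size[2],
                )
                bricks.append(
                    CountingBrick(
                        frame_width=frame_width,
                        frame_height=frame_height,
                        n_sections=n_sections,
                        section_thickness=section_thickness,
                        origin=origin,
                    )
                )
    return bricks


def load_profiles(path: str | Path) -> list[SynapticProfile3D]:
    """Read the standard profile list: a JSON array of
    ``{"id", "type": "asym"|"sym", "min": [x,y,z], "max": [x,y,z]}``."""
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, list):
        raise ValueError(f"profile file {path} must contain a JSON array")
    profiles = []
    for i, obj in enumerate(data):
        try:
            profiles.append(
                SynapticProfile3D(
                    id=str(obj["id"]),
                    type=obj["type"],
                    min_corner=tuple(float(v) for v in obj["min"]),
                    max_corner=tuple(float(v) for v in obj["max"]),
                )
            )
        except (KeyError, TypeError) as exc:
            raise ValueError(f"profile file {path}, entry {i}: {exc}") from None
    return profiles


def save_profiles(
    profiles: Sequence[SynapticProfile3D], path: str | Path
) -> None:
    """Write profiles in the standard JSON format."""
    data = [
        {
            "id": p.id,
            "type": p.type,
            "min": list(p.min_corner),
            "max": list(p.max_corner),
        }
        for p in profiles
    ]
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)
        fh.write("\n")
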