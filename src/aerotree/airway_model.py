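"""Procedural generation of the idealized upper-airway tree.

The geometry is a single lumped mouth-throat compartment feeding a
seven-generation dichotomously branching, mildly asymmetric bronchial tree
(trachea + 6 bifurcation levels = 64 terminal outlets, each labelled with
one of the five lung lobes).  Anchor dimensions are the adult mouth
hydraulic diameter (19 mm), tracheal diameter (16 mm) and main-bronchus
diameter (10.8 mm); pediatric anatomy is obtained by homothetic scaling
(every length and diameter multiplied by one age-specific factor).

Distal morphometry below the main bronchi is not anchored to measurements:
per-level child/parent diameter ratios follow a Weibel-like taper with mild
asymmetry, and all ratios, angles and the lobe partition are configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
import pandas as pd

__all__ = [
    "Region", "Lobe", "AirwaySegment", "AirwayTree", "AgeAnatomy",
    "TreeConfig", "AGE_ANATOMY", "age_scale_factor", "build_adult_tree",
    "build_tree", "scale_tree", "path_to_outlet", "write_segment_table",
    "read_segment_table",
]

N_BRONCHIAL_LEVELS = 6          # bifurcation levels below the trachea
N_OUTLETS = 2 ** N_BRONCHIAL_LEVELS


class Region(str, Enum):
    MOUTH_THROAT = "MOUTH_THROAT"
    TRACHEA = "TRACHEA"
    CONDUCTING = "CONDUCTING"


class Lobe(str, Enum):
    RU = "RU"   # right upper
    RM = "RM"   # right middle
    RL = "RL"   # right lower
    LU = "LU"   # left upper
    LL = "LL"   # left lower
    NONE = "NONE"


class ConfigurationError(ValueError):
    """Raised for geometrically impossible tree configurations."""


@dataclass(frozen=True)
class AirwaySegment:
    """One airway conduit (straight-tube idealization).

    ``gravity_angle`` is the inclination of the segment axis from the
    horizontal plane (gravity acts along -Y): pi/2 means vertical.
    ``branching_angle`` is measured from the parent axis and is zero for
    the mouth-throat and trachea (straight entry).
    """

    id: int
    region: Region
    level: int                   # -1 mouth-throat, 0 trachea, 1..6 bronchial
    parent_id: int | None
    child_ids: tuple[int, ...]
    length: float                # m
    diameter: float              # m (hydraulic diameter for mouth-throat)
    branching_angle: float       # rad
    gravity_angle: float         # rad
    lobe: Lobe = Lobe.NONE

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.length <= 0:
            raise ValueError(f"segment {self.id}: non-positive dimensions")
        allowed = (0, 1) if self.region is Region.MOUTH_THROAT else (0, 2)
        if len(self.child_ids) not in allowed:
            raise ValueError(
                f"segment {self.id}: dichotomous tree requires 0 or 2 children "
                "(mouth-throat feeds the trachea serially)")
        if not 0.0 <= self.branching_angle <= math.pi / 2:
            raise ValueError(f"segment {self.id}: branching angle out of range")
        if not -math.pi / 2 <= self.gravity_angle <= math.pi / 2:
            raise ValueError(f"segment {self.id}: gravity angle out of range")

    @property
    def is_terminal(self) -> bool:
        return not self.child_ids


@dataclass(frozen=True)
class AgeAnatomy:
    """Tabulated anatomy anchor for one age point (diameters in mm)."""

    age: float                   # years
    scale_factor: float
    expected_mouth_d: float
    expected_trachea_d: float
    expected_bronchus_d: float


#: Anchor table: airway diameters (mm) and homothetic scale factor per age.
AGE_ANATOMY: dict[float, AgeAnatomy] = {
    5.0: AgeAnatomy(5.0, 0.578, 11.0, 9.0, 6.2),
    10.0: AgeAnatomy(10.0, 0.743, 14.0, 11.6, 8.0),
    25.0: AgeAnatomy(25.0, 1.0, 19.0, 16.0, 10.8),
}

#: Default terminal-outlet count per lobe (sums to 64).
DEFAULT_LOBE_COUNTS: dict[Lobe, int] = {
    Lobe.RU: 10, Lobe.RM: 6, Lobe.RL: 16, Lobe.LU: 12, Lobe.LL: 20,
}


@dataclass(frozen=True)
class TreeConfig:
    """Knobs for the procedural tree builder (adult scale, SI units)."""

    mouth_hydraulic_d: float = 0.019
    mouth_length: float = 0.17
    trachea_d: float = 0.016
    trachea_length_over_d: float = 6.25
    bronchus_d: float = 0.0108          # level-1 main bronchi
    major_ratio: float = 0.86           # major child d / parent d, levels >= 2
    minor_ratio: float = 0.72
    length_over_d: float = 3.0          # conducting segments
    branching_angle: float = math.radians(35.0)
    gravity_angle_odd: float = math.radians(20.0)   # levels 1, 3, 5
    gravity_angle_even: float = math.radians(50.0)  # levels 2, 4, 6
    lobe_counts: dict[Lobe, int] = field(
        default_factory=lambda: dict(DEFAULT_LOBE_COUNTS))

    def validate(self) -> None:
        for name in ("mouth_hydraulic_d", "mouth_length", "trachea_d",
                     "trachea_length_over_d", "bronchus_d", "length_over_d"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("major_ratio", "minor_ratio"):
            r = getattr(self, name)
            if not 0.0 < r <= 1.0:
                raise ConfigurationError(
                    f"{name}={r}: child/parent diameter ratio must be in (0, 1]")
        if self.bronchus_d > self.trachea_d:
            raise ConfigurationError("bronchus diameter exceeds trachea diameter")
        counts = self.lobe_counts
        right = counts.get(Lobe.RU, 0) + counts.get(Lobe.RM, 0) + counts.get(Lobe.RL, 0)
        left = counts.get(Lobe.LU, 0) + counts.get(Lobe.LL, 0)
        if right != N_OUTLETS // 2 or left != N_OUTLETS // 2:
            raise ConfigurationError(
                "lobe outlet counts must sum to 32 per lung "
                f"(got right={right}, left={left})")
        if any(v <= 0 for v in counts.values()):
            raise ConfigurationError("every lobe needs at least one outlet")


@dataclass(frozen=True)
class AirwayTree:
    """Immutable airway tree for one age point."""

    segments: dict[int, AirwaySegment]
    age_label: float             # years
    scale_factor: float

    @property
    def mouth(self) -> AirwaySegment:
        return next(s for s in self.segments.values()
                    if s.region is Region.MOUTH_THROAT)

    @property
    def trachea(self) -> AirwaySegment:
        return next(s for s in self.segments.values()
                    if s.region is Region.TRACHEA)

    @property
    def mouth_hydraulic_diameter(self) -> float:
        return self.mouth.diameter

    @property
    def mouth_inlet_area(self) -> float:
        """Circular-equivalent inlet area pi*Dh^2/4 (m^2)."""
        d = self.mouth_hydraulic_diameter
        return math.pi * d * d / 4.0

    @property
    def outlets(self) -> list[AirwaySegment]:
        return sorted((s for s in self.segments.values() if s.is_terminal),
                      key=lambda s: s.id)

    def lobe_counts(self) -> dict[Lobe, int]:
        counts: dict[Lobe, int] = {}
        for s in self.outlets:
            counts[s.lobe] = counts.get(s.lobe, 0) + 1
        return counts

    def validate(self) -> None:
        regions = [s.region for s in self.segments.values()]
        if regions.count(Region.MOUTH_THROAT) != 1:
            raise ValueError("tree must have exactly one mouth-throat segment")
        if regions.count(Region.TRACHEA) != 1:
            raise ValueError("tree must have exactly one trachea segment")
        outs = self.outlets
        if len(outs) != N_OUTLETS:
            raise ValueError(f"tree must have {N_OUTLETS} outlets, got {len(outs)}")
        if any(s.lobe is Lobe.NONE for s in outs):
            raise ValueError("every terminal segment needs a lobe label")
        for s in self.segments.values():
            for cid in s.child_ids:
                if self.segments[cid].diameter > s.diameter + 1e-15:
                    raise ValueError(
                        f"child {cid} wider than parent {s.id}")


def age_scale_factor(age: float) -> float:
    """Homothetic scale factor for a tabulated age point (5, 10 or 25 y)."""
    anat = AGE_ANATOMY.get(float(age))
    if anat is None:
        raise ValueError(
            f"age point {age} y not tabulated (supported: 5, 10, 25); "
            "no interpolation is performed")
    return anat.scale_factor


def build_adult_tree(config: TreeConfig | None = None) -> AirwayTree:
    """Build the deterministic 25-year reference tree.

    Topology: segment 0 = mouth-throat, 1 = trachea, then bifurcation
    levels 1..6 in breadth-first id order.  At levels >= 2 the wider
    (major) child alternates sides deterministically with the parent's
    position in its level, which produces a mildly asymmetric
    Horsfield-style tree without any randomness.
    """
    config = config or TreeConfig()
    config.validate()

    # raw records mutated during construction; frozen dataclasses at the end
    recs: dict[int, dict] = {}
    recs[0] = dict(id=0, region=Region.MOUTH_THROAT, level=-1, parent_id=None,
                   child_ids=[1], length=config.mouth_length,
                   diameter=config.mouth_hydraulic_d,
                   branching_angle=0.0, gravity_angle=0.0, lobe=Lobe.NONE)
    trachea_len = config.trachea_length_over_d * config.trachea_d
    recs[1] = dict(id=1, region=Region.TRACHEA, level=0, parent_id=0,
                   child_ids=[], length=trachea_len,
                   diameter=config.trachea_d,
                   branching_angle=0.0, gravity_angle=math.pi / 2,
                   lobe=Lobe.NONE)

    next_id = 2
    current = [1]                       # ids at the previous level
    for level in range(1, N_BRONCHIAL_LEVELS + 1):
        grav = (config.gravity_angle_odd if level % 2 == 1
                else config.gravity_angle_even)
        nxt: list[int] = []
        for pos, pid in enumerate(current):
            parent = recs[pid]
            if level == 1:
                # both main bronchi pinned to the tabulated diameter
                child_d = (config.bronchus_d, config.bronchus_d)
            elif pos % 2 == 0:
                child_d = (config.major_ratio * parent["diameter"],
                           config.minor_ratio * parent["diameter"])
            else:
                child_d = (config.minor_ratio * parent["diameter"],
                           config.major_ratio * parent["diameter"])
            for d in child_d:
                recs[next_id] = dict(
                    id=next_id, region=Region.CONDUCTING, level=level,
                    parent_id=pid, child_ids=[], length=config.length_over_d * d,
                    diameter=d, branching_angle=config.branching_angle,
                    gravity_angle=grav, lobe=Lobe.NONE)
                parent["child_ids"].append(next_id)
                nxt.append(next_id)
                next_id += 1
        current = nxt

    # lobe labels: trachea child 0 roots the right lung, child 1 the left;
    # ordered outlets within each lung are split into contiguous lobar blocks
    right_root, left_root = recs[1]["child_ids"]

    def subtree_terminals(root: int) -> list[int]:
        out, stack = [], [root]
        while stack:
            i = stack.pop()
            kids = recs[i]["child_ids"]
            if kids:
                stack.extend(reversed(kids))
            else:
                out.append(i)
        return sorted(out)

    cc = config.lobe_counts
    assignment: list[tuple[Lobe, int]] = [
        (Lobe.RU, cc[Lobe.RU]), (Lobe.RM, cc[Lobe.RM]), (Lobe.RL, cc[Lobe.RL])]
    terminals = subtree_terminals(right_root)
    i = 0
    for lobe, n in assignment:
        for tid in terminals[i:i + n]:
            recs[tid]["lobe"] = lobe
        i += n
    terminals = subtree_terminals(left_root)
    i = 0
    for lobe, n in ((Lobe.LU, cc[Lobe.LU]), (Lobe.LL, cc[Lobe.LL])):
        for tid in terminals[i:i + n]:
            recs[tid]["lobe"] = lobe
        i += n

    segments = {
        i: AirwaySegment(**{**r, "child_ids": tuple(r["child_ids"])})
        for i, r in recs.items()
    }
    tree = AirwayTree(segments=segments, age_label=25.0, scale_factor=1.0)
    tree.validate()
    return tree


def scale_tree(tree: AirwayTree, factor: float,
               age_label: float | None = None) -> AirwayTree:
    """Homothetic scaling: every length and diameter multiplied by ``factor``.

    Angles, topology and lobe labels are untouched; the mouth inlet area
    therefore scales by ``factor**2``.
    """
    if factor <= 0:
        raise ValueError(f"scale factor must be positive, got {factor}")
    segments = {
        i: replace(s, length=s.length * factor, diameter=s.diameter * factor)
        for i, s in tree.segments.items()
    }
    return AirwayTree(
        segments=segments,
        age_label=tree.age_label if age_label is None else age_label,
        scale_factor=tree.scale_factor * factor,
    )


def build_tree(age: float, config: TreeConfig | None = None) -> AirwayTree:
    """Adult reference tree homothetically scaled to a tabulated age point."""
    factor = age_scale_factor(age)
    return scale_tree(build_adult_tree(config), factor, age_label=float(age))


def path_to_outlet(tree: AirwayTree, outlet_id: int) -> list[AirwaySegment]:
    """Ordered mouth-throat -> trachea -> ... -> outlet segment list."""
    seg = tree.segments.get(outlet_id)
    if seg is None or not seg.is_terminal:
        raise ValueError(f"segment {outlet_id} is not a terminal outlet")
    path = [seg]
    while seg.parent_id is not None:
        seg = tree.segments[seg.parent_id]
        path.append(seg)
    return path[::-1]


# ---------------------------------------------------------------------------
# segment-table I/O

_CSV_COLUMNS = ["id", "region", "level", "parent_id", "lobe", "length_m",
                "diameter_m", "branching_angle_rad", "gravity_angle_rad"]


def write_segment_table(tree: AirwayTree, path: str | Path) -> None:
    rows = [
        dict(id=s.id, region=s.region.value, level=s.level,
             parent_id=-1 if s.parent_id is None else s.parent_id,
             lobe=s.lobe.value, length_m=s.length, diameter_m=s.diameter,
             branching_angle_rad=s.branching_angle,
             gravity_angle_rad=s.gravity_angle)
        for s in sorted(tree.segments.values(), key=lambda s: s.id)
    ]
    # %.17g keeps the write/read round trip bit-exact
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False,
                                                    float_format="%.17g")


def read_segment_table(path: str | Path, age_label: float = 25.0,
                       scale_factor: float = 1.0) -> AirwayTree:
    df = pd.read_csv(path, float_precision="round_trip")
    children: dict[int, list[int]] = {}
    for _, row in df.iterrows():
        pid = int(row["parent_id"])
        if pid >= 0:
            children.setdefault(pid, []).append(int(row["id"]))
    segments = {}
    for _, row in df.iterrows():
        i = int(row["id"])
        pid = int(row["parent_id"])
        segments[i] = AirwaySegment(
            id=i, region=Region(row["region"]), level=int(row["level"]),
            parent_id=None if pid < 0 else pid,
            child_ids=tuple(sorted(children.get(i, []))),
            length=float(row["length_m"]), diameter=float(row["diameter_m"]),
            branching_angle=float(row["branching_angle_rad"]),
            gravity_angle=float(row["gravity_angle_rad"]),
            lobe=Lobe(row["lobe"]))
    tree = AirwayTree(segments=segments, age_label=age_label,
                      scale_factor=scale_factor)
    tree.validate()
    return tree
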