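"""The apparatus graph: four compartments on a ring, bridged by four tube
corridors carrying two antennas each.

Every antenna belongs to exactly one corridor and sits at one of its ends,
next to the "nearest compartment" there.  The session-reconstruction rules
only need, for any two antennas, whether they are the same antenna, share a
corridor, share a nearest compartment, or none of these ("opposite" —
evidence of at least one missed detection).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping

from .errors import ConfigError, ValidationError

__all__ = [
    "AntennaInfo",
    "Topology",
    "PairCategory",
    "PairRelation",
    "standard_topology",
    "parse_topology",
    "relate",
]


@dataclass(frozen=True)
class AntennaInfo:
    corridor: int
    nearest_compartment: int


class Topology:
    """Antenna → (corridor, nearest compartment) assignment, validated as a
    single 4-compartment / 4-corridor ring."""

    def __init__(self, antennas: Mapping[int, AntennaInfo]):
        self.antennas = dict(antennas)
        self._validate()

    def _validate(self) -> None:
        corridors: dict[int, list[int]] = {}
        comp_degree: dict[int, int] = {}
        for aid, info in self.antennas.items():
            corridors.setdefault(info.corridor, []).append(aid)
            comp_degree[info.nearest_compartment] = comp_degree.get(info.nearest_compartment, 0) + 1
        for cid, aids in corridors.items():
            if len(aids) != 2:
                raise ValidationError(f"corridor {cid} must carry exactly 2 antennas, has {len(aids)}")
            ends = {self.antennas[a].nearest_compartment for a in aids}
            if len(ends) != 2:
                raise ValidationError(f"corridor {cid}: its two antennas must face distinct compartments")
        for comp, deg in comp_degree.items():
            if deg != 2:
                raise ValidationError(f"compartment {comp} must adjoin exactly 2 antennas, has {deg}")
        # the compartment-corridor graph must be one cycle: every compartment
        # has degree 2 (checked above) and the edge set is connected
        if len(corridors) != len(comp_degree):
            raise ValidationError("need equally many corridors and compartments for a ring")
        adj: dict[int, set[int]] = {c: set() for c in comp_degree}
        for cid in corridors:
            a, b = self.corridor_ends(cid)
            adj[a].add(b)
            adj[b].add(a)
        seen = set()
        stack = [next(iter(adj))]
        while stack:
            node = stack.pop()
            if node in seen:
                continue
            seen.add(node)
            stack.extend(adj[node] - seen)
        if seen != set(adj):
            raise ValidationError("compartment-corridor graph is not a single ring")

    @property
    def compartments(self) -> list[int]:
        return sorted({i.nearest_compartment for i in self.antennas.values()})

    @property
    def corridors(self) -> list[int]:
        return sorted({i.corridor for i in self.antennas.values()})

    def corridor_of(self, antenna: int) -> int:
        return self._info(antenna).corridor

    def nearest_compartment(self, antenna: int) -> int:
        return self._info(antenna).nearest_compartment

    def corridor_ends(self, corridor: int) -> tuple[int, int]:
        ends = sorted(
            info.nearest_compartment
            for info in self.antennas.values()
            if info.corridor == corridor
        )
        return ends[0], ends[1]

    def corridors_of_compartment(self, compartment: int) -> list[int]:
        return sorted(
            {info.corridor for info in self.antennas.values() if info.nearest_compartment == compartment}
        )

    def antenna_at(self, corridor: int, compartment: int) -> int:
        for aid, info in self.antennas.items():
            if info.corridor == corridor and info.nearest_compartment == compartment:
                return aid
        raise ValidationError(f"no antenna at corridor {corridor} end facing compartment {compartment}")

    def _info(self, antenna: int) -> AntennaInfo:
        try:
            return self.antennas[antenna]
        except KeyError:
            raise ValidationError(f"unknown antenna id {antenna}") from None


class PairCategory(Enum):
    SAME_ANTENNA = "same_antenna"
    SAME_CORRIDOR = "same_corridor"
    SHARED_COMPARTMENT = "shared_compartment"
    OPPOSITE = "opposite"


@dataclass(frozen=True)
class PairRelation:
    category: PairCategory
    compartment: int | None = None

    def __post_init__(self) -> None:
        has_comp = self.category in (PairCategory.SAME_ANTENNA, PairCategory.SHARED_COMPARTMENT)
        if has_comp != (self.compartment is not None):
            raise ValidationError("compartment present iff the relation designates one")


def standard_topology() -> Topology:
    """Canonical ring numbering: corridor k connects compartments k and
    (k mod 4)+1; antennas 2k-1 and 2k sit at those ends respectively."""
    antennas = {}
    for k in range(1, 5):
        antennas[2 * k - 1] = AntennaInfo(corridor=k, nearest_compartment=k)
        antennas[2 * k] = AntennaInfo(corridor=k, nearest_compartment=(k % 4) + 1)
    return Topology(antennas)


def parse_topology(text: str) -> Topology:
    """Parse a small plain-text description, one antenna per line:

    ``antenna<TAB>corridor<TAB>nearest_compartment``  (``#`` comments allowed)
    """
    antennas: dict[int, AntennaInfo] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.replace("\t", " ").split()
        if len(fields) != 3:
            raise ConfigError(f"topology line {lineno}: expected 'antenna corridor compartment'")
        try:
            aid, corridor, comp = (int(f) for f in fields)
        except ValueError:
            raise ConfigError(f"topology line {lineno}: non-integer field") from None
        if aid in antennas:
            raise ConfigError(f"topology line {lineno}: duplicate antenna {aid}")
        antennas[aid] = AntennaInfo(corridor, comp)
    return Topology(antennas)


def relate(top: Topology, a1: int, a2: int) -> PairRelation:
    """Classify an ordered antenna pair geometrically (symmetric in a1, a2)."""
    i1, i2 = top._info(a1), top._info(a2)
    if a1 == a2:
        return PairRelation(PairCategory.SAME_ANTENNA, i1.nearest_compartment)
    if i1.corridor == i2.corridor:
        return PairRelation(PairCategory.SAME_CORRIDOR)
    if i1.nearest_compartment == i2.nearest_compartment:
        return PairRelation(PairCategory.SHARED_COMPARTMENT, i1.nearest_compartment)
    return PairRelation(PairCategory.OPPOSITE)
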