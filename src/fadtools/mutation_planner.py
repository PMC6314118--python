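"""From candidate sites to concrete mutagenesis plans.

The planning rule mirrors common practice for testing specificity
candidates by swapping residues between functional groups:

* if a group is conserved at a column but the query differs (categories ②
  and ④), the query is mutated *to that group's consensus*;
* if the query shares a group's consensus (categories ① and ③), it is
  mutated to the residue of a named representative of the *other* group
  (e.g. the archetypal Δ12 enzyme for an ω3-shared site), since the other
  group need not have a consensus at all.

Sites very close in sequence are merged into single mutagenesis units and
beneficial single mutations are stacked into multi-site variants with
canonical names like ``K36R/L153R/F157H``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from fadtools.family_io import GAP, GroupedAlignment, build_column_map
from fadtools.sdp_classifier import CandidateSite, Category

_MUTATION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")

DEFAULT_MERGE_WINDOW = 3


class PlanningError(ValueError):
    pass


@dataclass(frozen=True)
class Mutation:
    """A single amino-acid substitution in reference numbering."""

    wild_type: str
    position: int
    substitute: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if self.substitute == self.wild_type:
            raise ValueError(
                f"synonymous change {self.wild_type}{self.position}{self.substitute}"
            )
        for aa in (self.wild_type, self.substitute):
            if not (len(aa) == 1 and aa.isalpha() and aa.isupper()):
                raise ValueError(f"invalid residue {aa!r}")

    @property
    def name(self) -> str:
        return f"{self.wild_type}{self.position}{self.substitute}"

    @classmethod
    def from_name(cls, name: str) -> "Mutation":
        m = _MUTATION_RE.match(name.strip())
        if not m:
            raise ValueError(f"cannot parse mutation name {name!r}")
        wt, pos, sub = m.groups()
        return cls(wild_type=wt, position=int(pos), substitute=sub)

    def __str__(self) -> str:
        return self.name


@dataclass(frozen=True)
class Variant:
    """An ordered combination of point mutations (ascending position)."""

    mutations: tuple[Mutation, ...]

    def __post_init__(self) -> None:
        positions = [m.position for m in self.mutations]
        if len(set(positions)) != len(positions):
            raise ValueError(f"duplicate positions in variant: {positions}")
        if positions != sorted(positions):
            raise ValueError("mutations must be ordered by ascending position")

    @property
    def name(self) -> str:
        return "/".join(m.name for m in self.mutations)

    def __str__(self) -> str:
        return self.name

    def __len__(self) -> int:
        return len(self.mutations)


@dataclass(frozen=True)
class MutagenesisUnit:
    """Near-adjacent candidate positions handled as one construct."""

    positions: tuple[int, ...]
    mutations: tuple[Mutation, ...] = ()

    def __post_init__(self) -> None:
        if list(self.positions) != sorted(self.positions):
            raise ValueError("unit positions must be sorted")


def stack(mutations: Iterable[Mutation]) -> Variant:
    """Combine point mutations into one variant, canonically ordered."""
    ordered = sorted(mutations, key=lambda m: m.position)
    return Variant(mutations=tuple(ordered))


def parse_variant(name: str) -> Variant:
    """Parse a ``"K36R/L153R/F157H"``-style variant name."""
    return stack(Mutation.from_name(part) for part in name.split("/"))


def plan_substitution(
    site: CandidateSite,
    ga: GroupedAlignment,
    donor_delta12: str,
    donor_omega3: str,
) -> Mutation:
    """Choose the substitution for one candidate site.

    Categories ② and ④ take the conserved group's consensus as donor.
    Categories ① and ③ take the residue of the *other* group's named
    representative (``donor_omega3`` for ①, ``donor_delta12`` for ③) at the
    same column.  When a site carries two category flags the group-differs
    side (② or ④) wins, since its donor is a full-group consensus rather
    than a single representative.

    Raises
    ------
    PlanningError
        If the chosen donor has a gap at the column, or the donor equals
        the query residue (no substitution possible).
    """
    ga.validate_for_classification()
    (query_id,) = ga.group_ids("query")
    cmap = build_column_map(ga, query_id)
    col = cmap.column(site.ref_position)
    cats = site.categories

    donor_residue: str | None
    if Category.DELTA12_ONLY in cats:
        donor_residue = site.delta12_consensus
    elif Category.OMEGA3_ONLY in cats:
        donor_residue = site.omega3_consensus
    elif Category.QUERY_WITH_DELTA12 in cats:
        donor_residue = ga.aligned(donor_omega3)[col - 1]
    elif Category.QUERY_WITH_OMEGA3 in cats:
        donor_residue = ga.aligned(donor_delta12)[col - 1]
    else:  # pragma: no cover - CandidateSite guarantees a category
        raise PlanningError(f"site {site.ref_position}: no category to plan from")

    if donor_residue is None or donor_residue == GAP:
        raise PlanningError(
            f"site {site.ref_position}: donor has a gap at alignment column {col}"
        )
    if donor_residue == site.query_residue:
        raise PlanningError(
            f"site {site.ref_position}: donor residue {donor_residue} equals the "
            "query residue; no substitution to make"
        )
    return Mutation(
        wild_type=site.query_residue,
        position=site.ref_position,
        substitute=donor_residue,
    )


def manual_plan(residues: str, position: int, substitute: str) -> Mutation:
    """Plan a substitution chosen by hand (e.g. structure-motivated donors).

    Bypasses category rules entirely: the wild-type residue is read from the
    query protein string and the substitute is whatever the user names.
    """
    if not 1 <= position <= len(residues):
        raise PlanningError(f"position {position} outside sequence 1..{len(residues)}")
    return Mutation(
        wild_type=residues[position - 1], position=position, substitute=substitute
    )


def merge_adjacent(
    positions: Sequence[int], window: int = DEFAULT_MERGE_WINDOW
) -> list[MutagenesisUnit]:
    """Greedy left-to-right clustering of near-adjacent positions.

    Consecutive positions at most *window* residues apart share a unit, so
    e.g. 206/207/208 become one construct.  The units partition the input.
    """
    if list(positions) != sorted(positions):
        raise ValueError("positions must be sorted ascending")
    units: list[MutagenesisUnit] = []
    current: list[int] = []
    for pos in positions:
        if current and pos - current[-1] <= window:
            current.append(pos)
        else:
            if current:
                units.append(MutagenesisUnit(positions=tuple(current)))
            current = [pos]
    if current:
        units.append(MutagenesisUnit(positions=tuple(current)))
    return units


def apply_variant(residues: str, variant: Variant) -> str:
    """Apply a variant to a protein string, checking wild-type identity."""
    out = list(residues)
    for m in variant.mutations:
        if m.position > len(residues):
            raise PlanningError(
                f"{m.name}: position beyond sequence length {len(residues)}"
            )
        observed = out[m.position - 1]
        if observed != m.wild_type:
            raise PlanningError(
                f"{m.name}: expected wild-type {m.wild_type} at position "
                f"{m.position}, observed {observed}"
            )
        out[m.position - 1] = m.substitute
    return "".join(out)


def invert_variant(variant: Variant) -> Variant:
    """The variant undoing this one (swap wild-type and substitute)."""
    return stack(
        Mutation(wild_type=m.substitute, position=m.position, substitute=m.wild_type)
        for m in variant.mutations
    )
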