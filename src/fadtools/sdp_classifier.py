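"""Group-consensus classification of alignment columns.

The idea: align a bifunctional Δ12/ω3 desaturase (the *query*) with a group
of Δ12-desaturases and a group of ω3-desaturases.  At a column where one
functional group is conserved but the conserved residue differs between the
groups, the query's residue is potentially specificity-determining.  Each
such column falls into up to two of four categories, one per group side:

* ``①`` — Δ12 group conserved, query matches its consensus
* ``②`` — Δ12 group conserved, query differs
* ``③`` — ω3 group conserved, query matches its consensus
* ``④`` — ω3 group conserved, query differs

The two sides are evaluated independently, so one column can carry a flag
from each side (a column conserved in both groups at different residues is
both Δ12-classified and ω3-classified).  Columns conserved at the *same*
residue in both groups carry no signal and are never called.

A second, independent rule compares two paralogous query enzymes: columns
where the paralogs differ from each other *and* neither functional group is
conserved are "divergent sites", candidate explanations for the paralogs'
differing product profiles.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

from fadtools.family_io import GAP, ColumnMap, GroupedAlignment, build_column_map

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 1.0
DEFAULT_GAP_MAX = 0.25

#: Coarse physicochemical classes used by the optional property mode.
PROPERTY_CLASSES: dict[str, str] = {
    **{aa: "hydrophobic" for aa in "AVLIMC"},
    **{aa: "aromatic" for aa in "FWY"},
    **{aa: "polar" for aa in "STNQ"},
    **{aa: "positive" for aa in "KRH"},
    **{aa: "negative" for aa in "DE"},
    **{aa: "special" for aa in "GP"},
}


class Category(str, Enum):
    """Venn category of a candidate column (one flag per group side)."""

    QUERY_WITH_DELTA12 = "1"  # ① Δ12-conserved, query matches
    DELTA12_ONLY = "2"        # ② Δ12-conserved, query differs
    QUERY_WITH_OMEGA3 = "3"   # ③ ω3-conserved, query matches
    OMEGA3_ONLY = "4"         # ④ ω3-conserved, query differs

    def __str__(self) -> str:  # TSV-friendly
        return self.value


class ConsensusError(ValueError):
    pass


@dataclass(frozen=True)
class ColumnProfile:
    """Per-group residue content of one alignment column."""

    column: int  # 1-based alignment column
    delta12: tuple[str, ...]
    omega3: tuple[str, ...]
    query_residue: str
    delta12_consensus: str | None = None
    omega3_consensus: str | None = None


@dataclass(frozen=True)
class CandidateSite:
    """An alignment position nominated as specificity-determining."""

    ref_position: int  # query-sequence residue number (1-based)
    categories: frozenset[Category]
    query_residue: str
    delta12_consensus: str | None = None
    omega3_consensus: str | None = None

    def __post_init__(self) -> None:
        cats = self.categories
        if not cats:
            raise ValueError("candidate site must carry at least one category")
        if (
            Category.QUERY_WITH_DELTA12 in cats or Category.DELTA12_ONLY in cats
        ) and self.delta12_consensus is None:
            raise ValueError("delta12-side category requires a delta12 consensus")
        if (
            Category.QUERY_WITH_OMEGA3 in cats or Category.OMEGA3_ONLY in cats
        ) and self.omega3_consensus is None:
            raise ValueError("omega3-side category requires an omega3 consensus")
        if Category.QUERY_WITH_DELTA12 in cats and Category.DELTA12_ONLY in cats:
            raise ValueError("a site cannot both match and differ from delta12")
        if Category.QUERY_WITH_OMEGA3 in cats and Category.OMEGA3_ONLY in cats:
            raise ValueError("a site cannot both match and differ from omega3")


@dataclass(frozen=True)
class DivergentSite:
    """A column where two paralogous queries differ and no group is conserved."""

    ref_position: int  # numbering of the first query
    query1_residue: str
    query2_residue: str

    def __post_init__(self) -> None:
        if self.query1_residue == self.query2_residue:
            raise ValueError("divergent site requires differing residues")


def _consensus_token(residue: str, mode: str) -> str:
    if mode == "property":
        return PROPERTY_CLASSES.get(residue, "unknown")
    return residue


def group_consensus(
    residues: Iterable[str],
    threshold: float = DEFAULT_THRESHOLD,
    gap_max: float = DEFAULT_GAP_MAX,
    mode: str = "identity",
) -> str | None:
    """Consensus residue of one group's column, or None.

    Gaps are excluded from the denominator as long as the column's gap
    fraction is at most *gap_max*; gappier columns return no consensus.
    In ``property`` mode conservation is judged at the level of coarse
    physicochemical classes but the reported consensus is still the most
    frequent residue of the conserved class.

    Parameters
    ----------
    residues : iterable of str
        The group's residues at one column, gaps included.
    threshold : float in (0.5, 1.0]
        Minimum frequency among non-gap residues; 1.0 demands unanimity.
    """
    residues = list(residues)
    if not residues:
        raise ConsensusError("empty group")
    if not 0.5 < threshold <= 1.0:
        raise ConsensusError(f"threshold must be in (0.5, 1.0], got {threshold}")
    if mode not in ("identity", "property"):
        raise ConsensusError(f"unknown consensus mode {mode!r}")
    non_gap = [r for r in residues if r != GAP]
    if not non_gap:
        logger.info("all-gap column in group; no consensus")
        return None
    gap_fraction = 1.0 - len(non_gap) / len(residues)
    if gap_fraction > gap_max:
        return None
    tokens = Counter(_consensus_token(r, mode) for r in non_gap)
    token, count = tokens.most_common(1)[0]
    if token == "unknown" or count / len(non_gap) < threshold:
        return None
    if mode == "property":
        members = Counter(r for r in non_gap if PROPERTY_CLASSES.get(r) == token)
        return members.most_common(1)[0][0]
    return token


def column_profile(ga: GroupedAlignment, col: int, **consensus_kwargs) -> ColumnProfile:
    """Collect one column's per-group residues and consensuses."""
    ga.validate_for_classification()
    residues = ga.column(col)
    delta12 = tuple(residues[i] for i in ga.group_ids("delta12"))
    omega3 = tuple(residues[i] for i in ga.group_ids("omega3"))
    (query_id,) = ga.group_ids("query")
    return ColumnProfile(
        column=col,
        delta12=delta12,
        omega3=omega3,
        query_residue=residues[query_id],
        delta12_consensus=group_consensus(delta12, **consensus_kwargs),
        omega3_consensus=group_consensus(omega3, **consensus_kwargs),
    )


def classify_column(profile: ColumnProfile, mode: str = "identity") -> frozenset[Category]:
    """Venn categories of one column (possibly empty).

    A group side "fires" when that group has a consensus that differs from
    the other group's situation: either the other group has no consensus, or
    its consensus differs.  Query-vs-consensus comparison is by residue
    identity in both modes.  Query-gap columns are skipped (empty result,
    logged).
    """
    q = profile.query_residue
    if q == GAP:
        logger.info("column %d: query residue is a gap; skipped", profile.column)
        return frozenset()
    d = profile.delta12_consensus
    w = profile.omega3_consensus

    def differs(a: str | None, b: str | None) -> bool:
        if a is None or b is None:
            return True
        if mode == "property":
            return PROPERTY_CLASSES.get(a) != PROPERTY_CLASSES.get(b)
        return a != b

    cats: set[Category] = set()
    if d is not None and differs(d, w):
        cats.add(
            Category.QUERY_WITH_DELTA12 if q == d else Category.DELTA12_ONLY
        )
    if w is not None and differs(w, d):
        cats.add(
            Category.QUERY_WITH_OMEGA3 if q == w else Category.OMEGA3_ONLY
        )
    return frozenset(cats)


def scan_candidates(
    ga: GroupedAlignment,
    threshold: float = DEFAULT_THRESHOLD,
    gap_max: float = DEFAULT_GAP_MAX,
    mode: str = "identity",
) -> list[CandidateSite]:
    """Scan every column and return candidate sites in query numbering.

    One :class:`CandidateSite` per unique reference position, sorted
    ascending, each carrying every category flag its column earned.
    Adjacent positions are *not* merged here; that is the mutation planner's
    concern.
    """
    ga.validate_for_classification()
    (query_id,) = ga.group_ids("query")
    cmap = build_column_map(ga, query_id)
    sites: list[CandidateSite] = []
    for col in range(1, ga.length + 1):
        profile = column_profile(
            ga, col, threshold=threshold, gap_max=gap_max, mode=mode
        )
        cats = classify_column(profile, mode=mode)
        if not cats:
            continue
        ref_position = cmap.residue_number(col)
        if ref_position is None:  # query gap; classify_column already skipped
            continue
        sites.append(
            CandidateSite(
                ref_position=ref_position,
                categories=cats,
                query_residue=profile.query_residue,
                delta12_consensus=profile.delta12_consensus,
                omega3_consensus=profile.omega3_consensus,
            )
        )
    sites.sort(key=lambda s: s.ref_position)
    return sites


def divergent_sites(
    ga: GroupedAlignment,
    query1_id: str,
    query2_id: str,
    threshold: float = DEFAULT_THRESHOLD,
    gap_max: float = DEFAULT_GAP_MAX,
) -> list[DivergentSite]:
    """Columns where two paralogs differ and neither group is conserved.

    Positions are reported in *query1*'s residue numbering; columns where
    either paralog has a gap are skipped.
    """
    if query1_id == query2_id:
        raise ValueError("query1_id and query2_id must name different rows")
    aligned1 = ga.aligned(query1_id)
    aligned2 = ga.aligned(query2_id)
    cmap = build_column_map(ga, query1_id)
    for group in ("delta12", "omega3"):
        if not ga.group_ids(group):
            raise ValueError(f"divergence scan needs at least one {group} row")
    sites: list[DivergentSite] = []
    for col in range(1, ga.length + 1):
        r1, r2 = aligned1[col - 1], aligned2[col - 1]
        if GAP in (r1, r2) or r1 == r2:
            continue
        residues = ga.column(col)
        d = group_consensus(
            [residues[i] for i in ga.group_ids("delta12")],
            threshold=threshold, gap_max=gap_max,
        )
        w = group_consensus(
            [residues[i] for i in ga.group_ids("omega3")],
            threshold=threshold, gap_max=gap_max,
        )
        if d is None and w is None:
            sites.append(
                DivergentSite(
                    ref_position=cmap.residue_number(col),
                    query1_residue=r1,
                    query2_residue=r2,
                )
            )
    return sites
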