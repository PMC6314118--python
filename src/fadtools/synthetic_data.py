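"""Seeded synthetic inputs with planted ground truth.

Every stage of the pipeline can be exercised offline against data whose
correct answer is known by construction:

* :func:`simulate_family` builds a grouped alignment in which chosen
  columns carry a planted conservation pattern (category ①–④) while every
  background column is deliberately *balanced* within each group so it can
  never reach consensus;
* :func:`simulate_structure` writes a toy PDB model with an iron atom at
  the origin and residues placed at exact, user-chosen distances;
* :func:`simulate_peaks` emulates the GC-FAME measurement model
  (fixed-mass 17:0 internal standard, triplicate cultures, multiplicative
  log-normal noise) by inverting the quantification formula.

All generators take an explicit seed and are deterministic: the same spec
reproduces byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from fadtools.family_io import GAP, GroupedAlignment, build_column_map
from fadtools.mutation_planner import Mutation, apply_variant, stack
from fadtools.phenotype_analysis import ISTD_MASS_UG, PeakTable
from fadtools.sdp_classifier import CandidateSite, Category
from fadtools.structure_shell import Atom, StructureModel, write_structure

#: disjoint within-group residue pools for background (never-conserved) columns
DELTA12_POOL = "ILMV"
OMEGA3_POOL = "STQN"
QUERY_POOL = "GAEDK"

NOMINAL_ISTD_AREA = 10_000.0


class SimSpecError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedSite:
    """One alignment column with a designed conservation pattern.

    ``delta12`` / ``omega3`` give a single residue when that group is to be
    unanimously conserved, or None for a deliberately mixed (uncallable)
    column on that side.  The declared *category* must be among the
    categories the pattern actually produces.
    """

    column: int
    category: Category
    query: str
    delta12: str | None = None
    omega3: str | None = None

    def expected_categories(self) -> frozenset[Category]:
        d, w, q = self.delta12, self.omega3, self.query
        if d is not None and w is not None and d == w:
            raise SimSpecError(
                f"column {self.column}: both groups conserved at {d}; no "
                "between-group difference exists for any category"
            )
        cats: set[Category] = set()
        if d is not None:
            cats.add(
                Category.QUERY_WITH_DELTA12 if q == d else Category.DELTA12_ONLY
            )
        if w is not None:
            cats.add(
                Category.QUERY_WITH_OMEGA3 if q == w else Category.OMEGA3_ONLY
            )
        if not cats:
            raise SimSpecError(
                f"column {self.column}: no group is conserved; nothing planted"
            )
        if self.category not in cats:
            raise SimSpecError(
                f"column {self.column}: declared category {self.category} is not "
                f"produced by the planted pattern (produces {sorted(c.value for c in cats)})"
            )
        return frozenset(cats)


@dataclass(frozen=True)
class FamilySimSpec:
    """Parameters of a synthetic desaturase family alignment."""

    seed: int
    n_delta12: int = 4
    n_omega3: int = 4
    length: int = 400
    planted: tuple[PlantedSite, ...] = ()
    divergent: tuple[tuple[int, str, str], ...] = ()  # (column, q1, q2)
    include_paralog: bool = False
    indel_rate: float = 0.02
    gap_cap: float = 0.25

    def __post_init__(self) -> None:
        if self.n_delta12 < 2 or self.n_omega3 < 2:
            raise SimSpecError("each group needs >= 2 sequences")
        cols = [p.column for p in self.planted] + [c for c, _, _ in self.divergent]
        if len(set(cols)) != len(cols):
            raise SimSpecError("planted/divergent columns must be distinct")
        for p in self.planted:
            if not 1 <= p.column <= self.length:
                raise SimSpecError(f"planted column {p.column} outside 1..{self.length}")
            p.expected_categories()  # validates pattern feasibility
        for col, q1, q2 in self.divergent:
            if q1 == q2:
                raise SimSpecError(f"divergent column {col}: residues must differ")
        if not 0 <= self.indel_rate < 1:
            raise SimSpecError("indel rate must be in [0, 1)")


@dataclass
class SimTruth:
    """Ground truth of a simulated family."""

    sites: list[CandidateSite]              # expected scan_candidates output
    sequences: dict[str, str]               # id -> ungapped residues
    expected_mutations: dict[int, Mutation]  # ref position -> planned mutation
    mutant_sequences: dict[str, str]        # variant name -> mutated query
    divergent_positions: list[int] = field(default_factory=list)


def _balanced_pair(rng: np.random.Generator, pool: str, size: int) -> list[str]:
    """A shuffled, maximally balanced column from two distinct pool residues.

    With two residues split as evenly as possible, the majority frequency is
    ceil(size/2)/size (0.5 for even group sizes), so the column can never be
    called at any consensus threshold above that.
    """
    a, b = rng.choice(list(pool), size=2, replace=False)
    column = [a] * (size // 2) + [b] * (size - size // 2)
    rng.shuffle(column)
    return list(column)


def simulate_family(spec: FamilySimSpec) -> tuple[GroupedAlignment, SimTruth]:
    """Generate a grouped alignment with planted, recoverable signal columns.

    Background columns are balanced within each group (no consensus at any
    threshold > 0.5 + gap effects); planted columns are unanimous per their
    pattern and never gapped.  Gaps are injected only at background columns
    at ``indel_rate``, capped per group-column at ``floor(gap_cap × group
    size)`` so that gap removal can never create an accidental unanimity in
    a balanced column.

    Returns the alignment together with a :class:`SimTruth` holding the
    expected candidate sites, substitution plans (donor = first row of the
    other group) and mutant query sequences.
    """
    rng = np.random.default_rng(spec.seed)
    d12_ids = [f"d12_{i+1}" for i in range(spec.n_delta12)]
    w3_ids = [f"w3_{i+1}" for i in range(spec.n_omega3)]
    ids = d12_ids + w3_ids + ["query"]
    groups = {i: "delta12" for i in d12_ids}
    groups.update({i: "omega3" for i in w3_ids})
    groups["query"] = "query"
    if spec.include_paralog or spec.divergent:
        ids.append("query2")
        groups["query2"] = "other"

    planted_by_col = {p.column: p for p in spec.planted}
    divergent_by_col = {c: (q1, q2) for c, q1, q2 in spec.divergent}

    columns: dict[str, list[str]] = {i: [] for i in ids}
    max_gaps = {
        "delta12": int(spec.gap_cap * spec.n_delta12),
        "omega3": int(spec.gap_cap * spec.n_omega3),
    }

    for col in range(1, spec.length + 1):
        planted = planted_by_col.get(col)
        divergent = divergent_by_col.get(col)
        if planted is not None:
            d12_col = (
                [planted.delta12] * spec.n_delta12
                if planted.delta12 is not None
                else _balanced_pair(rng, DELTA12_POOL, spec.n_delta12)
            )
            w3_col = (
                [planted.omega3] * spec.n_omega3
                if planted.omega3 is not None
                else _balanced_pair(rng, OMEGA3_POOL, spec.n_omega3)
            )
            q1 = q2 = planted.query
        else:
            d12_col = _balanced_pair(rng, DELTA12_POOL, spec.n_delta12)
            w3_col = _balanced_pair(rng, OMEGA3_POOL, spec.n_omega3)
            if divergent is not None:
                q1, q2 = divergent
            else:
                q1 = q2 = str(rng.choice(list(QUERY_POOL)))
        signal = planted is not None or divergent is not None
        if not signal and spec.indel_rate > 0:
            for group_col, group in ((d12_col, "delta12"), (w3_col, "omega3")):
                gaps = 0
                for i in range(len(group_col)):
                    if gaps >= max_gaps[group] :
                        break
                    if rng.random() < spec.indel_rate:
                        group_col[i] = GAP
                        gaps += 1
            if rng.random() < spec.indel_rate:
                q1 = GAP
        for i, seq_id in enumerate(d12_ids):
            columns[seq_id].append(d12_col[i])
        for i, seq_id in enumerate(w3_ids):
            columns[seq_id].append(w3_col[i])
        columns["query"].append(q1)
        if "query2" in columns:
            columns["query2"].append(q2 if q1 != GAP else GAP)

    rows = [(seq_id, "".join(columns[seq_id])) for seq_id in ids]
    ga = GroupedAlignment(rows=rows, groups=groups, reference_id="query")
    cmap = build_column_map(ga, "query")

    sites: list[CandidateSite] = []
    expected_mutations: dict[int, Mutation] = {}
    donor_d12, donor_w3 = d12_ids[0], w3_ids[0]
    for p in sorted(spec.planted, key=lambda p: p.column):
        ref = cmap.residue_number(p.column)
        assert ref is not None  # planted columns are never query-gapped
        cats = p.expected_categories()
        sites.append(
            CandidateSite(
                ref_position=ref,
                categories=cats,
                query_residue=p.query,
                delta12_consensus=p.delta12,
                omega3_consensus=p.omega3,
            )
        )
        if Category.DELTA12_ONLY in cats:
            sub = p.delta12
        elif Category.OMEGA3_ONLY in cats:
            sub = p.omega3
        elif Category.QUERY_WITH_DELTA12 in cats:
            sub = ga.aligned(donor_w3)[p.column - 1]
        else:
            sub = ga.aligned(donor_d12)[p.column - 1]
        if sub != GAP and sub != p.query:
            expected_mutations[ref] = Mutation(
                wild_type=p.query, position=ref, substitute=sub
            )

    query_residues = ga.records["query"].residues
    mutant_sequences = {
        m.name: apply_variant(query_residues, stack([m]))
        for m in expected_mutations.values()
    }
    if len(expected_mutations) > 1:
        combined = stack(expected_mutations.values())
        mutant_sequences[combined.name] = apply_variant(query_residues, combined)

    truth = SimTruth(
        sites=sites,
        sequences={i: ga.records[i].residues for i in ids},
        expected_mutations=expected_mutations,
        mutant_sequences=mutant_sequences,
        divergent_positions=sorted(
            cmap.residue_number(c) for c in divergent_by_col
        ),
    )
    return ga, truth


def default_family_spec(seed: int, length: int = 400) -> FamilySimSpec:
    """A 2×4-sequence family with 12 planted sites, three per category.

    Planted conserved residues are drawn outside the background pools so
    that representative-donor substitutions are always well defined.
    """
    rng = np.random.default_rng(seed)
    columns = sorted(
        rng.choice(np.arange(10, length - 10), size=12, replace=False).tolist()
    )
    plans = [
        # (category, delta12, omega3, query)
        (Category.QUERY_WITH_DELTA12, "W", None, "W"),
        (Category.QUERY_WITH_DELTA12, "F", None, "F"),
        (Category.QUERY_WITH_DELTA12, "H", None, "H"),
        (Category.DELTA12_ONLY, "R", None, "K"),
        (Category.DELTA12_ONLY, "Y", None, "F"),
        (Category.DELTA12_ONLY, "C", None, "G"),
        (Category.QUERY_WITH_OMEGA3, None, "H", "H"),
        (Category.QUERY_WITH_OMEGA3, None, "Y", "Y"),
        (Category.QUERY_WITH_OMEGA3, None, "W", "W"),
        (Category.OMEGA3_ONLY, None, "R", "K"),
        (Category.OMEGA3_ONLY, None, "F", "E"),
        (Category.OMEGA3_ONLY, None, "P", "A"),
    ]
    planted = tuple(
        PlantedSite(column=col, category=cat, delta12=d, omega3=w, query=q)
        for col, (cat, d, w, q) in zip(columns, plans)
    )
    return FamilySimSpec(seed=seed, planted=planted, length=length)


# ---------------------------------------------------------------------------
# toy metal-site structures
# ---------------------------------------------------------------------------

_AXES = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=float,
)


def simulate_structure_model(
    layout: Sequence[tuple[str, int, float]],
    seed: int = 0,
    metal_element: str = "FE",
) -> StructureModel:
    """Toy model: one metal at the origin, one CA atom per layout residue.

    Each ``(residue name, residue number, distance Å)`` entry places a
    single atom at exactly that distance along a randomly chosen coordinate
    axis, so distances survive the 3-decimal PDB coordinate format exactly
    (round the distances to 3 decimals to make that airtight).
    """
    rng = np.random.default_rng(seed)
    numbers = [num for _, num, _ in layout]
    if len(set(numbers)) != len(numbers):
        raise SimSpecError(f"duplicate residue numbers in layout: {numbers}")
    atoms = [
        Atom(
            chain="A",
            res_number=9999,
            insertion_code="",
            res_name=metal_element,
            atom_name=metal_element,
            element=metal_element,
            x=0.0,
            y=0.0,
            z=0.0,
        )
    ]
    for res_name, res_number, distance in layout:
        if distance < 0:
            raise SimSpecError(f"residue {res_number}: negative distance {distance}")
        axis = _AXES[rng.integers(len(_AXES))]
        pos = axis * distance
        atoms.append(
            Atom(
                chain="A",
                res_number=res_number,
                insertion_code="",
                res_name=res_name,
                atom_name="CA",
                element="C",
                x=float(pos[0]),
                y=float(pos[1]),
                z=float(pos[2]),
            )
        )
    metal_indices = [0]
    return StructureModel(atoms=atoms, metal_indices=metal_indices)


def simulate_structure(
    layout: Sequence[tuple[str, int, float]],
    path=None,
    seed: int = 0,
    metal_element: str = "FE",
) -> str:
    """PDB-format text for a toy metal-site model (see
    :func:`simulate_structure_model`).  If *path* is given the text is also
    written there.
    """
    import io
    import os
    import tempfile

    model = simulate_structure_model(layout, seed=seed, metal_element=metal_element)
    if path is not None:
        write_structure(model, path)
        with open(path) as fh:
            return fh.read()
    fd, tmp = tempfile.mkstemp(suffix=".pdb")
    os.close(fd)
    try:
        write_structure(model, tmp)
        with open(tmp) as fh:
            return fh.read()
    finally:
        os.unlink(tmp)


# ---------------------------------------------------------------------------
# GC-FAME peak tables
# ---------------------------------------------------------------------------

def simulate_peaks(
    truth: Mapping[str, tuple[float, Mapping[str, float]]],
    noise_sigma: float = 0.05,
    seed: int = 0,
    n_replicates: int = 3,
    istd_area: float = NOMINAL_ISTD_AREA,
) -> list[PeakTable]:
    """Peak tables whose quantification recovers the given true yields.

    *truth* maps sample id to ``(A600, {species shorthand: μg/A600})``.
    Areas invert the quantification formula,
    ``area = yield × A600 / ISTD mass × area(ISTD)``, then each replicate's
    species areas get independent multiplicative log-normal noise of
    geometric σ *noise_sigma* (σ=0 reproduces the truth exactly).  Three
    replicates per sample by default, ids ``<sample>_r1`` …
    """
    if noise_sigma < 0:
        raise SimSpecError(f"noise sigma must be >= 0, got {noise_sigma}")
    rng = np.random.default_rng(seed)
    tables: list[PeakTable] = []
    for sample_id, (a600, yields) in truth.items():
        if any(y < 0 for y in yields.values()):
            raise SimSpecError(f"{sample_id}: negative true yield")
        for rep in range(1, n_replicates + 1):
            peaks = {}
            for species, true_yield in yields.items():
                area = true_yield * a600 / ISTD_MASS_UG * istd_area
                if noise_sigma > 0:
                    area *= float(rng.lognormal(mean=0.0, sigma=noise_sigma))
                peaks[species] = area
            tables.append(
                PeakTable(
                    sample_id=f"{sample_id}_r{rep}",
                    a600=a600,
                    peaks=peaks,
                    istd_area=istd_area,
                )
            )
    return tables


def fm1_demo_truth() -> dict[str, tuple[float, dict[str, float]]]:
    """The shipped demo parameterization of a bifunctional desaturase assay.

    A reference enzyme producing ALA/(ALA+LA) = 0.86 at 20 μg/A600 total
    product, an activity-enhanced variant (2.5× reference, same ratio), a
    specificity-reversed variant (ALA fraction 0.06), a reduced-activity
    ratio-shifted variant (0.4), a dead variant, and an empty-vector
    control.  These are narrative parameter choices for the tutorial, not
    wet-lab measurements.
    """

    def sample(total: float, fraction: float) -> dict[str, float]:
        return {
            "16:0": 30.0,
            "18:0": 12.0,
            "18:1Δ9": 25.0,
            "18:2Δ9,12": total * (1 - fraction),
            "18:3Δ9,12,15": total * fraction,
        }

    return {
        "Fm1": (1.0, sample(20.0, 0.86)),
        "enhanced": (1.0, sample(50.0, 0.86)),
        "specificity_reversed": (1.0, sample(36.0, 0.06)),
        "ratio_shifted": (1.0, sample(10.0, 0.40)),
        "dead": (1.0, sample(0.0, 0.0)),
        "EV": (1.0, sample(0.0, 0.0)),
    }
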