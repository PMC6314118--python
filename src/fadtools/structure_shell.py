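"""His-box motifs and metal-coordination shells of a desaturase model.

Membrane desaturases ligate their catalytic di-iron center with histidines
arranged in conserved sequence motifs ("His boxes", HxxxH and HxxHH).  Given
a PDB-format structural model with the metal ions present, this module finds
the boxes in sequence, reads the model (through gemmi), and lists every
residue with an atom inside a distance shell around the metals — the
screen used to nominate active-site-proximal residues beyond the obligatory
histidine ligands.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

#: element symbols flagged as catalytic metals unless overridden
DEFAULT_METALS = frozenset({"FE", "ZN", "MN", "CU"})

# A window whose fourth residue is His is the three-His box HxxHH and is not
# double-reported as HxxxH, hence the [^H] in the two-His pattern.
_HIS_BOX_PATTERNS = {
    "HxxxH": re.compile(r"(?=(H.{2}[^H]H))"),
    "HxxHH": re.compile(r"(?=(H.{2}HH))"),
}


class StructureError(ValueError):
    pass


@dataclass(frozen=True)
class HisBox:
    """One histidine box occurrence in a protein sequence (1-based)."""

    motif: str  # "HxxxH" or "HxxHH"
    start: int
    his_positions: tuple[int, ...]


def find_his_boxes(residues: str) -> list[HisBox]:
    """All HxxxH and HxxHH motif occurrences, overlapping ones included.

    Returns boxes sorted by start position.  An empty result is valid (not
    every sequence has the boxes).
    """
    if not residues:
        raise ValueError("empty protein string")
    residues = residues.upper()
    boxes: list[HisBox] = []
    for motif, pattern in _HIS_BOX_PATTERNS.items():
        for m in pattern.finditer(residues):
            start = m.start() + 1
            if motif == "HxxxH":
                his = (start, start + 4)
            else:
                his = (start, start + 3, start + 4)
            boxes.append(HisBox(motif=motif, start=start, his_positions=his))
    boxes.sort(key=lambda b: (b.start, b.motif))
    return boxes


def his_box_positions(boxes: Iterable[HisBox], extra: Iterable[int] = ()) -> set[int]:
    """Union of all His positions of the given boxes plus *extra* ligands.

    *extra* accommodates lone metal-ligating histidines that sit outside any
    box motif (a common arrangement: three boxes plus one separate His).
    """
    positions: set[int] = set(extra)
    for box in boxes:
        positions.update(box.his_positions)
    return positions


@dataclass(frozen=True)
class Atom:
    chain: str
    res_number: int
    insertion_code: str
    res_name: str
    atom_name: str
    element: str
    x: float
    y: float
    z: float

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain, self.res_number, self.insertion_code)


@dataclass
class StructureModel:
    """Flat atom list of a structural model with its metal atoms flagged."""

    atoms: list[Atom]
    metal_indices: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        coords = self.coordinates
        if coords.size and not np.isfinite(coords).all():
            raise StructureError("non-finite atom coordinates")

    @property
    def coordinates(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)

    def metal_atoms(self) -> list[Atom]:
        return [self.atoms[i] for i in self.metal_indices]

    def select_metals(self, elements: Iterable[str]) -> "StructureModel":
        """Return a copy with the metal flag restricted to *elements*."""
        wanted = {e.upper() for e in elements}
        indices = [i for i, a in enumerate(self.atoms) if a.element in wanted]
        return StructureModel(atoms=self.atoms, metal_indices=indices)


def _highest_occupancy_atoms(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Resolve altlocs: keep the highest-occupancy conformer per atom name."""
    best: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            best[atom.name] = atom
    return list(best.values())


def read_structure(
    path: str | Path, metals: Iterable[str] = DEFAULT_METALS
) -> StructureModel:
    """Read a PDB-format file into a flat atom list.

    Only the first model of a multi-model file is used.  Atoms whose element
    symbol is in *metals* are flagged as catalytic metals; pass a different
    set (or use :meth:`StructureModel.select_metals`) to override.
    """
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"{path}: {exc}") from exc
    atoms: list[Atom] = []
    if len(st) == 0:
        raise StructureError(f"{path}: no models in file")
    model = st[0]
    for chain in model:
        for residue in chain:
            for atom in _highest_occupancy_atoms(residue):
                atoms.append(
                    Atom(
                        chain=chain.name,
                        res_number=residue.seqid.num,
                        insertion_code=(residue.seqid.icode or " ").strip() or "",
                        res_name=residue.name,
                        atom_name=atom.name,
                        element=atom.element.name.upper(),
                        x=atom.pos.x,
                        y=atom.pos.y,
                        z=atom.pos.z,
                    )
                )
    if not atoms:
        raise StructureError(f"{path}: no ATOM/HETATM records parsed")
    wanted = {e.upper() for e in metals}
    metal_indices = [i for i, a in enumerate(atoms) if a.element in wanted]
    return StructureModel(atoms=atoms, metal_indices=metal_indices)


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write the model back out as a PDB file (via gemmi, fixed columns)."""
    st = gemmi.Structure()
    st.name = "model"
    gm = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for atom in model.atoms:
        chain = chains.get(atom.chain)
        if chain is None:
            chain = gemmi.Chain(atom.chain)
            chains[atom.chain] = chain
        seqid = gemmi.SeqId(atom.res_number, atom.insertion_code or " ")
        residue = None
        if len(chain) > 0:
            last = chain[len(chain) - 1]
            if last.seqid == seqid and last.name == atom.res_name:
                residue = last
        if residue is None:
            residue = gemmi.Residue()
            residue.name = atom.res_name
            residue.seqid = seqid
            residue.het_flag = "H" if atom.element in DEFAULT_METALS else "A"
            chain.add_residue(residue)
            residue = chain[len(chain) - 1]
        ga = gemmi.Atom()
        ga.name = atom.atom_name
        ga.element = gemmi.Element(atom.element)
        ga.pos = gemmi.Position(atom.x, atom.y, atom.z)
        ga.occ = 1.0
        residue.add_atom(ga)
    for chain in chains.values():
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


@dataclass(frozen=True)
class ShellResidue:
    """A residue with at least one atom inside the metal shell."""

    chain: str
    res_number: int
    insertion_code: str
    res_name: str
    min_distance: float  # Å to the nearest selected metal atom
    is_metal_ligand_his: bool = False


def shell_residues(
    model: StructureModel,
    radius: float = 5.0,
    metal_selection: Iterable[str] | None = None,
    ligand_his: Iterable[int] | None = None,
) -> list[ShellResidue]:
    """Residues with any atom within *radius* Å of any selected metal atom.

    Distances are Euclidean, atom-to-atom, taken over *all* atoms of a
    residue (the inclusive reading of a "within r Å of the metals" screen).
    The metal atoms themselves are excluded from the listing.  Results are
    sorted by ascending minimum distance.

    Parameters
    ----------
    radius : float
        Shell radius in Å (default 5.0).
    metal_selection : iterable of str, optional
        Element symbols to use as shell centers; defaults to the model's
        flagged metals.
    ligand_his : iterable of int, optional
        Residue numbers of known metal-ligating histidines (e.g. from
        :func:`find_his_boxes` via :func:`his_box_positions`).  When given,
        a HIS residue is flagged only if its number is in this set;
        otherwise every HIS in the shell is flagged.
    """
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    if metal_selection is not None:
        model = model.select_metals(metal_selection)
    metals = model.metal_atoms()
    if not metals:
        raise StructureError("no metal atoms selected for shell analysis")
    metal_idx = set(model.metal_indices)
    other = [(i, a) for i, a in enumerate(model.atoms) if i not in metal_idx]
    if not other:
        return []
    coords = np.array([[a.x, a.y, a.z] for _, a in other])
    metal_coords = np.array([[m.x, m.y, m.z] for m in metals])
    # min distance from each non-metal atom to its nearest metal
    dmin, _ = cKDTree(metal_coords).query(coords, k=1)
    per_residue: dict[tuple[str, int, str], tuple[float, Atom]] = {}
    for (_, atom), d in zip(other, dmin):
        if d > radius:
            continue
        key = atom.residue_key
        if key not in per_residue or d < per_residue[key][0]:
            per_residue[key] = (float(d), atom)
    his_set = set(ligand_his) if ligand_his is not None else None
    result = []
    for (chain, num, icode), (d, atom) in per_residue.items():
        is_his = atom.res_name.upper() == "HIS"
        flagged = is_his and (his_set is None or num in his_set)
        result.append(
            ShellResidue(
                chain=chain,
                res_number=num,
                insertion_code=icode,
                res_name=atom.res_name,
                min_distance=d,
                is_metal_ligand_his=flagged,
            )
        )
    result.sort(key=lambda r: r.min_distance)
    return result


@dataclass(frozen=True)
class NumberingMap:
    """Shift between model residue numbering and sequence numbering."""

    offset: int  # sequence position = model residue number + offset
    mapped: dict[int, int]  # model residue number -> sequence position
    mismatches: tuple[tuple[int, str, str], ...]  # (model resnum, model aa, seq aa)

    def sequence_position(self, model_res_number: int) -> int:
        return self.mapped[model_res_number]


def _one_letter(res_name: str) -> str:
    info = gemmi.find_tabulated_residue(res_name)
    if info is None:
        return "X"
    code = info.one_letter_code.upper()
    return code if code.isalpha() else "X"


def map_model_to_sequence(
    model: StructureModel,
    residues: str,
    offset: int | None = None,
    max_mismatch_fraction: float = 0.05,
) -> NumberingMap:
    """Align the model's residue numbering to a reference protein string.

    When *offset* is None the shift maximizing residue-name agreement over
    offsets in [-5, +5] is detected.  Residues whose model name disagrees
    with the sequence letter are reported; more than
    *max_mismatch_fraction* mismatches raises, advising renumbering.
    """
    seen: dict[int, str] = {}
    for atom in model.atoms:
        if atom.element in DEFAULT_METALS:
            continue
        seen.setdefault(atom.res_number, _one_letter(atom.res_name))
    if not seen:
        raise StructureError("model has no polymer residues to map")

    def score(off: int) -> int:
        return sum(
            1
            for num, aa in seen.items()
            if 1 <= num + off <= len(residues) and residues[num + off - 1] == aa
        )

    if offset is None:
        offset = max(range(-5, 6), key=score)
    mapped: dict[int, int] = {}
    mismatches: list[tuple[int, str, str]] = []
    for num, aa in sorted(seen.items()):
        pos = num + offset
        if not 1 <= pos <= len(residues):
            mismatches.append((num, aa, "-"))
            continue
        mapped[num] = pos
        if residues[pos - 1] != aa:
            mismatches.append((num, aa, residues[pos - 1]))
    if len(mismatches) / len(seen) > max_mismatch_fraction:
        raise StructureError(
            f"{len(mismatches)}/{len(seen)} residue-name mismatches at offset "
            f"{offset}; renumber the model to match the sequence"
        )
    return NumberingMap(offset=offset, mapped=mapped, mismatches=tuple(mismatches))
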