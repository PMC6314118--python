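"""Grouped sequence alignments and reference-residue numbering.

A desaturase family analysis starts from a multiple sequence alignment in
which every row carries a functional group label: ``delta12`` (oleate /
Δ12-desaturases), ``omega3`` (linoleate / ω3-desaturases), ``query`` (the
bifunctional enzyme under study) or ``other``.  This module reads and writes
such alignments (FASTA or Clustal, via Biopython), validates them, and keeps
the bijection between alignment columns and ungapped residue numbers of any
row so that downstream results are always reported in the query enzyme's
own 1-based numbering (e.g. "Phe157").
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

GROUPS = ("delta12", "omega3", "query", "other")
GAP = "-"
#: 20 standard residues plus X for an unknown residue.
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

CANDIDATE_HEADER = (
    "ref_position",
    "categories",
    "query_residue",
    "delta12_consensus",
    "omega3_consensus",
)


class AlignmentFormatError(ValueError):
    """Raised for unparseable or internally inconsistent alignment input."""


class GroupLabelError(ValueError):
    """Raised when group labels and alignment rows do not match up."""


@dataclass(frozen=True)
class SequenceRecord:
    """One ungapped protein sequence with its functional group label."""

    id: str
    residues: str
    group: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"{self.id}: empty sequence")
        if self.group not in GROUPS:
            raise GroupLabelError(
                f"{self.id}: unknown group {self.group!r}; expected one of {GROUPS}"
            )
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            raise AlignmentFormatError(
                f"{self.id}: invalid residue letter(s) {sorted(bad)}; only the 20 "
                "standard amino acids plus X are accepted"
            )

    def __len__(self) -> int:
        return len(self.residues)


def _normalize(aligned: str) -> str:
    """Upper-case and normalize '.' gaps to '-'."""
    if "." in aligned:
        logger.info("normalizing '.' gap characters to '-'")
        aligned = aligned.replace(".", GAP)
    return aligned.upper()


def degap(aligned: str) -> str:
    """Remove gap characters from an aligned string."""
    return aligned.replace(GAP, "")


@dataclass
class GroupedAlignment:
    """A multiple sequence alignment whose rows carry functional group labels.

    Parameters
    ----------
    rows : list of (str, str)
        ``(sequence id, aligned string)`` pairs in file order.  All aligned
        strings must have equal length; the only gap character is ``-``.
    groups : mapping of str to str
        Group label per sequence id.
    reference_id : str, optional
        Id of the query-role row used for reference numbering.  Defaults to
        the unique row labeled ``query`` if there is exactly one.
    """

    rows: list[tuple[str, str]]
    groups: dict[str, str]
    reference_id: str | None = None
    records: dict[str, SequenceRecord] = field(init=False)

    def __post_init__(self) -> None:
        if not self.rows:
            raise AlignmentFormatError("alignment has no rows")
        length = len(self.rows[0][1])
        if length < 1:
            raise AlignmentFormatError("alignment length must be >= 1")
        seen: set[str] = set()
        normalized = []
        for seq_id, aligned in self.rows:
            aligned = _normalize(aligned)
            if seq_id in seen:
                raise AlignmentFormatError(f"duplicate sequence id {seq_id!r}")
            seen.add(seq_id)
            if len(aligned) != length:
                raise AlignmentFormatError(
                    f"ragged alignment: row {seq_id!r} has length {len(aligned)}, "
                    f"expected {length}"
                )
            if seq_id not in self.groups:
                raise GroupLabelError(f"no group label for sequence {seq_id!r}")
            normalized.append((seq_id, aligned))
        self.rows = normalized
        unknown = set(self.groups) - seen
        if unknown:
            raise GroupLabelError(
                f"group table names unknown sequence id(s): {sorted(unknown)}"
            )
        self.records = {
            seq_id: SequenceRecord(
                id=seq_id, residues=degap(aligned), group=self.groups[seq_id]
            )
            for seq_id, aligned in self.rows
        }
        if self.reference_id is None:
            queries = [i for i, g in self.groups.items() if g == "query"]
            if len(queries) == 1:
                self.reference_id = queries[0]
        if self.reference_id is not None and self.reference_id not in seen:
            raise GroupLabelError(
                f"reference id {self.reference_id!r} is not a row of the alignment"
            )

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return len(self.rows[0][1])

    def ids(self) -> list[str]:
        return [seq_id for seq_id, _ in self.rows]

    def aligned(self, seq_id: str) -> str:
        for sid, aligned in self.rows:
            if sid == seq_id:
                return aligned
        raise KeyError(f"no row with id {seq_id!r}")

    def group_ids(self, group: str) -> list[str]:
        """Row ids belonging to a functional group, in row order."""
        return [sid for sid, _ in self.rows if self.groups[sid] == group]

    def column(self, col: int) -> dict[str, str]:
        """Residues (or gaps) of 1-based column *col*, keyed by sequence id."""
        if not 1 <= col <= self.length:
            raise IndexError(f"column {col} out of range 1..{self.length}")
        return {sid: aligned[col - 1] for sid, aligned in self.rows}

    def validate_for_classification(self) -> None:
        """Require >=1 delta12 row, >=1 omega3 row and exactly one query row."""
        for group in ("delta12", "omega3"):
            if not self.group_ids(group):
                raise GroupLabelError(f"classification needs at least one {group} row")
        queries = self.group_ids("query")
        if len(queries) != 1:
            raise GroupLabelError(
                f"classification needs exactly one query row, found {len(queries)}"
            )


@dataclass(frozen=True)
class ColumnMap:
    """Bijection between non-gap alignment columns and residue numbers.

    Both sides are 1-based.  ``col_to_res[c]`` gives the ungapped residue
    number sitting in alignment column ``c``; ``res_to_col`` is its inverse.
    """

    seq_id: str
    col_to_res: Mapping[int, int]
    res_to_col: Mapping[int, int]

    def residue_number(self, col: int) -> int | None:
        """Residue number at alignment column *col*, or None at a gap."""
        return self.col_to_res.get(col)

    def column(self, residue_number: int) -> int:
        return self.res_to_col[residue_number]


def build_column_map(ga: GroupedAlignment, seq_id: str) -> ColumnMap:
    """Map alignment columns to ungapped residue numbers for one row."""
    aligned = ga.aligned(seq_id)  # KeyError for unknown id
    col_to_res: dict[int, int] = {}
    res = 0
    for col, ch in enumerate(aligned, start=1):
        if ch != GAP:
            res += 1
            col_to_res[col] = res
    return ColumnMap(
        seq_id=seq_id,
        col_to_res=col_to_res,
        res_to_col={r: c for c, r in col_to_res.items()},
    )


# ---------------------------------------------------------------------------
# group label tables
# ---------------------------------------------------------------------------

def read_groups(path: str | Path) -> dict[str, str]:
    """Read an id→group table from a 2-column TSV or a JSON object."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        table = json.loads(text)
        if not isinstance(table, dict):
            raise GroupLabelError(f"{path}: JSON group table must be an object")
        items = table.items()
    else:
        items = []
        for line_no, line in enumerate(text.splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise GroupLabelError(
                    f"{path}:{line_no}: expected 'id<TAB>group', got {line!r}"
                )
            items.append(tuple(parts))
    groups: dict[str, str] = {}
    for seq_id, group in items:
        if group not in GROUPS:
            raise GroupLabelError(
                f"{path}: unknown group {group!r} for {seq_id!r}; "
                f"expected one of {GROUPS}"
            )
        groups[seq_id] = group
    return groups


# ---------------------------------------------------------------------------
# alignment I/O (Biopython behind the scenes)
# ---------------------------------------------------------------------------

def read_alignment(
    path: str | Path,
    groups: Mapping[str, str] | str | Path,
    fmt: str = "fasta",
    reference_id: str | None = None,
) -> GroupedAlignment:
    """Read a FASTA or Clustal alignment and attach group labels.

    The aligner itself is external: point this at the output file of any
    multiple-alignment program (the hook is simply the file path).

    Parameters
    ----------
    path : path
        Alignment file.
    groups : mapping or path
        Either an id→group mapping or the path of a TSV/JSON table
        (see :func:`read_groups`).
    fmt : {"fasta", "clustal"}
    reference_id : str, optional
        Query-role row for reference numbering; inferred when exactly one
        row is labeled ``query``.
    """
    if fmt not in ("fasta", "clustal"):
        raise AlignmentFormatError(f"unsupported alignment format {fmt!r}")
    if not isinstance(groups, Mapping):
        groups = read_groups(groups)
    try:
        msa = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise AlignmentFormatError(f"{path}: {exc}") from exc
    rows = [(rec.id, str(rec.seq)) for rec in msa]
    return GroupedAlignment(
        rows=rows, groups=dict(groups), reference_id=reference_id
    )


def write_alignment(ga: GroupedAlignment, path: str | Path, fmt: str = "fasta") -> None:
    """Write the alignment back out in FASTA or Clustal format."""
    if fmt not in ("fasta", "clustal"):
        raise AlignmentFormatError(f"unsupported alignment format {fmt!r}")
    msa = MultipleSeqAlignment(
        [
            _BioSeqRecord(Seq(aligned), id=seq_id, description="")
            for seq_id, aligned in ga.rows
        ]
    )
    AlignIO.write(msa, str(path), fmt)


def write_groups(groups: Mapping[str, str], path: str | Path) -> None:
    """Write an id→group table as 2-column TSV."""
    with open(path, "w", newline="") as fh:
        for seq_id, group in groups.items():
            fh.write(f"{seq_id}\t{group}\n")


# ---------------------------------------------------------------------------
# candidate-site TSV
# ---------------------------------------------------------------------------

def write_candidates(sites: Sequence, path: str | Path) -> None:
    """Write candidate sites as TSV, one row per site, sorted by position.

    Columns: ref_position, categories (comma-joined circled digits),
    query_residue, delta12_consensus, omega3_consensus.  Absent consensus is
    written as ``.``.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(CANDIDATE_HEADER)
        for site in sorted(sites, key=lambda s: s.ref_position):
            writer.writerow(
                [
                    site.ref_position,
                    ",".join(str(c) for c in site.categories),
                    site.query_residue,
                    site.delta12_consensus or ".",
                    site.omega3_consensus or ".",
                ]
            )


def read_candidates(path: str | Path) -> list:
    """Read a candidate TSV written by :func:`write_candidates`."""
    from fadtools.sdp_classifier import CandidateSite, Category

    sites = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = tuple(next(reader))
        if header != CANDIDATE_HEADER:
            raise AlignmentFormatError(f"{path}: unexpected header {header!r}")
        for row in reader:
            pos, cats, query, d12, w3 = row
            sites.append(
                CandidateSite(
                    ref_position=int(pos),
                    categories=frozenset(Category(c) for c in cats.split(",")),
                    query_residue=query,
                    delta12_consensus=None if d12 == "." else d12,
                    omega3_consensus=None if w3 == "." else w3,
                )
            )
    return sites
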