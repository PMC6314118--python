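"""GC-FAME quantification and desaturase regiochemistry.

Yeast strains expressing a desaturase (or one of its variants) are grown,
their total fatty acids are derivatized to methyl esters and run on GC with
a fixed mass of heptadecanoic acid (17:0) as internal standard.  Two
numbers summarize each strain:

* **activity** — μg of desaturation products per :math:`A_{600}` unit of
  cells, computed by internal-standard normalization:
  ``yield = area / area(ISTD) × ISTD mass / A600``;
* **ALA fraction** — ALA/(ALA+LA), the fraction of linoleate that was
  carried on to α-linolenate by the second desaturation.

The module also encodes the positional bookkeeping of desaturase
regiochemistry.  In Δ (carboxyl-end) numbering, an ω3 desaturase inserts a
double bond at carbon ``chain_length − 3`` while a v+3 desaturase counts
three carbons toward the methyl end from the last existing double bond.
Comparing the two predictions against an observed product identifies the
counting rule; on an 18:2Δ9,12 substrate both rules predict Δ15 (since
9 + 3 = 12 + 3 = 18 − 3), which is exactly why a 16-carbon substrate, where
the predictions split (Δ15 vs Δ13), is the discriminating experiment.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

ISTD_MASS_UG = 5.0  # μg of 17:0 added per sample
ISTD_SHORTHAND = "17:0"

_SPECIES_RE = re.compile(r"^(\d+):(\d+)(?:Δ([\d,]+))?$")

PEAK_COLUMNS = ("sample_id", "a600", "species", "area", "istd_flag")


class SpeciesFormatError(ValueError):
    pass


class QuantificationError(ValueError):
    pass


class InfeasibleProductError(ValueError):
    """The requested desaturation has nowhere valid to put its double bond."""


class RegioRule(Enum):
    """How a desaturase counts to its insertion position."""

    V_PLUS_3 = "v_plus_3"   # 3 carbons past the last existing double bond
    OMEGA3 = "omega3"       # 3 carbons from the methyl end
    AMBIGUOUS = "ambiguous"  # both rules predict the same position


@dataclass(frozen=True, order=True)
class FattyAcidSpecies:
    """A fatty acid in Δ (carboxyl-end) double-bond numbering."""

    chain_length: int
    double_bonds: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.chain_length < 2:
            raise SpeciesFormatError(f"chain length {self.chain_length} too short")
        bonds = self.double_bonds
        if list(bonds) != sorted(set(bonds)):
            raise SpeciesFormatError(
                f"double-bond positions must be strictly increasing, got {bonds}"
            )
        for p in bonds:
            if not 1 <= p <= self.chain_length - 1:
                raise SpeciesFormatError(
                    f"double bond at Δ{p} outside chain of {self.chain_length} carbons"
                )

    @property
    def shorthand(self) -> str:
        base = f"{self.chain_length}:{len(self.double_bonds)}"
        if self.double_bonds:
            base += "Δ" + ",".join(str(p) for p in self.double_bonds)
        return base

    def __str__(self) -> str:
        return self.shorthand

    @classmethod
    def parse(cls, shorthand: str) -> "FattyAcidSpecies":
        """Parse strict ``<C>:<n>Δ<p1>,<p2>,...`` shorthand (e.g. 18:2Δ9,12)."""
        m = _SPECIES_RE.match(shorthand.strip())
        if not m:
            raise SpeciesFormatError(f"cannot parse species {shorthand!r}")
        chain, n_bonds, positions = m.groups()
        bonds = tuple(int(p) for p in positions.split(",")) if positions else ()
        if len(bonds) != int(n_bonds):
            raise SpeciesFormatError(
                f"{shorthand!r}: declares {n_bonds} double bonds but lists {len(bonds)}"
            )
        return cls(chain_length=int(chain), double_bonds=bonds)


#: linoleic acid and α-linolenic acid, the two 18-carbon products tracked
LA = FattyAcidSpecies(18, (9, 12))
ALA = FattyAcidSpecies(18, (9, 12, 15))


# ---------------------------------------------------------------------------
# peak tables and quantification
# ---------------------------------------------------------------------------

@dataclass
class PeakTable:
    """One sample's GC-FAME peak areas with its internal-standard row."""

    sample_id: str
    a600: float
    peaks: dict[str, float]        # species shorthand -> peak area
    istd_area: float
    istd_mass_ug: float = ISTD_MASS_UG

    def __post_init__(self) -> None:
        if not self.a600 > 0:
            raise QuantificationError(f"{self.sample_id}: A600 must be > 0")
        if self.istd_area < 0 or any(a < 0 for a in self.peaks.values()):
            raise QuantificationError(f"{self.sample_id}: negative peak area")


def read_peak_tables(path: str | Path) -> list[PeakTable]:
    """Read peak tables from CSV (sample_id, a600, species, area, istd_flag).

    Rows sharing a ``sample_id`` form one table; exactly one row per sample
    must carry a truthy ``istd_flag``.
    """
    df = pd.read_csv(path)
    missing = set(PEAK_COLUMNS) - set(df.columns)
    if missing:
        raise QuantificationError(f"{path}: missing column(s) {sorted(missing)}")
    tables = []
    for sample_id, sub in df.groupby("sample_id", sort=False):
        istd_rows = sub[sub["istd_flag"].astype(bool)]
        if len(istd_rows) != 1:
            raise QuantificationError(
                f"{sample_id}: expected exactly one internal-standard row, "
                f"found {len(istd_rows)}"
            )
        a600_values = sub["a600"].unique()
        if len(a600_values) != 1:
            raise QuantificationError(f"{sample_id}: inconsistent A600 values")
        peaks = {
            str(row.species): float(row.area)
            for row in sub.itertuples()
            if not bool(row.istd_flag)
        }
        tables.append(
            PeakTable(
                sample_id=str(sample_id),
                a600=float(a600_values[0]),
                peaks=peaks,
                istd_area=float(istd_rows["area"].iloc[0]),
            )
        )
    return tables


def write_peak_tables(tables: Sequence[PeakTable], path: str | Path) -> None:
    rows = []
    for t in tables:
        rows.append((t.sample_id, t.a600, ISTD_SHORTHAND, t.istd_area, 1))
        for species, area in t.peaks.items():
            rows.append((t.sample_id, t.a600, species, area, 0))
    pd.DataFrame(rows, columns=PEAK_COLUMNS).to_csv(path, index=False)


@dataclass
class PhenotypeResult:
    """Quantified phenotype of one sample."""

    sample_id: str
    yields: dict[str, float]          # species shorthand -> μg per A600
    product_activity: float           # summed desaturation-product yields
    ala_fraction: float | None        # ALA/(ALA+LA); None when undefined
    relative_activity: float | None = None  # vs. a reference sample

    def relative_to(self, reference: "PhenotypeResult") -> "PhenotypeResult":
        if not reference.product_activity > 0:
            raise QuantificationError(
                f"reference {reference.sample_id} has no product activity"
            )
        return replace(
            self,
            relative_activity=self.product_activity / reference.product_activity,
        )


def ala_fraction(ala_yield: float, la_yield: float) -> float | None:
    """ALA/(ALA+LA); None (undefined, not zero) when both yields are zero."""
    if ala_yield < 0 or la_yield < 0:
        raise QuantificationError("yields must be non-negative")
    total = ala_yield + la_yield
    if total == 0:
        return None
    return ala_yield / total


def _is_product(species: str, min_double_bonds: int) -> bool:
    try:
        return len(FattyAcidSpecies.parse(species).double_bonds) >= min_double_bonds
    except SpeciesFormatError:
        return False


def quantify(
    table: PeakTable,
    response_factors: Mapping[str, float] | None = None,
    product_min_double_bonds: int = 2,
) -> PhenotypeResult:
    """Convert peak areas to μg/A600 yields by internal-standard normalization.

    ``yield(s) = area(s) / area(ISTD) × ISTD mass / A600``, optionally scaled
    by a per-species response factor (default: all factors 1, i.e. area
    ratios equal mass ratios).  ``product_activity`` sums the yields of
    desaturation products, by default any species with ≥2 double bonds.
    """
    if table.istd_area <= 0:
        raise QuantificationError(
            f"{table.sample_id}: internal-standard area must be > 0"
        )
    factors = response_factors or {}
    yields = {
        species: area / table.istd_area * table.istd_mass_ug / table.a600
        * factors.get(species, 1.0)
        for species, area in table.peaks.items()
    }
    product_activity = sum(
        y for s, y in yields.items() if _is_product(s, product_min_double_bonds)
    )
    return PhenotypeResult(
        sample_id=table.sample_id,
        yields=yields,
        product_activity=product_activity,
        ala_fraction=ala_fraction(
            yields.get(ALA.shorthand, 0.0), yields.get(LA.shorthand, 0.0)
        ),
    )


def classify_variant(
    result: PhenotypeResult,
    reference: PhenotypeResult,
    activity_gain: float = 1.25,
    loss_floor: float = 0.01,
    ratio_margin: float = 0.15,
) -> set[str]:
    """Label a variant against the reference enzyme's phenotype.

    Labels: ``increased_activity`` (relative activity above *activity_gain*,
    default 125%), ``loss_of_function`` (product activity at or below
    *loss_floor* × reference), ``ratio_shifted`` (absolute ALA-fraction
    change above *ratio_margin*).
    """
    if not reference.product_activity > 0:
        raise QuantificationError("reference must have positive product activity")
    labels: set[str] = set()
    relative = result.product_activity / reference.product_activity
    if relative > activity_gain:
        labels.add("increased_activity")
    if relative <= loss_floor:
        labels.add("loss_of_function")
    if (
        result.ala_fraction is not None
        and reference.ala_fraction is not None
        and abs(result.ala_fraction - reference.ala_fraction) > ratio_margin
    ):
        labels.add("ratio_shifted")
    return labels


# ---------------------------------------------------------------------------
# regiochemistry
# ---------------------------------------------------------------------------

def predict_product(
    substrate: FattyAcidSpecies, rule: RegioRule
) -> FattyAcidSpecies:
    """The single-desaturation product of *substrate* under a counting rule.

    ``V_PLUS_3`` inserts at (max existing Δ) + 3 and needs an existing
    double bond to count from; ``OMEGA3`` inserts at chain_length − 3.
    """
    if rule is RegioRule.AMBIGUOUS:
        raise ValueError("cannot predict a product from the ambiguous rule")
    if rule is RegioRule.V_PLUS_3:
        if not substrate.double_bonds:
            raise InfeasibleProductError(
                f"{substrate}: v+3 desaturation needs an existing double bond"
            )
        new = max(substrate.double_bonds) + 3
    else:
        new = substrate.chain_length - 3
    if new in substrate.double_bonds:
        raise InfeasibleProductError(
            f"{substrate}: predicted Δ{new} collides with an existing bond"
        )
    if new > substrate.chain_length - 1:
        raise InfeasibleProductError(
            f"{substrate}: predicted Δ{new} exceeds the {substrate.chain_length}-"
            "carbon chain"
        )
    return FattyAcidSpecies(
        chain_length=substrate.chain_length,
        double_bonds=tuple(sorted(substrate.double_bonds + (new,))),
    )


def infer_rule(
    substrate: FattyAcidSpecies, observed_product: FattyAcidSpecies
) -> RegioRule | None:
    """Which counting rule explains an observed desaturation product.

    Returns ``AMBIGUOUS`` when both rules predict the observed bond (which
    happens exactly when max existing Δ = chain_length − 6), the single
    matching rule otherwise, or None when neither rule explains the product.
    """
    if observed_product.chain_length != substrate.chain_length:
        raise ValueError("substrate and product chain lengths differ")
    extra = set(observed_product.double_bonds) - set(substrate.double_bonds)
    if (
        len(extra) != 1
        or not set(substrate.double_bonds) <= set(observed_product.double_bonds)
    ):
        raise ValueError(
            f"{observed_product} is not a single-desaturation derivative of "
            f"{substrate}"
        )
    matches = []
    for rule in (RegioRule.V_PLUS_3, RegioRule.OMEGA3):
        try:
            if predict_product(substrate, rule) == observed_product:
                matches.append(rule)
        except InfeasibleProductError:
            pass
    if len(matches) == 2:
        return RegioRule.AMBIGUOUS
    if len(matches) == 1:
        return matches[0]
    return None
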