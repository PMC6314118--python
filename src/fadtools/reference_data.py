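"""Published reference positions for the Fm1 desaturase family analysis.

Fm1 is a bifunctional Δ12/ω3 fatty-acid desaturase of *Fusarium
verticillioides* 7600.  The numbers below are the reported results of the
original alignment analysis of Fm1 against Δ12-desaturases (AtFAD2,
6803_DesA, AtFAD6) and ω3-desaturases (AtFAD8, AtFAD7, AtFAD3, 6803_DesB),
in Fm1 residue numbering.  They serve as bookkeeping fixtures: the pipeline
cannot regenerate them without the exact original alignment, but their
internal consistency (e.g. the size of the category union) is checkable.

Note one bookkeeping quirk of the published lists, preserved verbatim here:
positions 98 and 99 appear in both the Δ12-shared and Δ12-only lists, and
318 appears in the Δ12-shared list without appearing in the Δ12-only list.
"""

from __future__ import annotations

from fadtools.sdp_classifier import Category

#: reported candidate positions per Venn category (Fm1 numbering)
FM1_CATEGORY_POSITIONS: dict[Category, tuple[int, ...]] = {
    # ① conserved in Δ12-desaturases and shared by Fm1
    Category.QUERY_WITH_DELTA12: (98, 99, 318),
    # ② conserved in Δ12-desaturases only
    Category.DELTA12_ONLY: (98, 99, 120, 298, 350, 377),
    # ③ conserved in ω3-desaturases and shared by Fm1
    Category.QUERY_WITH_OMEGA3: (110, 162, 229, 235, 238, 240, 273, 280),
    # ④ conserved in ω3-desaturases
    Category.OMEGA3_ONLY: (
        36, 97, 110, 136, 139, 143, 156, 162, 165, 198, 199, 206, 207, 208,
        228, 229, 235, 237, 238, 240, 248, 250, 273, 280, 284, 288, 290,
        302, 304, 305, 327, 330, 335, 367, 380, 391, 398,
    ),
}

#: positions where neither the Fm1/Fm2 paralogs nor the two groups agree
FM1_FM2_DIVERGENT_POSITIONS: tuple[int, ...] = (
    25, 67, 121, 153, 164, 190, 194, 207, 210, 240, 264, 271, 345, 396,
)

#: His-box motif starts in Fm1 (HxxxH at 105, HxxHH at 141 and 337) ...
FM1_HIS_BOX_STARTS: tuple[int, ...] = (105, 141, 337)
#: ... plus one lone metal-ligating histidine outside any box motif
FM1_LONE_LIGAND_HIS: int = 295

#: non-histidine residues reported within 5 Å of the di-iron center
FM1_SHELL_NON_HIS: tuple[int, ...] = (157, 290, 308)

#: activity-tuning cluster near the di-iron site / specificity cluster on
#: the substrate-pocket entrance helix
CLUSTER_I: tuple[int, ...] = (153, 157, 194)
CLUSTER_II: tuple[int, ...] = (280, 284, 287)

#: NCBI accessions of the family members, with their group labels
FAMILY_ACCESSIONS: dict[str, tuple[str, str]] = {
    "AtFAD2": ("AEE75153.1", "delta12"),
    "6803_DesA": ("WP_010872792.1", "delta12"),
    "AtFAD6": ("NP_194824.1", "delta12"),
    "Fm1": ("XP_018759876.1", "query"),
    "Fm2": ("ABB88515.1", "other"),
    "AtFAD8": ("NP_196177.1", "omega3"),
    "AtFAD7": ("NP_187727.1", "omega3"),
    "AtFAD3": ("NP_180559.1", "omega3"),
    "6803_DesB": ("WP_010872924.1", "omega3"),
}


def candidate_position_union() -> list[int]:
    """Sorted union of the four reported per-category position lists."""
    union: set[int] = set()
    for positions in FM1_CATEGORY_POSITIONS.values():
        union.update(positions)
    return sorted(union)
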