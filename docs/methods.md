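# Methods

## The classification model

The pipeline assumes a family of homologous membrane desaturases that can
be partitioned into two monofunctional groups — Δ12 (oleate) and ω3
(linoleate) desaturases — plus one bifunctional query enzyme. The working
hypothesis is the standard specificity-determining-position (SDP) premise:
columns conserved *within* a functional group but *different between*
groups are candidate carriers of the functional difference, and the query's
residue at such a column hints at which group's behavior it inherits there.

Conservation is a per-group consensus call, not an information-theoretic
score. A group's column has a consensus when one residue reaches a
frequency `threshold` among its non-gap entries. The default threshold is
1.0 (strict unanimity): with the small group sizes typical of curated
desaturase families (3–4 sequences per group), frequency thresholds below
unanimity are barely distinguishable from it, and unanimity is the
reading that makes "conserved" unambiguous. The threshold is exposed for
larger families. An optional *property* mode judges conservation at the
level of coarse physicochemical classes (hydrophobic, aromatic, polar,
positive, negative, special) while still reporting the majority residue;
query-vs-consensus comparison stays identity-based in both modes because
the downstream substitution experiments are identity-based.

Gap handling: gaps are excluded from the consensus denominator as long as
the column's gap fraction is at most `gap_max` (default 25%); gappier
columns return no consensus. Membrane-desaturase alignments carry long
terminal and loop indels, and calling consensus on two residues of a
four-member group invites artifacts.

The four categories are evaluated independently per group side, so one
column can carry both a Δ12-side and an ω3-side flag (a column conserved in
both groups at different residues is both "Δ12-only" and, if the query
matches the ω3 residue, "shared with ω3"). A side fires only when it
differs from the other group's situation; columns conserved identically in
both groups reflect shared architecture, not specificity, and are never
called. Query-gap columns are skipped with a notice.

The paralog-divergence rule is the complement: columns where two
bifunctional paralogs differ from each other while *neither* group holds a
consensus. These columns cannot be explained by group membership and are
candidates for the paralogs' quantitative differences.

## Structural shell

The His-box scan reports every occurrence of HxxxH and HxxHH with 1-based
starts, overlapping occurrences included; a window whose fourth residue is
His is reported once, as HxxHH, not additionally as HxxxH. The shell screen
computes atom-to-atom Euclidean distances from every selected metal
(default elements FE/ZN/MN/CU) to every other atom and keeps residues whose
minimum distance is within the radius. Distance is taken over *all* atoms
of a residue — the inclusive reading of "within r Å of the metal ions" —
because backbone contacts can matter for active-site geometry;
a side-chain-only screen can be had by filtering atom names upstream.
Default radius 5.0 Å, the conventional first-shell cutoff for catalytic
metal neighborhoods. Altloc conformers are resolved to highest occupancy
on read; insertion codes stay part of the residue key. The KD-tree
implementation is checked in the tests against an independent all-pairs
scan, and is exactly monotone in the radius and invariant to rigid motions
(verified to 1e-6 Å under random orthogonal transforms).

Model-to-sequence numbering offsets are auto-detected over a ±5 window by
maximizing residue-name agreement; more than 5% disagreements abort with a
renumbering hint rather than silently reporting positions in the wrong
frame. Homology-model *construction* is out of scope — the module consumes
any PDB-format model the user provides.

## Mutation planning

Category ② and ④ sites are mutated to the conserved group's consensus.
Category ① and ③ sites (query shares one group's consensus) are mutated to
the residue of a single named representative of the other group, not that
group's consensus — the other group generally has no consensus at such
columns, and picking an archetype (e.g. the canonical Δ12 enzyme of the
family) is the reproducible choice. When a site carries two flags the
consensus-backed side (②/④) wins. A donor gap or a donor equal to the query
is a reported planning error, never a silent skip, and a planned
substitution is never synonymous by construction.

Near-adjacent candidate positions merge greedily left-to-right into one
mutagenesis unit when consecutive positions are within `window` residues
(default 3 — merges runs like 206/207/208 and pairs four residues apart
stay separate). A unit is exported as a single construct; whether its
members are mutated simultaneously is a construct-design decision the unit
representation leaves to the user. Structure-motivated substitutions that
follow no category rule (donors chosen case by case from a template
structure) enter through `manual_plan`. Variant names are
ascending-position, slash-joined (`K36R/L153R/F157H`) and parse back to
their mutation lists bijectively.

## Phenotype quantification

`yield(species) = area(species) / area(ISTD) × ISTD mass / A600`, with 5 μg
of 17:0 as the internal standard. FAME response factors are assumed equal
across species (area ratio = mass ratio); a per-species response-factor
table can be supplied when a calibrated instrument says otherwise.
`product_activity` sums species with ≥2 double bonds — for an enzyme fed
monounsaturated substrate every such species is an enzyme product; the
cutoff is configurable for other feeding designs. The ALA fraction is
ALA/(ALA+LA), well-defined because all ALA derives from a second
desaturation of LA; when both yields are zero it is *undefined* (None),
deliberately distinct from 0.

Variant labels against a reference: `increased_activity` above 1.25×
relative activity (the conventional highlight threshold for "clearly up"),
`loss_of_function` at or below 1% of reference (a floor for "no detectable
product" in the presence of integration noise), `ratio_shifted` when the
ALA fraction moves by more than 0.15 absolute (roughly the smallest shift
a triplicate assay at 5% noise calls reliably). All three are flags on a
continuous result, not substitutes for it.

Double-bond geometry is assumed cis throughout and not modeled. The
species grammar `<C>:<n>Δ<p1>,<p2>,...` is strict: the declared bond count
must match the listed positions.

## Synthetic data: what it emulates, what it does not

`simulate_family` plants unanimity at signal columns and makes every
background column *balanced*: each group draws exactly two distinct
residues from a group-specific pool, split as evenly as possible, so the
majority frequency is 0.5 for even group sizes and the column cannot be
called at any valid threshold. Gaps are injected only at background
columns, capped at `floor(gap_cap × group size)` per group-column, which
for the default 25% cap and groups of four means at most one gap — so gap
exclusion can never turn a balanced column unanimous. These two
constructions make the precision = recall = 1.0 assertions valid *by
construction*; real alignments have phylogenetic correlation, near-conserved
columns and alignment errors, so perfect planted recovery demonstrates
correctness of the bookkeeping, not expected field performance. The
generator is deterministic under its seed (explicit `numpy` generator, no
global state) and does not simulate sequence evolution along a tree.

`simulate_structure` places one atom per residue at an exact distance from
a metal at the origin along a coordinate axis, so distances survive the
3-decimal PDB coordinate format exactly. `simulate_peaks` inverts the
quantification formula (nominal ISTD area 10 000) and applies
multiplicative log-normal noise per species and replicate; σ=0 therefore
round-trips exactly, and the default σ=5% with triplicates mirrors a
well-behaved GC assay. The shipped demo parameterizes a reference enzyme at
ALA fraction 0.86 and 20 μg/A600, an activity-enhanced variant at 2.5×, a
specificity-reversed variant at fraction 0.06, a ratio-shifted and a dead
variant — narrative parameter choices for the tutorial and tests, not
wet-lab measurements.

## Numerical and design notes

* All positions are 1-based, in both alignment-column and residue space;
  outputs are always in the query's residue numbering via an explicit
  column map (a bijection on non-gap columns, property-tested).
* Gap character is `-`; `.` is normalized on read with a notice. Residues
  beyond the 20 standard letters plus X are rejected loudly rather than
  miscounted.
* Shell membership uses `≤ radius` (boundary inclusive); distances are
  reported exactly, not binned.
* The aligner is external by design: group-specific conservation calls are
  alignment-dependent, and different aligners can shift column/position
  sets. The published candidate lists shipped in `reference_data` are
  therefore fixtures for bookkeeping checks, not regeneration targets; they
  also preserve a known quirk of the original lists (98/99 double-listed in
  the Δ12-shared and Δ12-only sets, 318 only in the shared set).
* Problem sizes in tests and the acceptance script — 2×4-sequence families
  of 400 columns, 100 random 200-atom structures, triplicate assays — match
  the scale of the motivating study design and keep the full suite in the
  seconds range.

## Known limitations

* Consensus-based SDP calling has no significance model; with larger
  groups an entropy or mutual-information score would rank candidates,
  which is deliberately out of scope here.
* The property-mode class partition is one of several defensible binnings
  (His is grouped as positive, Cys as hydrophobic); swap the table if your
  family disagrees.
* Pairwise identity, pocket shape and channel geometry are not computed;
  the structural module is a distance screen only.
* mmCIF input is not supported (PDB-format models only).
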