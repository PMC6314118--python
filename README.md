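# fadtools

Sequence/structure analysis pipeline for dissecting the **regioselectivity of
membrane fatty-acid desaturases**, built around the bifunctional Δ12/ω3
(oleate + linoleate) desaturase Fm1 of *Fusarium verticillioides* as the model
system. It is aimed at enzymologists and protein engineers who want to
nominate specificity-determining residues from a family alignment, filter
them against a structural model of the di-iron active site, plan and name
mutants, and interpret the GC-FAME phenotypes of those mutants.

## What it computes

**Candidate specificity positions (Venn classification).** Given a multiple
sequence alignment of Δ12-desaturases, ω3-desaturases and a bifunctional
query enzyme, each column is tested for group-specific conservation. With
per-group consensus `c_G` (default: unanimity among non-gap residues, gap
fraction ≤ 25%) and query residue `q`, a column is classified per group side:

| category | condition |
|---|---|
| ① | Δ12 group conserved, `q = c_Δ12` |
| ② | Δ12 group conserved, `q ≠ c_Δ12` |
| ③ | ω3 group conserved, `q = c_ω3` |
| ④ | ω3 group conserved, `q ≠ c_ω3` |

A side only fires when the two groups actually differ; columns conserved at
the same residue in both groups carry no specificity signal. Positions are
reported in the query's own 1-based residue numbering. A second rule scans
two paralogous queries for columns where the paralogs differ *and* neither
group is conserved (candidate explanations for paralog-specific behavior).

**Metal-coordination shell.** `find_his_boxes` locates the HxxxH / HxxHH
iron-ligating histidine boxes in sequence; `shell_residues` reads a PDB
model (gemmi) and lists every residue with an atom within a radius (default
5 Å) of the catalytic metal ions, with exact minimum distances, so the
non-histidine active-site neighborhood is one call away.

**Mutation planning.** Candidate sites become substitutions (`②/④` → the
conserved group's consensus; `①/③` → the other group's representative
residue), near-adjacent sites merge into single mutagenesis units, and
mutations stack into canonically named variants (`K36R/L153R/F157H`).

**Phenotypes and regiochemistry.** GC-FAME peak tables with a 5 μg 17:0
internal standard are quantified as
`yield = area / area(ISTD) × ISTD mass / A600` (μg fatty acid per A600 of
cells); the ALA fraction is ALA/(ALA+LA). Desaturation counting rules are
encoded in Δ (carboxyl-end) numbering — ω3 inserts at `chain − 3`, v+3 at
`(last double bond) + 3` — so observed products identify the rule: on
18:2Δ9,12 both rules predict Δ15 (ambiguous), while 16:2Δ9,12 splits them
(Δ15 vs Δ13).

Every stage has a seeded synthetic generator (`fadtools.synthetic_data`)
with planted ground truth, so the whole pipeline runs and is tested with no
downloads.

## Worked example

```bash
fadtools simulate family --seed 42 --out-prefix fam
fadtools scan --alignment fam.fasta --groups fam.groups.tsv | head -4
```

```
ref_position	categories	query_residue	delta12_consensus	omega3_consensus
42	1	W	W	.
45	1	F	F	.
84	1	H	H	.
```

Position 42 is category ① — the Δ12 group is unanimously W, the query
shares it, the ω3 group is mixed (`.` = no consensus). Planning and
stacking:

```bash
fadtools plan --alignment fam.fasta --groups fam.groups.tsv \
    --donor-delta12 d12_1 --donor-omega3 w3_1 | head -3
fadtools stack --mutations F157H,L153R,K36R
```

```
position	wt	substitute	unit	categories
42	W	N	1	1
45	F	T	1	1
K36R/L153R/F157H
```

The ①-sites at 42 and 45 are swapped to the ω3 representative's residues
(N, T) and, being three residues apart, share mutagenesis unit 1.
Phenotypes of the demo assay (noise-free) and a regiochemistry query:

```bash
fadtools simulate peaks --sigma 0 --out peaks.csv
fadtools quantify --peaks peaks.csv --reference Fm1_r1 | grep -E '^(sample|Fm1_r1|enhanced_r1)'
fadtools regio --substrate 16:2Δ9,12 --rule v_plus_3
```

```
sample	product_activity_ug_per_A600	ala_fraction	relative_activity
Fm1_r1	20.000	0.860	1.000
enhanced_r1	50.000	0.860	2.500
16:3Δ9,12,15
```

The reference enzyme makes 20 μg desaturation products per A600 with 86% of
its linoleate carried on to α-linolenate; the enhanced variant is 2.5× as
active; a v+3 desaturase acting on 16:2Δ9,12 yields 16:3Δ9,12,15.

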