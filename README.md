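# somcyp

Mechanism-based prediction of CYP3A4 sites of metabolism (SoM).

Cytochrome P450 3A4 is the dominant human drug-metabolizing enzyme, with a
large, promiscuous active cavity and notoriously poor regioselectivity —
especially on rigid substrates such as steroids, where many chemically
similar C–H bonds compete.  `somcyp` implements a two-factor model of the
catalytic event for the two dominant reaction classes, aliphatic
hydroxylation and *N*-dealkylation:

1. **Binding accessibility.**  Across an ordered ensemble of docked ligand
   poses, a candidate carbon is accessible when its distance *r* to the heme
   iron lies in a window (default 2.5–7.5 Å, inclusive) *and* the same pose
   is anchored in the cavity by at least one key interaction feature: a
   hydrogen bond to Arg105 / Arg106 / Ser119 / Ile301 / Glu308 or to one of
   the conserved waters 619 / 623 / 637, or a lipophilic contact with the
   Phe-cluster roof (Phe57/108/219/220/241/304) or the heme face.  Carbons
   one bond from an accessible site are also admitted.  Each site carries
   the (weighted) fraction of poses placing it inside the window.

2. **Chemical reactivity.**  Both reaction classes are initiated by
   hydrogen abstraction, so qualified sites are ranked by the
   hydrogen-abstraction reaction energy

   ΔH*rxn* = *E*(R•) + *E*(H•) − *E*(R–H),

   computed per hydrogen class (all hydrogens on one carbon share a radical)
   with a self-contained CNDO/2 semi-empirical SCF: restricted for the
   closed-shell parent, spin-unrestricted for the doublet radical, at frozen
   parent geometry.  Lower ΔH*rxn* = more labile = better site.

The top three ranked sites are the prediction; a substrate is scored
correct when any experimentally observed site appears among them.

## Worked example

The `demo` subcommand generates a complete synthetic scenario — a toy
active-site PDB (heme iron, Ser119, three waters, a phenylalanine ring), a
10-pose SDF ensemble of cyclohexanone with controlled site–iron distances —
and runs the full pipeline:

```text
$ somcyp demo --seed 0
somcyp demo (seed=0)
substrate: cyclohexanone (17 atoms)
poses: 10 generated, 6 with the marked site inside the 2.5-7.5 A window
 rank  carbon_index           reaction_type  delta_h_hartree  delta_h_kcal  pose_fraction  hbond  lipophilic  adjacency_derived  in_top_k
    1             1 aliphatic_hydroxylation         0.329494      206.7608            0.5   True        True              False      True
    2             5 aliphatic_hydroxylation         0.329494      206.7608            0.4   True        True              False      True
    3             3 aliphatic_hydroxylation         0.332321      208.5346            0.6   True        True              False      True
    4             2 aliphatic_hydroxylation         0.333811      209.4695            0.6   True        True              False     False
    5             4 aliphatic_hydroxylation         0.333811      209.4695            0.5   True        True              False     False
```

Reading the table: the two carbons alpha to the carbonyl (C1, C5) are the
most labile (lowest ΔH*rxn*, here 206.76 kcal/mol on the engine's internal
scale — only differences within one molecule are meaningful) and rank
first; the symmetric pair is tied in energy and ordered by pose fraction.
`pose_fraction` is the share of the ten poses placing that carbon inside
the distance window; the flag columns record how each site qualified
(hydrogen bond, lipophilic contact, or adjacency to a qualified site).

Real inputs run through `somcyp predict`:

```bash
somcyp predict --complex 3tjs.pdb --poses docked.sdf \
               --substrate substrate.sdf --config config.yaml \
               --out prediction.json
```

`--complex` is a CYP3A4 holo PDB (heme FE required), `--poses` an ordered
multi-record SDF/MOL2 from any docking engine (record order = rank),
`--substrate` the same molecule with explicit hydrogens.  An optional
`--energies` TSV (carbon index, ΔH*rxn*) substitutes energies from any
external quantum-chemistry package for the built-in engine.  Predictions
for annotated substrates can then be scored with
`somcyp.evaluation.score_substrate` / `aggregate`, which build the
per-reaction-type Nc/N accuracy tables.

## Layout

| module | contents |
|---|---|
| `somcyp.chemio` | SDF V2000 / MOL2 reading, SDF writing, hydrogen classes, adjacency, Morgan symmetry labels |
| `somcyp.active_site` | active-site model extraction from PDB (heme Fe, donor residues, waters, Phe-cluster) |
| `somcyp.pose_features` | site–iron distances, H-bond / lipophilic detectors, pose fractions |
| `somcyp.cndo` | CNDO/2 SCF engine (H, C, N, O, F, S, Cl) and abstraction energies |
| `somcyp.predictor` | candidate enumeration, qualification, adjacency expansion, ranking |
| `somcyp.evaluation` | top-3 scoring rule, accuracy tables, annotation I/O |
| `somcyp.fixtures` | synthetic active sites, pose ensembles, reference molecules |

See `docs/methods.md` for the model's assumptions, parameter choices and
known limitations.
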