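# Methods

## The model

CYP3A4 oxidation proceeds by substrate binding followed by a two-step
radical mechanism whose rate-determining step, for aliphatic hydroxylation
and for the hydrogen-atom-transfer channel of *N*-dealkylation, is
abstraction of a hydrogen from the site of metabolism.  The model therefore
factorizes regioselectivity into two independent questions:

* *Can the carbon reach the reactive iron–oxo center, in a pose that is
  actually bound?*  — answered geometrically against an ensemble of docked
  poses of the substrate in the protein frame.
* *How hard is the abstraction at that carbon?*  — answered by a
  semi-empirical single-point estimate of the homolytic C–H reaction
  energy.

Qualified sites (accessible, anchored) are ranked by reaction energy and
the three lowest-energy carbons are reported.  The package does **not**
dock: the pose ensemble is an input, produced by any engine that writes an
ordered multi-record SDF/MOL2.

## Accessibility filter

**Distance window.**  A pose makes a carbon accessible when its distance to
the heme iron lies in the closed interval [2.5, 7.5] Å (defaults; the upper
cutoff is configurable, with 6.5/7.0/7.5 Å the natural alternatives).  The
catalytically competent Fe–C distance is usually quoted near 6 Å; the wider
default window compensates for docking into a rigid crystal conformation of
an enzyme known for induced fit.  Only the top `poses_kept` poses (default
10) are considered, in file order.

**Anchoring features.**  A pose counts as bound when it shows at least one
of:

* a hydrogen bond between a ligand N/O and a polar atom of Arg105, Arg106,
  Ser119, Ile301 or Glu308 (side-chain N/O; backbone O and N are included
  for Ile301 and Glu308), or a conserved water (619, 623, 637);
* a lipophilic contact: ≥ 3 ligand-carbon / ring-carbon pairs within 4.5 Å
  of the Phe-cluster (Phe57, 108, 219, 220, 241, 304), or the analogous
  count against heme heavy atoms, restricted to candidate-site carbons
  ("hydrophobic toward the heme").

Hydrogen-bond geometry uses standard criteria — donor–acceptor ≤ 3.5 Å and
a D–H⋯A angle ≥ 120° when the ligand donates.  When the ligand atom has no
hydrogen (a carbonyl oxygen, say), the protein or water side would donate;
crystallographic models carry no hydrogens, so that direction is accepted
on the distance criterion alone.  At most one feature is emitted per
(ligand atom, partner atom) pair.  A ligand atom that *has* hydrogens but
is misaligned is not silently converted to an acceptor: that direction is
dropped, a deliberately conservative reading.

Feature attribution is pose-level: one anchor qualifies every in-window
site of that pose, matching how binding modes are described (a whole pose
held by a single water-mediated hydrogen bond).

**Adjacency expansion.**  Candidate sites one bond from a qualified site
are admitted once (derived sites never seed further expansion, so the
operation is idempotent), flagged, and inherit the best parent's pose
fraction — they qualify *because of* the parent's accessibility.

**Pose fraction.**  Each site reports Σ of normalized pose weights over
in-window poses.  The default weighting is uniform (the plain fraction);
a linear-rank scheme w_i ∝ (n+1−i) is available by configuration.  The
fraction is reported and used only as a tie-breaker in ranking: the
qualification decision itself is binary.

## Reactivity: the CNDO/2 engine

ΔH_rxn = E(radical) + E(H atom) − E(parent), all single points.  Because
E(H atom) is an engine constant and all comparisons are within one parent
geometry, the ranking is invariant to any constant shift — which is why
total-energy differences can stand in for heats of formation.

Choices, in the order they matter:

* **Parameterization** — Pople–Segal CNDO/2: valence Slater s/p orbitals
  (ζ_H = 1.2, first-row ζ from Slater rules), orbital electronegativities
  −(I+A)/2, β_AB = ½(β°_A + β°_B)·S_μν, point-charge core repulsion
  Z_A Z_B / R.  Elements H, C, N, O, F plus S and Cl via the second-row
  sp extension (no d orbitals).  Absolute energies from this
  parameterization are not comparable across programs; within-molecule
  rankings are the claim.
* **Overlap integrals** are fully analytic: prolate-spheroidal expansion
  into A_k/B_k auxiliary integrals, valid for any s/p pair with principal
  quantum numbers 1–3 (B_k switches to a power series below |β| = 2 for
  numerical stability).  Verified against 3-D numerical quadrature and the
  1s/1s closed form.
* **Two-center repulsion γ_AB** uses the exact closed-form electrostatic
  potential of an s-Slater density, averaged over spheres analytically;
  the remaining one-dimensional radial integral is evaluated by 96-point
  Gauss–Legendre panels split at the inter-atomic distance, accurate to
  ~1e-12 (verified against the equal-exponent 1s closed form, the
  one-center values 5ζ/8 and 93ζ/256, and the 1/R long-range limit).
* **Radical geometry** is the parent geometry minus the abstracted
  hydrogen — no relaxation.  A geometry-optimizing treatment would lower
  all radicals by similar relaxation energies; freezing keeps the
  evaluation cheap, deterministic, and unbiased across sites of one
  molecule, at the cost of absolute accuracy.
* **Open shells** are spin-unrestricted doublets, no spin-projection.
* **Class value** = minimum over the member hydrogens of a carbon: the
  most labile accessible hydrogen governs abstraction.
* **SCF controls**: damped density mixing (0.4 of the previous density),
  convergence at max|ΔP| ≤ 1e-8, 200 iterations, diagonal initial guess
  from core charges.  The tight density threshold keeps total energies
  reproducible to ≲1e-10 hartree so that symmetry-equivalent sites tie
  cleanly.  Energies within 1e-9 hartree are treated as exact ties and
  broken by pose fraction, then lower carbon index.
* **External energies**: a per-carbon TSV can replace the engine entirely,
  so DFT or ab initio abstraction energies can drive the same predictor.

## Candidate enumeration

Aliphatic hydroxylation: sp3 carbons (all single bonds) bearing ≥ 1
hydrogen.  *N*-dealkylation: the same test plus a single bond to nitrogen.
Aromatic C–H is out of scope by construction.  A carbon qualifying under
both reaction types is ranked once — its two entries share a dense rank —
so duplicates never consume top-3 positions.

## Scoring protocol

A substrate is correct when any experimentally known site matches a top-3
carbon (carbon identity; one hit suffices for multi-metabolite
substrates).  Accuracy tables report Nc, N and 100·Nc/N to two decimals
per reaction type and overall; a substrate with known sites of both types
counts once per type row but once overall, making the row-sum identity
testable.

## Synthetic fixtures and what they do (not) show

The fixture module generates every input the pipeline needs: a minimal
PDB (heme Fe + four nitrogens, ideal-geometry side chains anchored at
requested positions, numbered waters), pose ensembles with site–iron
distances honoured exactly by construction, and six reference molecules
(Td methane, eclipsed ethane, propane, trimethylamine, toluene,
cyclohexanone) built from ideal internal coordinates so that symmetry
assertions hold to machine precision.

These fixtures exercise every contract — parsing, extraction, feature
geometry, SCF physics, qualification logic, ranking determinism — but they
are not a CYP3A4 mimic: passing tests demonstrate correctness of the
machinery, not predictive accuracy on real substrates.  Reproducing the
reported accuracies would require the 50 experimental substrates, a
commercial docking engine, and curated metabolite annotations, all outside
this package's scope; the acceptance script therefore reproduces the
evaluation arithmetic from the reported counts and the full pipeline on
synthetic inputs.  Problem sizes in tests and the acceptance run (≤ 17
atoms, ≤ 10 poses) were chosen as the smallest instances that exercise
every code path, including symmetric ties and open-shell SCF.

## Known limitations

* No docking, protonation, tautomer or conformer generation; explicit
  hydrogens are required and enforced.
* Reaction scope is aliphatic hydroxylation and *N*-dealkylation; aromatic
  hydroxylation, O-dealkylation and other isoforms are out of scope, as are
  stereochemical face labels (6β vs 6α).
* CNDO/2 absolute energies are not thermochemical; only within-molecule
  rankings are meaningful.
* SDF is V2000 only (V3000 is rejected with a clear message); MOL2 is
  read, not written.
* Waters and protein atoms carry no hydrogens, so protein-donor hydrogen
  bonds are distance-only.
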