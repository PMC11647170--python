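# Methods

This note documents the models, conventions and numerical choices behind
`bitterqsar`, and what the synthetic benchmarks do and do not demonstrate.

## Molecular model

Molecules are heavy-atom graphs; hydrogens are implicit, carried as a
per-atom count and materialised only where needed (molecular weight, donor
detection, 3D embedding). Multi-fragment SMILES (salts) keep the largest
fragment, because the topological descriptors assume a connected graph.
Stereochemistry is parsed but not used. 3D conformers come from RDKit's
ETKDG with a fixed seed followed by MMFF minimisation; one conformer per
molecule, no conformational averaging — determinism is preferred over an
ensemble, and the surface-area descriptor below is only required to rank
molecular size/branching, which a single reasonable conformer does.

Receptor structures keep the PDB file's own chain/residue numbering.
Generic GPCR (Ballesteros–Weinstein) labels are accepted only as a
user-supplied annotation map and never computed, since label assignment
depends on alignments outside this package's scope.

## Descriptors

**wienerPath** is half the sum of all entries of the topological distance
matrix of the heavy-atom graph, with unit bond lengths regardless of bond
order. For a path graph on *n* vertices it equals *n(n²−1)/6*. The
hydrogen-suppressed convention matches how the descriptor is normally
defined for QSAR work; a hydrogen-inclusive variant would simply operate on
the graph with explicit hydrogens attached, but is not exposed. A
disconnected graph raises by default; with an explicit flag the
per-component sums are added — an infinite distance is never produced
silently.

**Molecular weight** uses a pinned atomic-weight table (C 12.0107,
H 1.00794, N 14.0067, O 15.9994, S 32.065, …). The table is part of the
reproducibility contract: it reproduces two-decimal printed weights
(e.g. strychnine C21H22N2O2 → 334.41 g/mol) that newer IUPAC tables shift
by 0.01.

**Descriptor pool.** Eleven built-ins (heavy atoms, H count, ring count,
aromatic rings, H-bond donors/acceptors, the two Zagreb indices,
wienerPath, MW, branch count) padded with deterministic derived columns —
seeded nonlinear combinations of the built-ins — to a configurable width
(default 336). The padding exists so descriptor-selection experiments face
a realistically wide, partially redundant table; the padded columns carry
no new information and are not meant to be interpretable.

## Interaction-field surface area (vsurf_S analogue)

The commercial descriptor of this name is the area of an isoenergy surface
of a water-probe molecular interaction field. Our analogue:

* **Field.** Sum over atoms of a Lennard-Jones 12-6 term with an OPLS-like
  water-oxygen probe (r = 1.52 Å, ε = 0.152 kcal/mol; Lorentz–Berthelot
  mixing against per-element radii/well depths) plus a Coulomb term with
  Gasteiger partial charges, probe charge −0.66 e, and a
  distance-dependent dielectric ε(r) = 4r. Implicit-hydrogen charges are
  folded into their heavy atom (united-atom view); without this a neutral
  molecule acquires a spurious net monopole and the far field never decays
  below the iso level. If charges cannot be assigned the Coulomb term is
  dropped with a warning.
* **Grid.** Bounding box plus 4 Å padding, spacing 0.5 Å by default; the
  node lattice is centered on the box so symmetric molecules get symmetric
  grids. Distances are clamped at 0.05 Å so values at atomic centers are
  huge but finite.
* **Isosurface area.** Faces between adjacent nodes whose values straddle
  the level each contribute spacing²; the sum over-counts an isotropically
  oriented smooth surface by the spherical mean of |n_x|+|n_y|+|n_z|,
  which is exactly 3/2, so the raw count is divided by 1.5. Validated
  against the analytic sphere: error < 5 % at 0.2 Å spacing (−0.9 %
  measured), disjoint-sphere additivity within 2 %, rigid-motion
  sensitivity < 2 % at the default spacing. The default iso level is
  +0.2 kcal/mol, the conventional "molecular surface" level for water-probe
  fields.

Absolute values are **not** comparable to any vendor's descriptor — no
reference values exist to calibrate against. What the package relies on,
and what the tests check, is the descriptor's semantics: larger and
branchier molecules expose monotonically larger interaction surfaces.

## QSAR

**OLS.** `fit_ols` solves least squares with an intercept. Conventions for
degenerate inputs are explicit: a constant response returns the zero model
with R² defined as 0; a rank-deficient design raises and names the
redundant columns; a zero-variance response makes R²/q² an error rather
than a silent NaN.

**LOO q².** Computed with the PRESS identity e_i/(1−h_ii), which is
algebraically identical to n refits with one observation held out; the
test suite checks agreement with an explicit refit loop to 1e−10. The
descriptor subset is held fixed across folds — selection is not repeated
per fold — matching how q² is conventionally quoted for a final model.

**Frozen published model.** S = −1.26777 − 0.01161·vsurf_S +
0.00007·wienerPath (kcal/mol); constants are module-level literals and are
never refit.

**Genetic algorithm.** Chromosomes are descriptor subsets encoded as bit
vectors capped at 4 descriptors; fitness is training-set R² minus 0.01 per
selected descriptor; population 100, 200 generations, tournament selection
(size 2), one-point crossover at rate 0.8, per-bit mutation 0.01, elitism
1. One non-obvious operator choice: per-bit mutation on a mostly-zero
336-bit string adds ~3.4 bits per child on average, so a repair that always
trims an oversized child back to the cap drives the whole population to
maximum-size subsets and parsimony can never act. The repair therefore
re-samples the target size uniformly in [1, max] when a child exceeds the
cap, keeping small subsets represented. With this operator the planted
two-descriptor signal is recovered in 10/10 seeds at study scale
(n = 490, pool 336).

**Validation protocol.** The GA's fitness uses only the training split
(80 % of compounds; |train| = round(0.8·n), giving 392/98 for n = 490).
The final model's coefficients are fit on the training set; reported
statistics are training R², held-out test R², all-data R², and LOO q² over
the full table. Fitting the final coefficients on all data instead would
be defensible; the training-set fit was chosen as the standard
anti-leakage protocol, and at these sizes the two differ negligibly.

## Interaction typing

Contacts are typed from geometry alone, ligand's perspective, in this
vocabulary: H-Donor, H-Acceptor, Ionic, H-pi, pi-H, pi-pi. Defaults
(config-exposed):

| kind | rule | default cutoff |
|---|---|---|
| H-Donor / H-Acceptor | donor heavy atom to acceptor heavy atom | ≤ 3.5 Å, D–H–A ≥ 120° where an explicit H exists |
| Ionic | charge-group centers (carboxylate midpoint vs. protonated amine N) | ≤ 4.0 Å |
| pi-pi | ring centroid–centroid, inter-plane angle | ≤ 5.5 Å, ≤ 30° |
| H-pi / pi-H | C–H carrier heavy atom to ring centroid, elevation | ≤ 4.5 Å, ≥ 45° |

The cutoffs were chosen to accept every contact distance printed in the
reference tables this module mirrors (up to 4.19 Å for CH-π, 3.55 Å for the
salt bridge). Conventions:

* Protonation at pH 7: Asp/Glu carboxylates deprotonated; Lys/Arg and
  aliphatic (non-amide, non-aromatic) amines protonated. A pair may yield
  both an H-Donor and an Ionic record — that is the salt-bridge signature.
* Angle checks apply only where an explicit hydrogen is present to measure;
  with implicit hydrogens the distance criterion alone decides ("H
  placeable" is assumed).
* Precedence: carbons of a ring already in a pi-pi contact with a receptor
  ring are not additionally reported as CH-π donors to that same ring;
  otherwise every parallel stack would double-report. Distinct rings and
  distinct carriers still produce separate records.
* Aromatic rings: cycle-basis rings whose atoms all carry the aromatic
  flag (ligand side); fixed atom-name sets for Phe/Tyr/Trp/His (receptor
  side). Residues missing group atoms are skipped for that group with a
  warning.

Population maps count records per residue over a compound set (usually the
lowest-energy pose per compound; ties broken by input order) and report
percentages as 100·count/total rounded to one decimal.

## Synthetic data

`gen_descriptor_table` plants S = −1.26777 − 0.01161·vsurf_S +
0.00007·wienerPath + ε inside a pool of independent Gaussian decoys with
heterogeneous scales. Signal distributions: vsurf_S uniform on
150–1500 Å²; wienerPath log-uniform integers on 50–60000, the span implied
by compounds from phenol to large oligomeric polyphenols. The noise sd
defaults to the value that makes the *population* R² of the planted pair
exactly 0.93 — computed analytically as σ² = Var(signal)·(1−R²)/R², giving
σ ≈ 1.268 kcal/mol — so a recovered fit of the published quality is the
expected outcome, not a tuned one.

What the generator does **not** emulate: real descriptor correlation
structure (decoys are independent; real pools are strongly collinear),
chemically meaningful compound structures, docking-score error structure,
or any receptor dependence. Passing the GA-recovery benchmark therefore
shows the search machinery works at the study's dimensions and noise
level; it does not show that two descriptors would be selected from a real
MOE table.

Toy complexes place one residue and a minimal ligand at exact design
geometry: Glu carboxylate + methylammonium with an in-line N–H at 3.24 Å
(salt bridge), methanol to a backbone carbonyl at 2.9 Å (H-bond), benzene
parallel over a Phe ring at 3.6 Å (pi-pi), methane over the same ring at
3.8 Å (CH-π), and a far-away ligand (none). A Phe-like residue is used for
the aromatic fixtures rather than a Trp-like one deliberately: indole's two
ring centroids are only ~2.1 Å apart, so any ligand stacked on the
six-membered ring also falls inside the centroid cutoffs of the
five-membered ring, and no single-record design geometry exists. A
reference salt-bridge + stacking pocket with a Phe contact is equally
representative for fixture purposes.

## Problem sizes and runtimes

The test suite runs the GA-recovery benchmark at full study scale (490 ×
336, 10 seeds, ~1 s per seed thanks to a centered-Gram subset solver with
a fitness cache), the isosurface calibration at 0.2 Å spacing, and
everything else at desk scale; the whole suite completes in well under a
minute. The pipeline's stage seeds derive from one global seed via SHA-256,
so a run is a pure function of (inputs, config); reruns produce
byte-identical model files, and timestamps appear only in the run log.

## Known limitations

* The surface-area descriptor is an analogue on its own scale; predictions
  from the frozen model using it are internally consistent but not
  numerically comparable to scores computed with the commercial descriptor.
* Interaction typing omits cation-π and halogen bonds, and uses fixed
  residue templates rather than force-field atom typing.
* The PDB reader covers the fixed-column ATOM/HETATM/TER/END subset only
  (no mmCIF, no altloc logic).
* Gasteiger charges are crude for anions/cations; charged ligands fall
  back to the documented united-atom treatment.
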