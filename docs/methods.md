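# Methods

This note documents the model, its parameters and defaults, the synthetic
generators and their limits, and the numerical choices made where the design
was genuinely open.

## Burial level on an atomic contact graph

The pipeline treats a protein complex as a graph of heavy atoms. Two design
commitments shape everything downstream:

* **Buried waters are part of the complex.** Crystallographic waters whose
  oxygen has SASA below the exposure threshold stay in the structure and
  act as ordinary contact-graph nodes. They can deepen the burial of nearby
  atoms (a buried water "shelters" the residues around it), but they never
  count as interfacial contact partners — they belong to neither chain side.
  Exposed waters are bulk solvent and are deleted.
* **Contacts need both a Voronoi facet and a distance gate.** Delaunay
  adjacency alone admits arbitrarily long edges on the convex hull; a
  distance threshold alone admits pairs that are spatially blocked by an
  intervening atom. An edge requires both: Delaunay neighbours with
  d(i, j) < r_i + r_j + 2.75 Å. The inequality is strict; a pair exactly at
  the boundary is not a contact.

Burial levels come from a single-source shortest path: a pseudo node
standing for bulk solvent connects to exactly the exposed atoms, and an
atom's level is its unit-weight distance to that node minus one. With unit
weights, Dijkstra and breadth-first search coincide; the implementation uses
BFS through `scipy.sparse.csgraph`. An equivalent formulation — the minimum
over exposed atoms of the pairwise BFS distance — is used by the test oracle
and must agree exactly. Atoms in fully enclosed pockets with no path to any
exposed atom get an infinite sentinel and a logged warning; they are
excluded from residue means (a residue consisting only of such atoms is an
error, not a silent zero).

### Parameters

| parameter | default | units | notes |
|---|---|---|---|
| probe radius | 1.4 | Å | water-sized probe; standard for SASA |
| sphere points | 960 | – | Shrake–Rupley mesh density |
| exposure threshold | 10.0 | Å² | *inclusive*: SASA = 10.0 is exposed |
| contact pad | 2.75 | Å | diameter of a water molecule |
| ΔΔG hot-spot threshold | 2.0 | kcal/mol | *inclusive*: 2.0 is a hot spot |
| van der Waals radii | C 1.87, N 1.65, O 1.40, S 1.85, P 1.90 | Å | element-keyed JSON, editable |

The radius table and the atom chemistry-class dictionary (positive,
negative, donor, acceptor atoms per residue) ship as JSON data files so an
alternative classification can be substituted without code changes. The
shipped dictionary is a standard reconstruction: charged groups of Arg, Lys,
His (His is treated as positively charged and both ring nitrogens as
donor/acceptor), carboxylates of Asp/Glu and the chain-terminal OXT,
side-chain O–H/N–H bearers and backbone amides as donors (except proline,
which has no amide hydrogen), carbonyl/carboxyl/hydroxyl oxygens, Met SD and
water as acceptors. Water oxygen is both donor and acceptor.

### Open choices, resolved

* **Water-pruning order.** Whether exposure is computed before or after
  removing exposed waters is circular in principle. Default: one SASA pass
  over the full complex supplies both the water pruning and the exposure
  flags of the remaining atoms; a `recompute_after_prune` flag re-labels
  from a second pass for sensitivity analysis.
* **Alternate locations** resolve to the highest-occupancy conformer, ties
  broken by altloc letter, so the graph is built on a single deterministic
  conformer.
* **Degenerate geometry.** Exactly collinear/cospherical inputs can break
  the triangulation; `build_contact_graph` raises with advice to enable the
  deterministic jitter mode (uniform ±1e-6 Å, fixed seed) rather than
  jittering silently.
* **OXT** is kept in the alanine-remainder set {N, CA, C, O, CB, OXT}: the
  chain terminus survives the substitution.

## Feature extraction

For a mutated residue, only *directly broken* interfacial contacts are
counted: the residue-side endpoint must be a side-chain atom beyond Cβ
(removed by the substitution); the partner may be any atom of the opposite
side, backbone included. Glycine and alanine therefore always have empty
counts. Contact types use precedence I > II > III, so a positive–negative
pair that is also donor–acceptor is Type I, and a positive atom facing a
mere acceptor falls through to the Type-II test. Burial bands are fixed at
{0, 1, 2, ≥3}; Type I merges 2 and ≥3 into ≥2 because deeper salt bridges
are vanishingly rare. Interface residues (for filtering mutation tables) are
those with at least one interfacial contact; a ΔSASA-based alternative
definition is deliberately out of scope.

## SVM protocol

The classifier is an RBF-kernel SVM (scikit-learn's LIBSVM binding).
Evaluation is strictly nested: the held-out record's label is never read
before its prediction (an explicit anti-leakage test corrupts the held-out
label and asserts the prediction is unchanged). Inside each outer fold, a
grid search over cost ∈ {2⁻⁵, 2⁻³, …, 2¹⁵} and γ ∈ {2⁻¹⁵, 2⁻¹³, …, 2³}
maximises mean F1 over a seeded stratified 5-fold split; ties go to the
smaller cost, then the smaller γ, making the search deterministic. Features
are min–max scaled to [0, 1] with training-fold statistics only. If an inner
fold loses a class, that grid point scores 0; if an outer training set loses
a class entirely, the fold falls back to majority prediction with a warning.
F1 is defined as 0 when nothing is predicted positive. Leave-n-out mode
partitions the records into seeded random blocks of size n under the same
nested procedure.

The Mann–Whitney U test (ΔΔG of predicted-positive vs predicted-negative
groups, and per-feature class comparisons) is two-sided: exact when the
pooled sample is tie-free and both groups have ≤25 observations, otherwise
the normal approximation with tie correction. Constant feature columns get
p = 1 with a warning.

## Synthetic generators and what they show

* **Lattice blocks** (`make_lattice_block`) are cubic carbon lattices
  (default spacing 3.8 Å) with a sub-milli-Å deterministic jitter to break
  exact cosphericity. They exercise the full SASA → graph → BFS chain
  against an independent brute-force pipeline (Biopython's Shrake–Rupley,
  Delaunay pairs enumerated from simplex lists, networkx BFS) that shares no
  code with the production path.
* **Toy complexes** (`make_toy_complex`) plant a requested number of
  Type-I/II/III cross-chain contacts at a requested burial band. Each
  planted site is a histidine side-chain atom (NE2 for Type I, ND1 for
  Type II, ring carbons for Type III) facing single-atom partner residues
  (Asp OD1, backbone O, Leu CD1) 3.1 Å away, embedded in a solid ball of
  filler carbons on a jittered 3.0 Å lattice. Ball radii of 6.5, 10.0 and
  15.0 Å force burial bands 1, 2 and ≥3; band-0 pairs are left bare. A
  solid ball is used rather than hollow shells because a hollow shell's
  interior cavity gives its atoms enough inner accessible surface to cross
  the exposure threshold and corrupt the planted band. The generator
  validates every emission against the brute-force oracle and refuses to
  emit a composition it could not realise, so test expectations are
  construction-time truths, not recomputed values. Per residue, one Type-I,
  one Type-II and up to three Type-III entries are realisable, each with up
  to six partners.
* **Feature datasets** (`make_feature_dataset`) draw negatives around a
  near-zero centroid and positives shifted by `separation` units of the
  unit-variance Gaussian noise along an elevated burial/deep-count
  direction; count columns are rounded and clipped at zero.

What passing these fixtures does **not** show: real interfaces have
correlated geometry (side-chain packing, backbone continuity, partial
occupancy), waters in networks rather than isolation, and feature
distributions far from isotropic Gaussians. The generators validate the
machinery — exposure labelling, graph construction, shortest paths, typed
counting, the nested protocol — not the biological claim that deeply buried
contacts predict hot spots; that claim rests on the published benchmark.

## Problem sizes and runtime choices

The default test and acceptance runs use sizes chosen to finish in minutes
on one CPU: 5×5×5 lattices, 20 toy complexes (~10–450 atoms each), and a
125-record synthetic benchmark (25 positives). The separable-benchmark
LOOCV runs the full canonical grid (~2 minutes); the permutation-null and
anti-leakage checks, which probe protocol properties rather than grid
coverage, use a 3×3 coarse grid so that 20 null permutations stay tractable.
The four worked-example tests on public complexes (1A22, 1CBW, 1BRS, 1A4Y)
download structures from the PDB archive at run time and are the only part
of the suite requiring network access; chain partitions used there are
growth hormone A vs receptor B, chymotrypsin A/B/C vs BPTI D, barnase A vs
barstar D, and ribonuclease inhibitor A vs angiogenin B.

## Known limitations

* The chemistry-class dictionary is a reconstruction; counts of Type-I/II
  contacts on real structures can shift by ±1 against other reasonable
  dictionaries (hence the tolerance on the worked examples).
* Shrake–Rupley at 960 points carries ~0.3 Å² per-atom sampling noise;
  atoms within that margin of the 10.0 Å² threshold can flip exposure
  between SASA implementations.
* Only the first model of a PDB entry is read; occupancy-weighted ensembles,
  protonation states and hydrogen geometry are out of scope, as are mmCIF
  input and symmetry expansion.
* Euclidean residue depth is related to but intentionally distinct from the
  graph burial level; no depth-based features are provided.
* The headline published benchmark (258 curated mutations over 13 complexes)
  requires dataset curation that is out of scope here; the evaluation layer
  reproduces its printed metrics from the implied confusion counts, and the
  protocol is validated on synthetic benchmarks instead.
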