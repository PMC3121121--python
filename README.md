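# dbac — hot-spot prediction from deeply buried atomic contacts

`dbac` predicts protein–protein binding **hot spots**: interfacial residues
whose mutation to alanine raises the binding free energy by
ΔΔG ≥ 2.0 kcal/mol. It is aimed at structural bioinformaticians who have an
X-ray structure of a complex (crystallographic waters included) and an
alanine-scanning mutation table, and want a fast, geometry-based classifier
instead of an energy-function scan.

## The method

The core descriptor is the **burial level**, defined on an atomic contact
graph rather than on Euclidean depth:

1. **Exposure.** Per-atom solvent accessible surface area (SASA) is computed
   with a 1.4 Å probe (Shrake–Rupley, 960 points). An atom with
   SASA ≥ 10.0 Å² is *exposed*, otherwise *buried*. Exposed waters are bulk
   solvent and are removed; buried waters stay as part of the complex.
2. **Contact graph.** Heavy atoms are nodes; atoms *i, j* are in contact iff
   they share a Voronoi facet (Delaunay neighbours) **and**
   d(i, j) < r_i + r_j + 2.75 Å (the van der Waals radii plus a water
   diameter).
3. **Burial level.** A pseudo node for bulk solvent is attached to every
   exposed atom; the burial level of an atom is its shortest-path length to
   the pseudo node minus one (exposed atoms: 0; neighbours differ by at
   most 1). A residue's burial level (RBL) is the mean over its heavy atoms;
   a contact's level is the smaller of its endpoint levels.
4. **Features.** For a residue, count the interfacial contacts that are
   *directly broken* by alanine substitution — contacts made by side-chain
   atoms beyond Cβ — typed as Type I (positive–negative, salt-bridge-like),
   Type II (donor–acceptor, hydrogen-bond-like) or Type III (everything
   else), with precedence I > II > III. The DBAC feature vector keeps the
   *deeply buried* counts (level ≥ 2):
   `C(I,≥2), C(II,2), C(II,≥3), C(III,2), C(III,≥3)` plus RBL. The AC
   variant adds the exposed (0) and slightly buried (1) bands.
5. **Classifier.** An RBF-kernel SVM evaluated by nested leave-one-out
   cross-validation: for each held-out mutation, (cost, γ) are chosen by an
   inner stratified 5-fold grid search maximising F1 on the training records
   only. Performance is reported as sensitivity, precision, specificity,
   accuracy and F1, and the ΔΔG split between predicted groups is tested
   with a two-sided Mann–Whitney U.

## Worked example

Build a synthetic two-chain complex with a residue planted to make three
deeply buried Type-II contacts, run the pipeline and read its features:

```python
from dbac import (FixtureSpec, PlantedResidue, make_toy_complex,
                  solvate_and_label, build_contact_graph,
                  atom_burial_levels, feature_vector)

spec = FixtureSpec(plants=(PlantedResidue(10, (("II", 2, 3),)),), seed=1)
structure, expected = make_toy_complex(spec)
pruned, flags, _ = solvate_and_label(structure)      # SASA + water pruning
graph = build_contact_graph(pruned, flags)           # Delaunay + distance gate
levels = atom_burial_levels(graph)                   # BFS from bulk solvent
print(feature_vector(pruned, levels, ("A", 10, "")))
```

```
RBL          0.333333
C_I_ge2      0.000000
C_II_2       3.000000
C_II_ge3     0.000000
C_III_2      0.000000
C_III_ge3    0.000000
Name: (A, 10, ), dtype: float64
```

The planted residue averages burial level 0.33 over its six atoms (the
exposed backbone clump sits at level 0, the buried site atom at level 2) and
shows exactly the three planted Type-II contacts in the deeply buried band —
the signature the SVM uses to call hot spots.

Cross-validating the classifier on a synthetic labelled benchmark:

```python
from dbac import HotspotSVM, make_feature_dataset
import numpy as np

x, y = make_feature_dataset(25, 100, separation=5.0, seed=0)
ddg = np.where(y, 4.0, 0.5)
res = HotspotSVM(x, ddg=ddg).fit(protocol="loocv", seed=0)
print(res.summary())
```

```
Hot-spot SVM (RBF), nested cross-validation
protocol: loocv   records: 125   seed: 0
hot spots: 25   non hot spots: 100   ddG threshold: 2.0 kcal/mol
----------------------------------------------------------
TP   24  FP    0  TN  100  FN    1
sensitivity    0.9600
precision      1.0000
specificity    1.0000
accuracy       0.9920
F1             0.9796
Mann-Whitney p (ddG split) 1.954e-27
```

For real structures, the same pipeline runs from the shell:

```bash
dbac run complex.pdb --side-a A --side-b B \
    --mutations muts.csv --mode dbac --out-dir results/
```

which writes `features.csv` (one feature row per mutated interface residue),
`report.json` (confusion counts, the five metrics, Mann–Whitney p, chosen
SVM parameters per fold) and a reproducibility manifest.

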