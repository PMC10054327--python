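# hypercys

Structure- and sequence-based prediction of hyper-reactive druggable
cysteines.

Covalent drugs work by letting a weakly electrophilic warhead form a bond
with a nucleophilic residue of the target — most often a cysteine thiol.
Not every cysteine is equally reactive or accessible: the ones observed
covalently bound to ligands in high-resolution complexes tend to sit in
druggable pockets, be more solvent-exposed, and have a perturbed thiol
pKa. `hypercys` is a toolkit for medicinal chemists and structural
bioinformaticians that turns a protein 3D structure plus an evolutionary
profile into an 80-dimensional per-cysteine feature vector and classifies
each candidate cysteine as covalently targetable or not with a stacked
ensemble of six machine-learning models.

## The model

For each candidate cysteine the package extracts:

**Structure-based (34 features)**

- *SASA–pKa profile (SPP, 18)* — the cysteine's solvent-accessible surface
  area (Shrake–Rupley, deterministic sphere lattice) and thiol pKa, plus
  totals and averages of both quantities over all residues within 4, 6, 8
  and 10 Å shells (`10Å.pka.total`, `4Å.SASA.ave`, …).
- *Pocket profile (PP, 4)* — burial depth of the Sγ atom below the
  accessible surface, and the druggability, hydrophobicity and polarity
  scores of the enclosing detected pocket.
- *Shell amino-acid composition (AAC, 12)* — total, hydrophobic and polar
  neighbor-residue counts per shell under a binary
  hydrophobic/polar partition (hydrophobic = A C F I L M V W Y).

**Sequence-based (46 features)**

- *Conservation profile (CP, 41)* — the 20-column PSSM row at the cysteine,
  smoothed by summing the `ws` surrounding rows (zero-padded at termini;
  `ws` odd, selected by a sweep over 1–23), plus one monogram and 20 bigram
  conservation-transition features built from the logistic-normalized PSSM
  and its consensus sequence.
- *Energy profile (EP, 1)* — a position-specific estimated energy: a ±2
  window sum of burial-weighted residue contact energies,
  `PSEE(i) = Σⱼ (1−rsa_i)(1−rsa_j)·e(aᵢ,aⱼ)`.
- *Secondary-structure profile (SSP, 4)* — helix/strand/coil probabilities
  and relative accessibility, from external predictor files or a built-in
  deterministic propensity fallback.

A feature table of labeled cysteines (1 = covalently modified) then trains
six base learners — KNN, logistic regression, RBF-SVM, gradient-boosted
trees (LightGBM), random forest, and an MLP — each tuned by grid search
under stratified 10-fold cross-validation. A logistic-regression
meta-classifier is trained on the base learners' out-of-fold
probabilities (leakage-free stacking). Reported metrics are CV means of
accuracy, F1, recall and ROC AUC.

## Worked example

Everything below runs on synthetic fixtures generated by the package
itself — a toy α-helical peptide with two cysteines, a random PSSM, and
fabricated pocket/pKa reports:

```bash
hypercys simulate --seed 1 --n-pos 80 --n-neg 80 --effect-size 2.0 --out demo/fixtures
hypercys extract \
    --pdb demo/fixtures/peptide.pdb \
    --pssm A demo/fixtures/peptide.pssm \
    --pocket-report demo/fixtures/pocket_report.txt \
    --pka-report demo/fixtures/pka_report.txt \
    --window-size 21 --out demo/features
hypercys train --table demo/fixtures/planted_table.csv --folds 5 --seed 42 --out demo/model
```

`extract` prints

```
wrote 2 sites x (34 structure + 46 sequence) features
```

and writes `structure_features.csv` / `sequence_features.csv` with one row
per cysteine (here `peptide:A:4` and `peptide:A:23`). `train` fits the
stack on the planted-signal table (160 rows, a 2-SD mean shift on eight
informative columns for the positive class) and prints the CV report:

```
          ACC    F1  RECALL  ROC AUC
KNN     0.969 0.967   0.963    0.995
LR      0.988 0.987   0.988    0.999
SVM     0.994 0.994   1.000    0.998
LGBM    0.975 0.975   0.975    0.998
RF      0.988 0.987   0.988    0.998
MLP     0.981 0.981   0.975    0.998
stacked 0.981 0.981   0.988    0.999
```

Near-perfect scores are expected here: the planted signal is strong by
construction. On real data the numbers reflect how separable covalent and
noncovalent pocket cysteines actually are. `predict` scores new feature
rows with a saved bundle; `evaluate` recomputes the metrics from saved
predictions; `sweep` repeats training across window sizes and reports the
best.

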