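# Methods

## Problem and scope

The package classifies candidate cysteines in protein–ligand complex
structures as hyper-reactive/druggable (observed covalently bound) versus
noncovalent pocket cysteines on the same targets. It covers feature
extraction from structures, profiles and external-tool reports; benchmark
table construction; and a stacked ensemble classifier. It does not run
the upstream tools themselves: PSI-BLAST profiles, pocket-detector
reports and pKa-predictor reports are inputs (with built-in fallbacks for
the last two), and pocket detection, homology search and empirical pKa
calculation are out of scope.

## Structure descriptors

**Neighbor shells.** A residue belongs to the r-Å shell of a cysteine if
the minimum heavy-atom pair distance between the two residues is ≤ r,
with r ∈ {4, 6, 8, 10}. The cysteine itself is excluded; hydrogens are
ignored; HETATM groups and waters are excluded by default (a flag
includes hetero groups). This minimum-heavy-atom convention is
parameter-free and matches common pocket-shell practice. Shell counts are
split hydrophobic/polar by a configurable binary partition (default
hydrophobic = {A, C, F, I, L, M, V, W, Y}); unknown residues are counted
and classified polar with a warning.

**SASA.** Shrake–Rupley with a deterministic golden-spiral lattice of
960 points per atom and a 1.4 Å probe. A deterministic lattice was chosen
over Monte-Carlo sampling so that every downstream feature is
byte-reproducible; the isolated-atom area is exact to well under 2% at
this point count. The lattice is fixed in the laboratory frame, so total
SASA is exactly translation-invariant and rotation-invariant only up to
lattice discretization; an optional rotation argument co-rotates the
lattice when exact invariance is needed.

**Burial depth.** Depth of the cysteine Sγ (fallback Cβ, then Cα, with a
warning) is `max(0, min‖x_SG − p‖ − (r_SG + r_probe))` over all
accessible lattice points p of the molecule. A fully exposed sulfur
therefore has depth ≈ 0. This surface-point approximation replaces
bulk-solvent placement schemes; it preserves the burial semantics without
a solvent-box dependency but saturates inside fully enclosed cavities,
where no accessible points exist nearby.

**SASA–pKa shell profile.** Per shell: SASA total and average over all
member residues; pKa total and average over the members that have a pKa
(the ionizable set D, E, H, C, Y, K, R — predictor reports contain no
others). Empty shells contribute zeros; averages are over the
contributing subset only, so `ave × count = total` holds exactly. Site
pKa comes from a parsed predictor report or, when enabled, from an
intrinsic side-chain table (D 3.8, E 4.5, H 6.5, C 9.0, Y 10.0, K 10.5,
R 12.5); a missing site pKa with no fallback is an error, never imputed.

**Pockets.** Pocket membership is by residue list; a cysteine in several
pockets is assigned the one with the highest druggability score. The
"Atom Depth" feature is implemented as the cysteine Sγ burial depth (the
alternative pocket-level reading was rejected as less site-specific).

**PDB parsing.** Fixed-width ATOM/HETATM parsing with explicit altloc
resolution: the highest-occupancy conformer wins, ties break
alphabetically. Malformed records raise an error naming the line. Van der
Waals radii come from a built-in element table (Bondi-style values,
default 1.70 Å for unknown elements).

## Sequence descriptors

**Smoothed PSSM.** Row i of the smoothed profile is the sum of source
rows i−(ws−1)/2 … i+(ws−1)/2, with zero vectors padding both termini;
ws is odd in [1, 23] and ws = 1 is the identity. Smoothing applies to the
raw integer PSSM only; the smoothed rows (not the raw ones) enter the
feature vector, since capturing local context is the point of the
encoding.

**Monogram/bigram.** The PSSM is squashed elementwise by the logistic
function, and the consensus sequence is the per-row argmax (ties break in
PSI-BLAST column order A R N D C Q E G H I L K M F P S T W Y V). Then
MG(i) is the normalized score of the consensus residue at i, and
BG(n, i) = MG(i) × normalized(i+1, n), with a zero final column. The
cited bigram construction produces sequence-level 20×20 matrices; these
per-position definitions were adopted to obtain the required 1×L and
20×L shapes while preserving the "consensus residue replaced by another"
semantics.

**PSEE.** `PSEE(i) = Σ_{j≠i, |i−j|≤2} (1−rsa_i)(1−rsa_j)·e(aᵢ,aⱼ)` with a
symmetric 20×20 contact potential and relative accessibility rsa from the
SSP block (out-of-range values are clipped with a warning). The default
potential is an additive approximation to the Miyazawa–Jernigan contact
energies, `e(a,b) = (e_aa + e_bb)/2` built from the same-residue MJ
values; this hydrophobic-factorization form captures the dominant
one-body structure of the full table and is exactly symmetric by
construction. Both the table and the half-window are configurable.

**SSP fallback.** When no external secondary-structure/accessibility
predictions are supplied, Chou–Fasman-type helix/strand/turn propensities
are averaged over a ±3 window and normalized to probabilities, and
relative accessibility is mapped linearly from the Kyte–Doolittle
hydropathy scale (hydrophobic → buried). The fallback is deterministic
and exists so the pipeline runs end-to-end without external predictors;
it is not a competitive secondary-structure predictor.

## Dataset construction

Cysteines matching a covalent annotation are labeled positive; other
pocket cysteines are negative; cysteines outside every pocket are
dropped (annotated sites are kept regardless, since an observed adduct
implies a binding site). Annotations that match no extracted cysteine
are an error. Pocket filtering is applied before redundancy filtering.

Sequence redundancy is reduced by a deterministic greedy filter: ids are
visited by descending sequence length (ties lexicographic), and a
sequence joins an existing representative when its global
Needleman–Wunsch identity (match 1 / mismatch 0 / gap −1; identity =
matches ÷ alignment length including gaps) reaches the threshold
(default 0.5). An adapter also accepts a precomputed `.clstr` cluster
file. Feature assembly is a strict inner join on site keys — mismatched
keys and missing values are errors, never imputed. Summary statistics use
linear-interpolation quartiles and the population (n) standard
deviation.

## The stacked ensemble

Base learners and default grids (all seeded from one config):

| learner | grid |
|---|---|
| KNN | k ∈ {3, 5, 7, 9, 11} |
| LR | C ∈ {0.1, 1, 10} |
| SVM (RBF) | C ∈ {0.1, 1, 10}, γ ∈ {scale, 0.01, 0.1} |
| LGBM | leaves ∈ {15, 31}, trees ∈ {100, 300}, lr ∈ {0.05, 0.1} |
| RF | trees ∈ {200, 500}, depth ∈ {∞, 8} |
| MLP | hidden ∈ {(64,), (128, 64)}, α ∈ {1e-4, 1e-3} |

Each learner is a pipeline with per-feature standardization fitted from
training-fold statistics only. The SVM produces probabilities through
cross-fitted sigmoid calibration (`CalibratedClassifierCV(SVC(),
ensemble=False)`) rather than SVC's built-in Platt scaling, whose
estimates can invert on small samples.

Protocol: per learner, one grid search maximizing accuracy over a
stratified k-fold split (k = 10 by default, shuffled with the run seed);
the tuned learners then produce out-of-fold probabilities over those same
folds; the logistic-regression meta-classifier is trained on the
out-of-fold matrix. Per-fold stacked metrics are computed with the meta
model refit on the remaining folds each time, so no row's stacked score
was influenced by its own label. Base learners are refit on all data for
deployment. Grid search is performed once on the full table rather than
nested inside each outer fold — the same folds serve model selection and
reporting, which mildly favors the selected hyperparameters; the bundle
manifest records grids, chosen parameters, seed and column order.

The window-size sweep retrains the full stack per ws and picks the
highest CV accuracy, ties to the smaller window.

Grouped feature importance fits a 500-tree random forest on the full
table and sums normalized impurity importances per feature group, plus a
structure-based (SPP + PP + AAC) versus sequence-based (CP + EP + SSP)
aggregate. Impurity importances are biased toward high-cardinality
continuous features, which all 80 features are, so the bias is roughly
uniform here.

Evaluation: accuracy (TP+TN)/N, recall TP/(TP+FN), F1 as the harmonic
mean of precision and recall (0 when undefined), ROC AUC as the
Mann–Whitney statistic with half credit for ties. The positive class is
covalent. Single-class label vectors make ROC AUC undefined and raise.

## Synthetic data

The generator emulates every pipeline input: ideal α-helical peptides
(1.5 Å rise, 100°/residue, 2.3 Å radius; backbone + Cβ + Sγ, so burial
and shell features have realistic exposed-surface gradients), integer
PSSMs uniform on [−8, 8] with a +4 self-column conservation boost and
optional injected motif rows, one fabricated pocket containing all
residues with a druggability score in [0.3, 0.9], and pKa lines at
intrinsic values ± N(0, 0.3).

Planted-signal tables draw all 80 features standard normal and shift
eight designated columns (two site SPP values, two 4 Å shell averages,
the druggability score, and one each of the PSSM/monogram/PSEE columns —
the feature types the real signal is expected to live in) upward by the
effect size, in SD units, for the positive class. The default condition
for performance checks is n = 400 balanced at effect size 2, which is
strongly separable by construction; effect size 0 is the permutation
null. What passing shows: the pipeline recovers a mean-shift signal of
known location and strength and is honest under the null. What it does
not show: performance on real cysteines, where features are correlated,
class-imbalanced, non-Gaussian and far weaker — absolute benchmark
metrics require the external curated complex set and real evolutionary
profiles, which are deliberately not bundled.

## Numerical choices and reproducibility

- All randomness flows from explicit integer seeds; LightGBM runs
  single-threaded deterministic, and the CV splitter, grid search and
  meta fit are seeded, so a fixed-seed rerun reproduces feature CSVs,
  metrics and the bundle manifest byte-for-byte.
- Ties: altloc by occupancy then letter; consensus by column order;
  window sweep by smaller ws; overlapping pockets by druggability score.
- Degenerate inputs fail loudly (empty structures, single-class labels,
  n < k, mismatched PSSM/chain sequences, out-of-schema columns) rather
  than being silently patched.
- Test and acceptance problem sizes (n = 400 tables, ≤ 25-residue
  peptides, 960 lattice points) were chosen as the smallest scales at
  which the statistical assertions are stable.

## Known limitations

- The depth measure saturates for cysteines inside sealed cavities.
- The additive contact potential ignores the mixing (two-body residual)
  part of the full Miyazawa–Jernigan table.
- The propensity SSP fallback is far weaker than modern predictors;
  PSEE inherits its accessibility estimates when no external predictions
  are given.
- The greedy identity filter is exact but O(n²) in alignments; for large
  sequence sets a precomputed cluster file is the intended path.
- Grid search shares folds with metric reporting (see above); treat
  reported CV means as model-selection-optimistic by a small margin.
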