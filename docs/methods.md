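# Methods

## Model

`nrpcm` treats binder prediction as binary classification over
(compound, receptor) pairs. The input concatenates a 30-dimensional
protein block and a 187-dimensional ligand block; the default learner
is a random forest whose score — the fraction of trees voting active —
is read as a binding probability. The underlying assumptions are the
usual proteochemometric ones: receptors with similar sequences bind
similar chemistry, so a similarity profile against a fixed panel is an
adequate receptor representation, and the activity signal is carried by
interactions between that profile and interpretable 2-D ligand
properties rather than by either block alone.

### Protein block

The descriptor of a query receptor is its Smith–Waterman local
alignment score against each of 30 panel sequences, normalized by the
geometric mean of the two self-scores:
`SW(q, r) / sqrt(SW(q, q) · SW(r, r))`. This normalization was chosen
over query-self-score division because it is symmetric, bounded in
[0, 1], and exactly 1 at identity; the alternative remains selectable.
Alignment uses BLOSUM62 with affine gaps, open 10 and extend 0.5 (the
EMBOSS `water` defaults), a gap of length *k* costing
`open + (k − 1)·extend`; all three parameters are serialized with every
trained model. Alignment is delegated to Biopython's
`PairwiseAligner`; the test suite checks it against an independent
three-state dynamic program on hundreds of short pairs. Ambiguity
codes (B/Z/X) are rejected by default and scored through the matrix's
ambiguity rows when explicitly allowed. The panel is an ordered FASTA
file; order defines the descriptor axes and is part of the model
archive.

### Ligand block

Ligand features are 187 two-dimensional RDKit descriptors taken from a
version-pinned manifest (one name per line). The default manifest is
the first 187 registry descriptors in alphabetical order — a
deterministic choice that users can replace wholesale with their own
curated list; every model embeds its manifest, so provenance is never
ambiguous. Descriptors that fail or return non-finite values are
imputed as 0 and logged; tree ensembles are insensitive to the sentinel
value. No 3-D descriptors (they would demand conformer generation the
model does not need) and no hashed fingerprints in the default model —
descriptor inflation tends not to help on NR panels, and interpretable
tabular features suit tree learners. There is no feature scaling at
this stage; standardization is a model-side concern.

### Labels

EC50 values are dichotomized at 1 μM, boundary inclusive (active iff
EC50 ≤ 1 μM), the conventional potency cutoff for NR ligands; both the
threshold and the unit conversion (nM/μM/mM/M/pM → μM) are handled by
the CSV reader. A record carrying both an EC50 and a label is rejected
if they disagree.

### Augmentation

Bioactivity panels are imbalanced, so before fitting, each target's
examples are resampled with replacement to `n_per_target / 2` per class
(originals count toward the quota and are kept noise-free). Duplicated
rows receive i.i.d. Gaussian noise with σ = 0.1 applied in z-standardized
feature space — statistics fit on the un-augmented training set — and
mapped back, so one σ has the same meaning for the forest (which
consumes raw features) and the MLP (which consumes standardized ones).
The 50/50 class split is a design choice: the augmentation exists to
counter imbalance, and balancing exactly is the simplest policy that
does. `n_per_target` defaults to 5000; the supported sweep is
1000–5000 in steps of 500.

### Learners

Random forest: 500 trees, unlimited depth, sqrt-features per split,
seeded; these defaults sit on the performance plateau for this feature
set, and everything is configurable. MLP baseline: 217 → 5 × 300 ReLU
layers → 1 sigmoid output, trained with Adam, early stopping on a 10%
carve-out, max 200 epochs, on standardized features. The configured
dropout rate (0.5) is recorded but not applied — scikit-learn's
perceptron has no dropout layer, so regularization is L2 weight decay
plus early stopping instead. The forest is the shipped default; the
MLP exists for comparison and is noticeably less stable on small
panels.

### Scores and calls

Scores map to tri-level calls with strict upper comparisons: high iff
score > 0.7, medium iff 0.5 < score ≤ 0.7, low otherwise. Screening
supports two positivity cutoffs — level 1 (normal, > 0.5) and level 2
(strict, > 0.7). All threshold metrics use the same strict rule
(positive iff score > cutoff), so a score exactly at a cutoff is a
negative call everywhere.

## Evaluation protocol

ROC-AUC (ties counting one half) is the headline metric, delegated to
scikit-learn and verified against exhaustive pairwise concordance in
tests. Threshold metrics report accuracy, precision, recall, F1 and
FPR; ratios with empty denominators are reported as 0 with an explicit
degenerate flag rather than NaN. The balanced-accuracy cutoff scan
evaluates every distinct operating point — midpoints between
consecutive distinct scores plus the endpoints 0 and 1 — and breaks
ties toward the smallest cutoff. The train-fraction × oversampling
grid (9 fractions 0.50–0.90 × 9 counts 1000–5000 = 81 cells) fits one
seeded stratified split per cell, selects the best cell by validation
ROC-AUC (ties toward larger fraction, then larger count), and records
cell failures without aborting the sweep. Each cell uses a single
seeded split; averaging over repeats is done by re-running the sweep
with different seeds. Splits are stratified by label within target by default so
every receptor keeps both classes on both sides; a compound-level split
mode holds out whole compounds for the stricter regime.

## Matched molecular pairs

Single-cut MMPs only: every acyclic single bond between heavy atoms is
cut, fragments are canonicalized with a bare `[*]` attachment marker,
the larger fragment (heavy atoms, canonical-SMILES order on ties) is
the core, and substituents larger than 33% of the parent's heavy atoms
or 13 heavy atoms are discarded — common MMP practice, both limits
configurable. Pairs are found by indexing cuts on their canonical
core; two compounds sharing a core with differing substituents form
one pair per shared core. The chemical-space network has compounds as
nodes (annotated with the argmax screening target, first-in-order
tie-break), pairs as edges, and connected components as the scaffold
series; components stand in for "clusters" because they need no tuned
threshold. Export is GraphML plus an edge-list CSV.

## Synthetic study generator

The generator emulates the shape of an NR bioactivity study: a
30-member panel in 4 families (each member a per-site mutant of its
family ancestor at rate 0.05 — high enough to separate members, low
enough that within-family similarity far exceeds between-family), 300
compounds from a small grammar (alkyl chain of 1–20 carbons, benzene
ring with probability 0.35, head group carboxyl/amide/methoxy/none at
0.35/0.15/0.15/0.35), 5 modeling targets cycling through the families,
and 2 further targets excluded from training to emulate external
validation on unseen receptors. Activity comes from a planted
family × trait rule (e.g. family 0 binds long-chain carboxylic acids)
whose per-family base rates are deliberately comparable (~0.15–0.30),
so the protein block alone carries almost no marginal signal; labels
are flipped with probability 0.05, and EC50 values are drawn
log-uniformly on [0.001, 1] μM for actives and (1, 100] μM for
inactives so dichotomization reproduces the label exactly, including
at the boundary. Noise draws are re-seeded until every training target
retains both classes (with these defaults the first draw virtually
always suffices). Everything is deterministic under one seed.

What the fixtures do *not* emulate: real NR sequence conservation
(random ancestors, uniform mutation), real chemistry (a toy grammar,
no stereochemistry, no scaffold diversity beyond chains/rings/head
groups), assay noise structure, or activity cliffs. Passing tests
therefore demonstrate that the pipeline recovers a planted
protein–ligand interaction of the kind PCM assumes — not that it
reaches any particular accuracy on real receptor panels.

## Problem sizes and numerical choices

The test suite and the acceptance script run the study at desk scale:
forests of 50–200 trees (the AUC on the synthetic study plateaus well
below the 500-tree default), ablation and transfer fits at 1000
examples per target, and the flagship regime (85% / 5000 / σ 0.1) with
100–200 trees. The synthetic defaults give ~0.90–0.95 held-out AUC
against a noise ceiling of ≈ 0.95 (5% label flips bound the best
possible AUC), near-chance AUC for the protein-only ablation and for
shuffled labels, and > 0.8 AUC on receptors held out of training.
Determinism is end-to-end: a single seed fixes the generator, the
split, the augmentation and the learner, and the full
simulate → train → predict → evaluate chain is byte-identical across
runs.

## Known limitations

- The default descriptor manifest is a deterministic stand-in, not a
  curated list; substitute a domain-validated manifest for real work.
- The default reference panel is whatever FASTA the user supplies; the
  package ships no receptor sequences.
- Single-cut MMPs only; double-cut support is reserved.
- No probability recalibration; scores are raw ensemble fractions.
- Record-level splitting (the default) lets the same compound appear on
  both sides of a split against different targets; use the
  compound-level split for the stricter reading.
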