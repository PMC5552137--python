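# Methods

## Candidate sites and windows

Every asparagine in a protein is a candidate N-linked glycosylation site.
Candidates are represented by fixed-length windows of 2r+1 residues centered
on the site; the default r = 20 (41-mers) balances context against sparsity
and is exposed as a parameter.  Windows that overrun a terminus are
zero-padded rather than dropped, so terminal sites remain predictable and
every window shares one coordinate system; padding (code 0) is invisible to
the composition/position extractors but does shift the ordinal positions of
real residues in terminal windows.  Residue coding is alphabetical
(A=1 … Y=20) — any consistent bijection carries the same information, and
reserving 0 for padding keeps padding distinguishable from every real
residue.  Non-standard letters (B, J, O, U, X, Z) also map to 0; this is
lossy but lets real database sequences parse.

## Feature extraction

The 173-coefficient layout is the concatenation SVV(41) ‖ FM(20) ‖
AAPIV(20) ‖ RAAPIV(20) ‖ moments(7×7 grid, 24) ‖ moments(PRIM, 24) ‖
moments(RPRIM, 24), with each moment block ordered raw(8), central(8),
Hahn(8) over the index pairs (00, 01, 10, 11, 12, 21, 30, 03).  Design
choices that were genuinely open:

* **Grid construction.** A k-residue window fills an n×n grid row-major with
  n = ⌈√k⌉ (7 for 41-mers); element m (0-based) lands at row ⌊m/n⌋, column
  m mod n; trailing cells are zero.
* **Moment coordinates.** Raw/central moments index the grid 1..n; starting
  at 0 would annihilate first-row/column contributions to M10/M01.  Hahn
  moments index 0..N−1, the natural domain of the discrete polynomials.
* **Hahn polynomials.** The classical discrete Hahn family h_n^{(u,v)}(x, N)
  ∝ ₃F₂(−n, n+u+v+1, −x; u+1, 1−N; 1) with weight
  ρ(x) = Γ(u+x+1)Γ(v+N−x) / (Γ(x+1)Γ(N−x)) and the classical closed-form
  square norm; the basis used for moments is h̃_n = h_n √(ρ/d_n²), which is
  orthonormal (verified to ~1e−13 at N=7, ~1e−7 at N=20; only orders ≤ 3
  enter features, where precision is far better).  Parameters default to
  u = v = 0, the symmetric choice, and are configurable.  All
  Pochhammer/Gamma products are evaluated as signed log-space sums so the
  20×20 incidence matrices do not overflow.  Orthonormality makes the full
  transform invertible, so the moment description provably preserves the
  window's positional information.
* **PRIM "relative position"** is the signed difference (p_j − f_i) summed
  over all occurrences of residue j, where f_i is the first occurrence of
  residue i; occurrences before f_i contribute negatively.  This is the
  deterministic reading that preserves the most ordering information.
  Positions are window-local (1..41), not protein-global.
* **Degenerate grids.** An all-zero matrix has no centroid; its
  central-moment block is defined as zeros so all-pad windows featurize.
* **Standardization.** Features are shifted/scaled to zero mean and unit
  spread *estimated on the training split only* (refit inside every CV
  fold).  Moment magnitudes span many orders of magnitude and gradient
  descent needs comparable scales; constant features fall back to spread 1.
  The SVV enters as raw integer codes before standardization.

## Network and training

One hidden layer of 20 logistic-sigmoid units and a single sigmoid output
(both configurable) is the smallest architecture faithful to the multilayer
back-propagation design; the loss is plain mean squared error.  Training is
full-batch gradient descent with an adaptive learning rate: a step that does
not increase the loss is accepted and γ is multiplied by 1.05; otherwise the
weights are discarded, γ is multiplied by 0.7, and the step is retried with
the same gradient.  The accepted-loss sequence is therefore non-increasing
by construction, which doubles as a runtime invariant.  Defaults: γ₀ = 0.5,
at most 1000 epochs, stop when an accepted improvement falls below 1e−9;
weights initialize uniform in ±1/√fan-in from a seeded generator, so
training is bit-reproducible.  Momentum, regularization, mini-batching and
validation-based early stopping are deliberately out of scope.  The decision
threshold is 0.5 with ties called positive.

## Evaluation protocol

* **Self-consistency**: train on everything, test on everything — an
  optimistic ceiling, reported with confusion counts, Sn/Sp/Acc/MCC and a
  threshold-sweep ROC (trapezoidal AUC, which equals the Mann–Whitney
  statistic normalized by n₊ n₋).
* **k-fold cross-validation** (default k = 10): stratified balanced folds
  that are exact partitions (cover, disjoint, sizes within 1); scaler and
  network refit per fold; the aggregate mean accuracy and per-class
  (positive-site / negative-site) accuracies are both reported.
* **Jackknife**: each selected sample is tested against a model trained on
  all other samples; full leave-one-out is quadratic in training runs, so a
  seeded 100-sample estimation is the default mode.
* Metrics with zero denominators are reported as undefined (`None`), never
  silently zeroed.  Four-decimal presentation follows the truncation
  (not rounding) convention of this literature.

## Synthetic benchmark

The generator emulates the one biological invariant the predictor assumes:
the N-X-[S/T] sequon.  Windows carry N at the center; positives draw S or T
at center+2 with probability 0.95 and suppress proline at center+1;
negatives carry the sequon with probability 0.05; all other positions are
uniform over the 20 residues.  The default benchmark is 200+200 windows.
These defaults are the package's study conditions and are not tuned.

What the generator does **not** emulate: the broad flanking-composition
biases of real glycosylated sites, homology structure between windows,
database annotation noise, and corpus scale (tens of thousands of windows).
Consequences measured on the default benchmark (seeded runs, recomputed by
`scripts/acceptance.py`):

* self-consistency is essentially perfect (≈ 99–100% accuracy, AUC ≈ 1),
  and is always ≥ the cross-validated accuracy;
* held-out accuracy is far lower (10-fold CV ≈ 68–71%, estimated jackknife
  ≈ 72%): with a uniform background the only generalizable signal is a
  two-sided threshold on one ordinally-coded coordinate, and a smooth
  network trained by unregularized gradient descent fits the 172
  uninformative coordinates instead.  Reference implementations of the
  same model class (scikit-learn MLPs under several solvers and penalties)
  score the same on these features, while an axis-splitting learner
  (random forest) reaches ≈ 0.93 — the gap is a property of the model
  class on this synthetic task, not of the feature extraction or trainer,
  and passing tests on this benchmark accordingly certify the pipeline's
  mechanics, not real-data accuracy;
* at zero sequon separation the classes are exchangeable and CV accuracy
  sits at chance (≈ 0.5), confirming no information leak anywhere in the
  harness (scaler and folds included).

## Numerical and degenerate-input conventions

Ties in ROC scores are handled by sweeping unique score values (descending),
equivalent to midrank AUC.  `kfold` requires 2 ≤ k ≤ n.  ROC requires both
classes present.  Empty windows, empty training sets, unfitted scalers,
out-of-range sites and malformed table rows raise typed errors, with line
numbers for table parsing.  Training aborts with a diagnostic on non-finite
loss; the learning rate is kept positive and the loop exits if it underflows
below 1e−15.

## Problem sizes

Default test-suite and acceptance-script sizes (hundreds of windows, ≤ 1000
training epochs, 100 jackknife iterations) were chosen so a full run
completes in about a minute on one core while still exercising every code
path at the benchmark's standard 41-mer / 173-feature geometry.
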