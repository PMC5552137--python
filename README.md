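# glycosite

Prediction of N-linked glycosylation sites in protein primary sequences.

N-linked glycosylation — attachment of an oligosaccharide to the side-chain
nitrogen of an asparagine, almost always within the N-X-[S/T] sequon
(X ≠ proline) — shapes protein folding, trafficking and stability, and its
failure modes are implicated in disease.  Experimentally mapping which
asparagines are actually glycosylated is slow and expensive, so sequence-based
predictors matter.  `glycosite` implements one such predictor end to end, for
bioinformaticians who want a transparent, fully inspectable pipeline: every
feature, the network, and the whole evaluation protocol are plain Python on
NumPy.

## The method

Every asparagine is a candidate site.  Each candidate is represented by its
**site vicinity vector** (SVV): the 41-mer window `α(q−20) … α(q) … α(q+20)`
centered on the site, with residues integer-coded (A=1 … Y=20, 0 for padding
or non-standard letters).  From each window the pipeline derives a
173-coefficient feature vector:

| block | dim | contents |
|---|---|---|
| SVV | 41 | raw residue codes |
| FM | 20 | per-residue frequency τᵢ |
| AAPIV | 20 | μᵢ = Σ of 1-based positions where residue *i* occurs |
| RAAPIV | 20 | the same on the reversed window |
| grid moments | 24 | raw, central and Hahn moments of the 7×7 row-major grid |
| PRIM moments | 24 | the same moments of the 20×20 position-relative incidence matrix |
| RPRIM moments | 24 | the same of the reverse-sequence PRIM |

PRIM entry *A(i→j)* sums the positions of every occurrence of residue *j*
relative to the first occurrence of residue *i*; the moment families are
`M_ij = Σ p^i q^j β_pq`, the centered version `η_ij`, and projections `H_ij`
onto the orthonormal discrete Hahn polynomial basis — all up to order 3, as
the 8-tuple (00, 01, 10, 11, 12, 21, 30, 03).  None are scale-invariant,
deliberately: the point is sensitivity to sequence order.

A feed-forward sigmoid network (173 → 20 → 1 by default) is trained by
full-batch back-propagation, `θ ← θ − γ∇K(θ)` on mean squared error, with an
adaptive learning rate: steps that lower the loss are accepted and γ grows;
steps that raise it are discarded and γ shrinks, so the accepted-loss
sequence K(θ₀) ≥ K(θ₁) ≥ … is non-increasing by construction.

Evaluation follows the standard protocol: self-consistency (resubstitution),
stratified k-fold cross-validation with per-class accuracies, estimated or
full leave-one-out jackknife, sensitivity/specificity/accuracy/MCC, and a
threshold-sweep ROC with trapezoidal AUC.

Because the curated database corpus is not bundled, a seeded synthetic
generator produces labeled 41-mer windows with the sequon structure the
predictor assumes (S/T at center+2 with probability 0.95 for positives,
0.05 for negatives, by default), so the whole pipeline runs and is tested
without any download.

## Worked example

```
$ glycosite simulate --n-pos 100 --n-neg 100 --sep 0.9 --seed 42 --out windows.tsv
wrote 200 windows to windows.tsv
$ glycosite train windows.tsv --out model.json --seed 0
trained 447 epochs, final loss 0.00500002; model saved to model.json
$ glycosite evaluate windows.tsv --mode self --seed 0
{
  "mode": "self-consistency",
  "confusion": { "tp": 99, "fn": 1, "fp": 0, "tn": 100 },
  "metrics": { "sn": 0.99, "sp": 1.0, "acc": 0.995, "mcc": 0.9900495037128093 },
  "auc": 0.9901999999999999
}
```

The confusion matrix says the trained network re-classifies its own training
set almost perfectly (one false negative, no false positives); `sn`/`sp` are
the per-class recall rates, `mcc` the Matthews correlation, and `auc` the
area under the resubstitution ROC.  Self-consistency is an optimistic
ceiling — use `--mode cv` (10-fold cross-validation) or `--mode jackknife`
for held-out estimates, and see `docs/methods.md` for what held-out accuracy
on this synthetic benchmark does and does not show.

The same steps are available as library calls (`generate_dataset`,
`feature_matrix`, `fit_model`, `self_consistency`, `cross_validate`,
`jackknife`), and `glycosite windows proteins.fasta --out candidates.tsv`
extracts candidate windows from real FASTA input.

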