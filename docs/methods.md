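# Methods

This note records the modeling choices, defaults, and limitations of the
package, in the spirit of a methods appendix. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Problem setting

Binary classification of gene sequences: *normal* reference sequences versus
*mutated* sequences carrying point substitutions (the driver-mutation
setting in cancer genomics). Real cohorts are built by applying curated
mutation tables to reference sequences; because such cohorts are typically
not redistributable, a seeded synthetic generator provides a fully
specified stand-in for development and validation.

## Cohort construction

Mutation records are point substitutions `(gene, 1-based position, ref,
alt)`. Applying a record verifies the reference allele at the site and
fails loudly on mismatch — silent application would mislabel training data,
which is worse than losing a record. Positions are converted to 0-based
indexing exactly once, at application time. Insertions/deletions are out of
scope. A mutation table can yield one mutated sequence per record
(default) or one combined sequence per gene carrying all its records.

Redundancy reduction is a built-in exact-duplicate collapse within each
label stratum, with an optional greedy identity-threshold clustering
(exact-match identity over the shorter length, first-seen representative
kept). It replaces an external clustering tool at desk scale; it performs
no alignment.

## Synthetic generator (the stated world)

Defaults, chosen once: 100 genes, lengths uniform in **50–60 nt** (short
desk-scale sequences that fit the models' fixed 64-token input window),
uniform ACGT composition, **2 point mutations per gene** at distinct
positions, one mutated counterpart per gene. Signal modes shape the mutated
class only:

- `motif`: with probability `signal_strength`, the fixed CpG-repeat 16-mer
  `GCGCGCGCGCGCGCGC` overwrites a random window of the mutated sequence
  after the point mutations. The motif was chosen long (≈30 % of a default
  sequence) and compositionally extreme deliberately: the moment features
  aggregate over the whole sequence, so only a signal that shifts global
  composition/position statistics is visible to them, and a short motif
  diluted over the sequence is *not* class-separating in that feature space
  (measured with an independent linear probe). At strength 1.0 the motif is
  present in every mutated sequence and the classes are separable.
- `biased_substitution`: with probability `signal_strength`, the alternate
  allele is the transition partner (A↔G, C↔T) instead of a uniform draw.
  This biases *which* substitutions occur but leaves sequences almost
  identical to their references; it is a weak signal by construction.

What a green recovery test establishes: the pipeline can learn a fully
penetrant, compositionally strong class signal from ~400 sequences. What it
does not establish: performance on real cohorts, where signals are sparse,
heterogeneous, and entangled with phylogeny and gene identity; nor
robustness to class imbalance (the generator emits balanced cohorts);
nor anything about indels or structural variation.

A motif implant deliberately lies *outside* the mutation records, so the
record-inverse round trip (apply alt→ref to recover the reference) is exact
only for cohorts without implants; round-trip properties are therefore
stated and tested with `signal_mode="none"`.

## Feature extraction

A sequence of length L is encoded A=1, C=2, G=3, T=4, N=0 and written
row-major into the smallest square grid (side ⌈√L⌉, zero-padded). Zero
carries no weight in any moment, so padding and ambiguity codes are
invisible by construction.

Moments up to total order 3 — the ten (p,q) pairs with p+q ≤ 3 — are taken
of three grids: the sequence matrix, PRIM, and RPRIM.

- Raw: `R_xy = Σ_g Σ_h g^x h^y δ_gh` over 1-based indices (g rows, h
  columns).
- Central: about the intensity centroid (R10/R00, R01/R00); a zero-mass
  grid falls back to the geometric center with a warning.
- Hahn: projections onto discrete Hahn polynomials evaluated by their
  finite Pochhammer sum, with shape parameters a=b=0 by default
  (configurable). Normalization is the standard weighted square-norm
  (`h̃_m(x) = h_m(x)·√ρ(x)/√Σ_x ρ(x)h_m(x)²`), which for a=b=0 reduces to
  dividing by the Euclidean norm. For 2×2 and 3×3 grids, orders above the
  support size use the same finite sum (still well defined); orthogonality
  is not claimed there.

PRIM entry (i→j) accumulates positional offsets k−f_i over occurrences of
nucleotide j after the first occurrence f_i of nucleotide i; rows of absent
nucleotides are zero. RPRIM is PRIM of the reversed sequence, RAAPIV is
AAPIV of the reversed sequence. The assembled vector is
`FV(4) ⊕ AAPIV(4) ⊕ RAAPIV(4) ⊕ 30 sequence-matrix moments ⊕ 30 PRIM ⊕ 30
RPRIM` = 102 entries, fixed across sequence lengths.

## Base classifiers

Three recurrent architectures on a hand-written numpy BPTT engine (the
runtime environment provides no deep-learning framework; gradients are
verified against central finite differences in the test suite):

| model | stack |
|---|---|
| LSTM  | LSTM(128) → dropout 0.2 → dense(64, sigmoid) → dropout 0.2 → head |
| GRU   | GRU(256) → simple RNN(128) → dropout 0.3 ×2 → dense(10, sigmoid) → head |
| BLSTM | bidirectional LSTM(128/dir) → dropout 0.2 → dense(64, sigmoid) → dropout 0.2 → head |

The head is always a 2-unit softmax trained with sparse categorical
cross-entropy; the exported score is the mutated-class probability. The
10-unit dense layer of the GRU sits penultimate — a 10-unit terminal layer
cannot express two classes.

**Input modes.** Default is `token_sequence`: sequences are right-truncated
/ zero-padded to 64 tokens and pass through a trainable width-64 embedding —
the embedding-first architecture the models describe. `feature_vector` mode
standardizes the 102 features (z-score fit on training data only) and
presents them as a length-102 sequence of scalars. This mode is retained
and tested but is known to train poorly: with weights shared across
timesteps, the recurrence cannot identify which feature a timestep carries,
and the learnable signal collapses; temporal mean-pooling (below) mitigates
but does not remove this. Token mode is the recommended and default path.

**Readout.** Hidden states are mean-pooled over time before the dense stack
(the dense layer "links the feedback from all the layers"): every timestep
gets a direct gradient path, which measurably accelerates convergence.
`pooling="last"` restores the classical last-state readout.

**Optimization.** Momentum SGD, defaults: learning rate 0.05 (0.02 for the
GRU — with two stacked recurrent layers it destabilizes at larger steps),
momentum 0.9, batch 32, 50 epochs, global-norm gradient clipping at 5,
float32. Plain SGD at learning rate 0.01 without momentum was tried first
and cannot fit, within 50 epochs, cohorts that logistic regression fits to
0.94 — the momentum defaults are the smallest change that trains all three
architectures reliably. Training is deterministic given `random_state`
(numpy Generator; dropout masks drawn from the same stream; inference uses
no randomness).

Initialization: Glorot-uniform input weights, orthogonal recurrent blocks,
forget-gate bias 1.

## Ensemble (EDLM)

`g_i = Σ_n w_n f_{n,i}` over the three base scores, weights non-negative and
normalized. Weight modes: accuracy-proportional (default), uniform,
explicit, and an exhaustive grid over the weight simplex (step 0.1)
maximizing reference-set accuracy. Inside the evaluation protocols the
reference set is the split's training portion (training-data-only rule; no
extra model fits); the standalone `WeightedEnsembleClassifier` can hold out
a stratified `validation_fraction` instead. Scores at exactly the 0.5
threshold classify as mutated, making Sn/Sp accounting deterministic.

## Evaluation protocols

- **SCT**: train = test = full dataset. Reported as an overfitting /
  memorization diagnostic, not a generalization claim.
- **IST**: one stratified, seeded 80/20 split.
- **10-FCVT**: stratified seeded 10-fold CV; per-fold metrics retained,
  means reported.

Splits are stratified by class (unstratified small splits can lose a class
entirely). Metrics follow the confusion-matrix formulas exactly
(Sn = TP/(TP+FN), Sp = TN/(TN+FP), Acc = (TP+TN)/total, MCC with the
product-of-marginals denominator); a zero MCC denominator factor reports
MCC = 0 with a degenerate flag; Sn/Sp with an empty class report 0. ROC
curves group tied scores and AUC is trapezoidal; the suite cross-checks it
against an exhaustive pairwise-comparison estimator.

## Known limitations

- The synthetic world is balanced, i.i.d.-uniform and single-signal; none
  of the confounders of real mutation cohorts are represented.
- Feature-vector input mode underperforms token mode by construction (see
  above); it exists for completeness and for externally supplied feature
  matrices.
- The GRU converges noticeably more slowly than LSTM/BLSTM at desk scale;
  at heavily reduced epoch budgets it may sit at chance while the other
  two models have converged (the accuracy-weighted ensemble then discounts
  it).
- PRIM/RPRIM use a first-occurrence offset-sum definition chosen for this
  package (position-relative, O(L), degenerates sensibly for absent
  nucleotides); other position-incidence definitions exist in the
  literature and would change feature values.
- Hahn moments at grid sides 2–3 use polynomial orders beyond the support
  size, where the family is not orthogonal (values remain finite and
  deterministic).
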