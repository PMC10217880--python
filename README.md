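# mutscan

Classify gene sequences as **normal** or **mutated** (driver-mutation
carrying) with an ensemble of three recurrent neural classifiers over
moment-based sequence descriptors.

The package is aimed at computational-biology work on early cancer detection
from sequence data — the motivating case is cholangiocarcinoma (bile-duct
cancer) gene panels — where labeled cohorts are built by applying curated
point-mutation tables to reference gene sequences, and a classifier is asked
to recognize mutated sequences.

## What it does

1. **Cohort construction** (`mutscan.datagen`) — read reference sequences
   (FASTA) and point-mutation tables (`gene,position,ref,alt`; 1-based
   positions), verify the reference allele at every site, and generate the
   mutated counterparts; or synthesize a fully seeded desk-scale cohort with
   a controllable class signal (implanted motif or biased substitutions).
2. **Feature extraction** (`mutscan.features`) — encode each sequence into a
   square integer matrix (A=1, C=2, G=3, T=4, N=0) and summarize it, plus two
   4×4 position-relative incidence matrices (PRIM on the forward strand,
   RPRIM on the reverse), by raw, central, and discrete-Hahn moments up to
   total order 3. With per-nucleotide frequency (FV) and accumulated-position
   vectors (AAPIV/RAAPIV) this yields a fixed 102-dimensional descriptor:

   - raw moments  R_xy = Σ_g Σ_h g^x h^y δ_gh
   - central moments C_ab = Σ_g Σ_h (g − ḡ)^a (h − h̄)^b δ_gh about the
     intensity centroid ḡ = R10/R00, h̄ = R01/R00
   - Hahn moments A_pq = Σ_i Σ_j δ_ij h̃_p(i) h̃_q(j) with weighted-normalized
     discrete Hahn polynomials h̃_m

3. **Base classifiers** (`mutscan.models`) — three scikit-learn-style
   estimators built on a hand-written numpy BPTT engine (no deep-learning
   framework required):

   - `LSTMClassifier` — 128-unit LSTM, two 20 % dropouts, sigmoid dense layer
   - `GRUClassifier` — 256-unit GRU → 128-unit simple RNN, two 30 % dropouts,
     10-unit penultimate dense layer
   - `BiLSTMClassifier` — bidirectional LSTM (128 units per direction)

   All use a 2-unit softmax head trained with sparse categorical
   cross-entropy by momentum SGD; inputs are either token sequences
   (fixed 64-token window through a trainable embedding — the default) or
   the 102-dimensional feature vectors.

4. **Ensemble** (`mutscan.ensemble`) — the EDLM prediction is the weighted
   sum g_i = Σ_n w_n f_{n,i} of base-model scores with accuracy-proportional
   (or uniform / explicit / grid-searched) weights.
5. **Evaluation** (`mutscan.evaluation`) — self-consistency (SCT, train =
   test), independent-set (IST, stratified 80/20), and stratified 10-fold
   cross-validation (10-FCVT) protocols, reporting Acc, Sn, Sp, MCC and
   ROC/AUC per model.

## Worked example

```python
from mutscan import (SyntheticCohortConfig, generate_synthetic_cohort,
                     run_protocol)

cfg = SyntheticCohortConfig(n_genes=100, signal_mode="motif",
                            signal_strength=1.0, seed=7)
dataset, records = generate_synthetic_cohort(cfg)
result = run_protocol("IST", dataset, seed=7, epochs=30)
for rep in result.reports:
    print(f"{rep.model:6s} acc={rep.acc:.3f} sn={rep.sn:.3f} "
          f"sp={rep.sp:.3f} mcc={rep.mcc:.3f} auc={rep.auc:.3f}")
```

prints (seed 7, this package version):

```
LSTM   acc=0.975 sn=1.000 sp=0.950 mcc=0.951 auc=0.980
GRU    acc=0.750 sn=0.700 sp=0.800 mcc=0.503 auc=0.853
BLSTM  acc=0.700 sn=0.450 sp=0.950 mcc=0.462 auc=0.870
EDLM   acc=0.975 sn=1.000 sp=0.950 mcc=0.951 auc=0.972
```

The cohort implants a fixed CpG-repeat motif into every mutated sequence
(signal strength 1.0), so the classes are separable. On the held-out 20 %
split (40 sequences) the LSTM recovers the signal almost perfectly within
the reduced 30-epoch budget; the GRU and BLSTM are still mid-convergence
(their AUCs show ranking skill their thresholded accuracy does not yet
reflect), and the accuracy-weighted ensemble follows its strongest member.
Sensitivity (sn) is the detection rate on mutated sequences, specificity
(sp) the rate on normals; MCC summarizes the confusion matrix in [-1, 1].

The same pipeline runs from the shell:

```bash
mutscan generate --out cohort/ --seed 7 --n-genes 40 --signal-mode motif --signal-strength 1.0
mutscan mutate --reference cohort/normal.fasta --mutations cohort/mutations.tsv --out regen.fasta
mutscan features --fasta cohort/normal.fasta --out features.csv
mutscan all --config run.yaml --seed 7 --out results/
```

## Acceptance script

`scripts/acceptance.py` re-runs the full pipeline from scratch — synthetic
cohort generation, feature extraction, training of all three base models and
the ensemble, and all three evaluation protocols — and writes its results
JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Per-model metrics for every protocol are printed to stdout and written to
the run's `summary.csv`.

## Layout

```
src/mutscan/
  datagen.py     cohorts, mutations, synthetic generator
  features.py    moments, PRIM/RPRIM, AAPIV/RAAPIV, FV, MomentFeaturizer
  _rnn.py        numpy recurrent-network engine (BPTT)
  models.py      LSTM/GRU/BLSTM estimators, specs, save/load
  ensemble.py    weighted-sum ensemble (EDLM)
  evaluation.py  SCT/IST/10-FCVT, Acc/Sn/Sp/MCC, ROC/AUC
  pipeline.py    YAML-configured end-to-end runs
  cli.py         `mutscan` command
docs/methods.md  model/assumption/limitation notes
```
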