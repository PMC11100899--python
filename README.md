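# nfpscreen

Trainable neural graph fingerprints for docking-score virtual screening.

## The problem

Structure-based screening campaigns dock large compound libraries against a
protein target and keep the molecules whose binding free energy
ΔG°bind(aq) falls in the tight-binding (most negative) tail. Docking every
molecule is expensive, so a common shortcut is to dock a subset, binarize
the scores into *hits* and *non-hits* at a percentile threshold, and train
a classifier that predicts hit/non-hit directly from the structure — then
run the cheap classifier over the rest of the library. The classifier's
recall is the quantity that matters most: every false negative is a
potentially tight binder thrown away.

Classical pipelines featurize molecules with a *fixed* hashed circular
fingerprint (Morgan/ECFP). `nfpscreen` implements the trainable
alternative: a graph-convolutional fingerprint in which the two
non-differentiable steps of the ECFP algorithm are replaced by smooth
ones — the hash by a **sigmoid** layer and the array indexing by a
**softmax** layer — so the fingerprint parameters can be optimized jointly
with the downstream classifier by ordinary backpropagation.

## The model

A molecule is a graph with atom-feature matrix, bond-feature matrix, and
connectivity. With convolutional depth *L* (the ECFP-radius analog) and
fingerprint length *K*:

```
r⁰_a  = atom_features[a]
v_a   = r^{l−1}_a ⊕ Σ_{u∈N(a)} r^{l−1}_u ⊕ Σ_{b∋a} bond_features[b]
r^l_a = σ(v_a·H_l + h_l)                    l = 1..L   (smooth "hash")
i^l_a = softmax(r^l_a·W_l + c_l)            l = 0..L   (smooth "index")
fingerprint = Σ_{l=0..L} Σ_a i^l_a
```

Each softmax row sums to one, so the fingerprint entries always sum to
n_atoms·(L+1), and the sum pooling makes the result invariant to atom
ordering. The fingerprint feeds a small fully connected network with a
sigmoid output (hit probability); binary cross-entropy gradients flow
through the entire construction, so fingerprint and classifier train as
one model (Adam, Xavier-normal initialization, constant 0.01 biases).

Around the model sits the full screening pipeline: score-table ingestion,
random 70/15/15 train/validation/test split, hit threshold at a low-end
quantile of the *training* energies only, 50/50 oversampling of training
hits, hyperparameter grid search with recall-first model selection,
evaluation (precision, recall, F1, ROC-AUC, PR-AUC, and the predictive
enrichment probability per 0.01 kcal/mol energy bin), and a fixed
Morgan-fingerprint baseline trained on the identical split for comparison.
All gradients are exact reverse-mode, implemented in NumPy and validated
against central finite differences in the test suite.

## Worked example

```bash
python examples/03_train_and_evaluate.py
```

trains on an 800-molecule synthetic screen (20% hit tail, noise 0.5
kcal/mol) and prints:

```
trained 20 epochs; final training loss 0.423
  test precision      0.583
  test recall         0.913
  test f1             0.712
  test roc_auc        0.934
  test pr_auc         0.731
  test pep_aggregate  0.913
```

Read this as: the model keeps 91% of the true tight binders (recall /
aggregate PEP) while rejecting enough weak binders that 58% of what it
keeps is a true hit (precision) — the recall-leaning trade a screening
funnel wants. The other examples cover the fingerprint itself
(`01_fingerprint_basics.py`), data preparation and oversampling
(`02_prepare_screen.py`), and the grid search plus Morgan baseline
comparison (`04_grid_search_and_morgan_baseline.py`).

The same pipeline is scriptable from the shell:

```bash
nfpscreen simulate --n-molecules 2000 --seed 1 --out table.csv
nfpscreen prepare table.csv --hit-fraction 0.2 --seed 1 --out labeled.csv
nfpscreen train labeled.csv --fp-length 64 --conv-depth 2 --checkpoint model.npz
nfpscreen evaluate model.npz labeled.csv --out metrics.json
```

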