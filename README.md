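# localqsar

Local QSAR / read-across prediction of toxicological endpoints, with a
built-in applicability domain.

Toxicological risk assessors routinely practice *read across*: infer the
toxicity of an untested compound from experimentally tested, structurally
similar compounds. `localqsar` automates that procedure as a lazy,
per-query modelling scheme. Instead of one global model, for every query
compound it

1. finds *neighbors* — training compounds whose **activity-specific
   similarity** to the query exceeds a threshold,
2. builds a dedicated local model from the neighbors' experimental
   activities (similarity-weighted majority vote for two-class endpoints,
   a neighbor-only SVM for classification or regression),
3. returns the prediction together with a **confidence** — the mean
   neighbor similarity — and its full provenance (the neighbors and the
   activating/deactivating substructures matched in the query).

A query with no neighbors is reported as **unpredicted** (outside the
applicability domain) rather than guessed at.

## The core method

**Activity-specific similarity.** Linear substructures (simple paths of
heavy atoms, rendered as SMARTS) are mined from the training set; each
fragment's association with the endpoint is scored with a Pearson
chi-square test on its 2×2 occurrence/class table, and fragments with
*p* > 0.05 are discarded. Similarity between compounds *A*, *B* is the
weighted Tanimoto index over the retained fragments,

    sim(A, B) = Σ_{f ∈ A∩B} w_f / Σ_{f ∈ A∪B} w_f ,

with w_f = 1 by default (significance acts as a cutoff), so only
endpoint-relevant parts of the molecules contribute. The miner is a
pluggable interface; richer graph miners can be substituted as long as they
return fragments with *p*-values.

For numeric property vectors (physico-chemical descriptors or measured
properties) the features are standardized, reduced by truncated SVD, and
compared by cosine similarity clamped to [0, 1].

**Local models.** Classification: the predicted class is the one with the
larger summed neighbor similarity; the signed normalized margin serves as a
ranking score for ROC analysis. Regression (and optionally
classification): an SVM with Tanimoto or RBF kernel is trained on the
neighbors only, with (C, γ) selected on an 8×8 geometric grid by inner
cross-validation over the neighbors.

**Validation.** Seeded, stratified k-fold cross-validation mines fragments
on each training fold only (no information leakage into the test fold),
pools predictions, and reports accuracy/AUC/F/TPR/TNR/PPV/NPV or
RMSE/MAE/R²/r/Lin's CCC, plus confidence-vs-statistic curve tables showing
how performance rises when low-confidence predictions are discarded.

## Worked example

No external data is needed: a deterministic generator plants an activating
nitroso motif (`N=O`) in a fraction of small synthetic molecules.

```python
import localqsar as lq

ds = lq.generate_classification_fixture(lq.FixtureSpec(n_compounds=80, seed=7))
model = lq.train_model(ds, lq.ModelSpec())
top = model.fragments[0]
print(f"top fragment: {top.smarts}  p={top.p_value:.3g} "
      f"({top.support_active} active / {top.support_inactive} inactive)  {top.direction}")
for smi in ["CCCc1ccccc1N=O", "CCOC(C)N"]:
    pred = model.predict_smiles([smi])[0]
    print(f"{smi}: predicted={pred.value} confidence={pred.confidence:.3f} "
          f"neighbors={pred.n_neighbors}")
```

prints

```
top fragment: N=O  p=1.28e-16 (37 active / 1 inactive)  activating
CCCc1ccccc1N=O: predicted=active confidence=0.912 neighbors=7
CCOC(C)N: predicted=active confidence=0.524 neighbors=39
```

The miner recovers the planted toxicophore as the top-ranked fragment; the
motif-carrying query is predicted active with high confidence (few, highly
similar neighbors), while the second query is an in-domain but low-confidence
call backed by many weakly similar neighbors — exactly the gradation the
confidence value is meant to convey.

The same pipeline is available from the shell:

```bash
localqsar fixture --kind classification --n 200 --seed 42 --out train.csv
localqsar train --dataset train.csv --endpoint-name activity --endpoint-type nominal --out model.json
localqsar predict --model model.json --queries queries.csv --out predictions.csv
localqsar crossvalidate --dataset train.csv --endpoint-name activity \
    --endpoint-type nominal --k 10 --seed 42 --out-dir reports/
```

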