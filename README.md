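# efolearn

Sparse linear classifiers for strongly unbalanced descriptor tables,
trained by **enrichment-factor optimization (EFO)** — a ranking-based
alternative to likelihood fitting, built for problems like predicting which
drug substrates yield reactive metabolites, where positives are ~14% of the
data and the features are raw physicochemical descriptors spanning many
orders of magnitude.

## Who this is for

Cheminformaticians and ML practitioners who need a classifier that

* behaves well when the positive class is rare,
* uses only a handful of named, interpretable descriptors,
* returns a score-based probability with every call, and
* never standardizes the input (coefficients stay in the descriptors'
  native units).

## The method

A model is a linear score over k descriptors, `s(x) = c₁v₁ + … + c_kv_k`
(no intercept; the leading coefficient is normalized to ±1).  Training
maximizes a ranking-quality objective instead of a likelihood: the
descending score ranking is cut into clusters of size n (the number of
training positives), the positive percentage RMᵢ of each cluster is
recorded, and

```
Quality = AI × RM₁ ,   AI = m₃ / m₂^{3/2}
```

where AI is Pearson's moment coefficient of skewness of the cluster
profile {RMᵢ} and RM₁ is the first cluster's positive percentage.  A good
model front-loads positives (large RM₁) and decays from the front (right
skew).  Pipeline:

1. **EF filter** — keep descriptors whose single-column top-5% enrichment
   factor exceeds a cut-off (default 2.0; use 1.5/1.0/0 for balanced data,
   whose EF ceiling is 2.0);
2. **combination search** — exhaustive over C(m, k) kept-descriptor
   subsets, greedy forward construction past a cap;
3. **Hooke–Jeeves pattern search** over coefficients from σ-scaled random
   starts (12 per variable; the objective is piecewise constant, so
   derivative-free search is required);
4. **threshold** — the rank-n training score separates predicted classes
   (`score ≥ threshold` ⇒ positive);
5. **probabilities** — positive fractions of 2%-wide percentile bins of
   the training ranking.

See `docs/methods.md` for assumptions, numerical choices and limitations.

## Worked example

```python
import numpy as np
from efolearn import EFOClassifier, SyntheticSpec, generate, make_splits

table, truth = generate(SyntheticSpec(n_instances=400, n_descriptors=12,
                                      n_positive=56, informative=(0, 1, 2),
                                      effect_size=1.5, label_noise=0.02,
                                      seed=0))
X = table.to_dataframe().drop(columns=["id", "label"])
y = table.labels

split = make_splits(table, fraction=0.70, repeats=1, seed=0)[0]
train = np.isin(table.instance_ids, split.train_ids)

clf = EFOClassifier(n_variables=3, ef_filter_cutoff=1.5, random_state=0)
clf.fit(X[train], y[train])
print("best model :", clf.best_model_.equation())
print("threshold  :", round(clf.threshold_, 3))
print("train quality :", round(clf.best_model_.train_quality, 1))

from sklearn.metrics import matthews_corrcoef
pred = clf.predict(X[~train])
print("held-out MCC  :", round(matthews_corrcoef(y[~train], pred), 3))
proba = clf.predict_proba(X[~train])[:, 1]
print("top-scored test instance probability:", round(proba.max(), 2))
```

prints

```
best model : 1 d00 + 2.59276 d01 + 0.0459163 d02
threshold  : 1.336
train quality : 156.1
held-out MCC  : 0.542
top-scored test instance probability: 1.0
```

The fitted equation recovered the three planted descriptors (`d00`–`d02`)
with coefficients in their raw units — `d02`'s small coefficient reflects
its large native scale, not low importance.  Instances scoring at least
1.336 are predicted positive; on the untouched 30% test split that rule
reaches a Matthews correlation of 0.54, and the best-scoring test instance
falls in a training-ranking bin that was 100% positive, hence its
probability 1.0.

The same workflow from the shell:

```bash
efo simulate --instances 400 --descriptors 12 --positives 56 --seed 0 --out syn.csv
efo fit syn.csv --variables 3 --cutoff 1.5 --seed 0 --out-dir run
efo predict run/best.json syn.csv --out predictions.csv   # or any model from run/models.json
efo evaluate syn.csv --variables 3 --cutoff 1.5 --seed 0  # 70/30 × 5 protocol
```

`fit` writes the four run artifacts: `models.json` (kept models),
`run.log` (config, seed, per-model qualities), `scores.csv` (per-instance
score/class/probability per model) and `reduced.csv` (the table restricted
to filter-surviving descriptors).

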