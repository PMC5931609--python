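# csom — consensus self-organizing maps for imbalanced multi-class data

`csom` is a Python library and command-line tool for classifying highly
imbalanced, multi-class (and optionally multi-label) tabular data with an
unsupervised backbone. It was built for a cheminformatics problem —
deciding whether a drug candidate is a substrate of the multidrug-resistance
ABC transporters P-glycoprotein, MRP1 or BCRP, where a couple of hundred
substrates drown in a thousand non-substrates — but applies to any numeric
feature table with a label column.

## The method

A **self-organizing map (SOM)** projects high-dimensional data onto a 2-D
lattice of neurons by competitive learning; here the lattice is **toroidal**
(edges wrap), so every cell has a full 8-cell Moore neighborhood. Training
uses the online Kohonen rule with a geometrically decaying learning rate, a
linearly shrinking adaptation radius, and a Gaussian neighborhood kernel.

Labels never enter training. Classification is added on top in three steps:

1. **Probability expansion.** After projecting the labelled training set,
   occupied cells hold class-frequency vectors. A wavefront then sweeps the
   torus: every empty cell adjacent to filled cells receives the weighted
   sum of their class vectors (occupied sources weighted by example count,
   expanded sources weight 1), normalized to a probability vector
   `p(c | cell)`. Occupied cells are frozen. The result is a class-probability
   surface covering the whole map.
2. **Consensus priors.** Because runs start from random weights, an example
   near a class boundary has different neighbors in every run. Repeating
   the SOM P times (P ≈ 10 suffices) and averaging each example's
   normalized neighbor-class tally yields a per-example prior distribution;
   these priors replace hard labels inside the expansion, so boundary
   ambiguity is spread into the surface instead of being hidden.
3. **Threshold gating.** A query is assigned the argmax class of its
   best-matching unit's probability vector only if that probability strictly
   exceeds a confidence threshold *t*; otherwise it is reported as
   `NON_CONCLUSIVE`. Raising *t* trades coverage for reliability.

Around this core the package provides SMOTE oversampling and random
undersampling, recall-centered metrics (arithmetic and geometric mean
recall, macro-F, percent non-conclusive), descriptor preparation
(|r| > 0.9 correlation pruning, sigmoid scaling, SVD reduction to 10
variables), the substrate-labelling rule (Pearson r < −0.3), a synthetic
imbalanced-Gaussian generator, stratified 10-fold cross-validation with
k-NN baselines (raw space or SOM space), and a paired Student t-test.

## Worked example

Generate a 3-class 1:1:10 benchmark (two minority Gaussians of 25 points,
one majority of 250) and compare consensus mapping against SOM + k-NN under
10-fold cross-validation with fold-internal SMOTE:

```bash
csom simulate spec.json --out demo.csv        # spec.json: counts 25/25/250
csom evaluate demo.csv --method csom --method som+knn \
    --grid 20x20 --rounds 50 -P 10 -t 0.5 --folds 10 --seed 4 \
    --out-csv folds.csv --out-json summary.json
```

prints

```
csom: acc=0.871 mean_recall=0.909 F=0.786 pct_out=2.3
som+knn: acc=0.838 mean_recall=0.870 F=0.743 pct_out=0.0
```

Mean recall (the average of per-class recalls, insensitive to class sizes)
is the headline number for imbalanced data: the consensus mapper reaches
0.909 versus 0.870 for SOM + k-NN, at the cost of declining to classify
2.3 % of queries. `summary.json` additionally carries the paired t-test on
the per-fold mean-recall series (here t = 1.50, p = 0.17, df = 9).

Fitting and prediction are separate commands:

```bash
csom fit demo.csv --grid 20x20 --rounds 50 -P 10 -t 0.9 --seed 1 \
    --out model.json --map-csv map.csv
csom predict model.json newdata.csv --out preds.csv
```

`preds.csv` holds one probability column per class plus a decision column
in which unconfident rows carry the explicit token `NON_CONCLUSIVE`.
For the substrate use case, `csom label correlations.csv --out labels.csv`
converts per-compound transporter correlations into label sets under the
−0.3 rule.

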