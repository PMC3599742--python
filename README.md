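# aiia — adaptive interbeat-interval analysis

`aiia` classifies heartbeat records from the symbolic dynamics of their
RR-interval series. It is aimed at heart-rate-variability (HRV) researchers
who have beat-annotation exports (one interbeat interval per line, the
format produced by `ann2rr`-style tools) and want a fully reproducible
symbolization-and-classification pipeline, plus a synthetic RR generator
for method development when no recordings are at hand.

## Method

For a record with interbeat intervals $x_1, \dots, x_N$ (ms), the pipeline:

1. **Differences.** Computes the signed RR-interval differences
   $d_i = x_{i+1} - x_i$, preserving both the magnitude and the direction
   (acceleration vs deceleration) of each beat-to-beat change.
2. **Symbolizes.** Clusters the $d_i$ with one-dimensional K-Means
   (Lloyd's algorithm, deterministic quantile initialisation) into
   $k \in [2, 26]$ clusters and maps each difference to a letter — `a` for
   the smallest centroid up through the $k$-th letter — turning the record
   into a string. Because the partition is learned from the data rather
   than fixed by hand, fine degrees of variation are kept (a +250 ms and a
   +100 ms lengthening get different letters, where a binary
   up/down coding would conflate them).
3. **Counts n-grams.** Slides windows of length $n = 1 \dots n_{\max}$
   (default 3) over the string and converts counts to probabilities
   $P(g) = c_g / (L - n + 1)$, one distribution per order, over the full
   vocabulary of $\sum_n k^n$ grams ($18{,}278$ for $k=26$, $n_{\max}=3$).
   Counting is order-sensitive: `ab` and `ba` are different grams.
4. **Classifies.** Feeds the per-record probability vectors to a
   classifier under stratified 10-fold cross-validation and pools the fold
   predictions into a single confusion matrix, reporting overall accuracy
   (correct / total) and per-class accuracy (diagonal / row sum).

Every stage is exposed both as a function and as a scikit-learn
estimator (`RRIDifferencer`, `KMeansSymbolizer`, `NGramFeaturizer`,
`GaussianNBClassifier`), so the whole method composes into a
`sklearn.pipeline.Pipeline` — which is also how the pooled-symbolization
variant avoids leaking validation records into centroid fitting.

## Worked example

```python
from aiia import generate_study, study1_spec
from aiia.pipeline import RunConfig, run_pipeline

records = generate_study(study1_spec(2000), seed=0)   # 142 labelled records
report = run_pipeline(RunConfig(k=10, n_max=2, seed=0), records=records)
print(report.to_table())
```

prints

```
Total instances      142
Correctly classified 134
Incorrectly classified 8
Accuracy             94.4%

Group           AF     CHF      HE      HY     WNU
Total            9      43      20      20      50
Correct          8      43      16      17      50
Accuracy     88.9%  100.0%   80.0%   85.0%  100.0%
```

The synthetic five-class corpus mirrors a typical HRV study design —
9 atrial-fibrillation (AF), 43 congestive-heart-failure (CHF), 20 healthy
young (HY), 20 healthy elderly (HE) and 50 uniform white-noise (WNU)
records. With per-record symbolization into k=10 letters and gram orders
1–2, the reference Gaussian naive Bayes classifier recovers the group of
134 of the 142 records (94.4%); the white-noise and CHF groups separate
perfectly, while the residual confusion sits between the two healthy
groups, whose dynamics differ only in oscillation amplitude and noise
level.

The same thing from a shell:

```
aiia simulate --preset study1 --length 2000 --seed 0 --outdir corpus/
aiia run --manifest corpus/manifest.csv --k 10 --n-max 2 --seed 0 --outdir out/
aiia sweep --manifest corpus/manifest.csv --k 2..26 --n-max 1..3 --outdir sweep/
```

`sweep` writes the accuracy-vs-cluster-count and gram-order comparison
table as CSV for replotting.

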