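# Methods

## The model

A heartbeat record is an ordered series of interbeat (RR) intervals in
milliseconds. The analysis treats the *signed successive differences*
(RRID) as the signal of interest: regular cardiac control produces
structured alternation of acceleration (negative differences) and
deceleration (positive differences), and pathology alters both the
magnitude distribution of these differences and their short-range
ordering. The pipeline makes that structure classifiable in three steps:
symbolization (1-D K-Means over the differences), bag-of-patterns
featurization (overlapping n-gram probabilities), and supervised
classification under cross-validation.

No detrending, artifact filtering or local-mean normalisation is applied
anywhere; a documented no-op hook (`preprocess.no_artifact_filter`) marks
where an ectopic-beat filter would plug in.

## Symbolization

`kmeans_fit` runs Lloyd's algorithm on the one-dimensional difference
values:

* **Initialisation** — the k data quantiles at positions (i + 0.5)/k,
  i = 0..k−1. This is deterministic, spreads the initial centroids over
  the empirical distribution, and removes the need for random restarts;
  identical data and parameters always give identical models, which in
  turn makes every downstream gram count and accuracy reproducible.
* **Assignment** — nearest centroid; a value exactly midway between two
  centroids goes to the lower-indexed (smaller) one. The tie is a
  measure-zero event on real data but must still be deterministic.
* **Update** — arithmetic mean of the assigned points. A cluster left
  empty is re-seeded at the point currently farthest from its assigned
  centroid.
* **Stopping** — maximum centroid movement < `tol` (default 1e−6 ms) or
  `max_iter` (default 300) sweeps. The per-iteration within-cluster sum
  of squares is recorded on the model (`inertia_history`) and is
  non-increasing, which the property suite asserts.

Centroids are sorted ascending and mapped alphabetically: `a` is always
the strongest acceleration cluster. Any fixed bijection gives identical
n-gram statistics up to relabeling; the sorted mapping makes sequences
readable and run-stable.

**Fit scope.** The default is *per-record*: each record is clustered on
its own differences, so the partition adapts to the record's own
variability scale and the features become scale-free descriptors of the
record's dynamics. The alternative, *pooled*, fits one model on the
training records' differences and applies it everywhere, making letters
comparable across records; inside cross-validation the pooled model is
refitted per fold on training records only, which the pipeline enforces
structurally (the symbolizer is a pipeline step, so it only ever sees the
fold's training half) and a bookkeeping test asserts. Both scopes are
first-class; neither is claimed to be canonical.

## Gram features

The vocabulary enumerates all grams of orders 1..n_max (default 3) over
the k-letter alphabet in canonical order (by length, then
lexicographically); its size is Σ kⁿ, 18,278 at k=26, n_max=3. Counting
slides overlapping windows of stride 1, and each order is normalised
separately: P(g) = count / (L − n + 1). Per-order normalisation keeps
each order's block a self-contained probability distribution, so an
order-1 analysis embedded in an order-3 feature vector is identical to a
standalone order-1 run, and feature semantics are independent of record
length. Feature vectors are stored sparsely but defined over the full
vocabulary, so all records share one column set.

## Classification

Folding is stratified by default: with a 9-member class under 10 folds,
plain random folds can produce training folds missing a class entirely.
When every class is smaller than the fold count (the leave-one-out
limit), stratification is undefined and plain shuffled folds are used.
Fold predictions are pooled into one confusion matrix; overall accuracy
is trace/total (not the mean of fold accuracies), per-class accuracy is
diagonal/row-sum, and printed accuracies round half-up to one decimal.

The reference classifier is a hand-written Gaussian naive Bayes:
per-class prior = class frequency, per-feature class-conditional Gaussian
with variance floored at 1e−9 × the largest feature variance, prediction
by argmax of log-prior + Σ log-density. It is deterministic, dependency
light, and cross-checked in the tests against a direct log-posterior
enumeration and against scikit-learn's implementation. Heavier
classifiers (logistic regression, linear SVM, decision tree, MLP,
scikit-learn's Gaussian NB) are available through a registry behind the
same fit/predict interface; the scale-sensitive ones are wrapped with a
standardising scaler because gram probabilities live on a 1/kⁿ scale.

## Synthetic data

The generator produces labelled surrogate corpora with the group
structure of two typical HRV study designs: a five-class corpus (9 AF,
43 CHF, 20 HY, 20 HE, 50 WNU; 142 records) and a four-class apnea corpus
(20 each of APNEA, HY, HE, WNU; 80 records). Each class is the minimal
standard surrogate for the physiology named, with every parameter
exposed:

| class | model | defaults |
|---|---|---|
| WNU | i.i.d. uniform intervals | range [600, 1400] ms (the range is arbitrary and configurable) |
| HY | mean + sinusoid + AR(1) noise | 800 ms, amplitude 40 ms, period 5 beats (respiratory-type oscillation), AR 0.3, noise 25 ms |
| HE | same, reduced variability | 850 ms, amplitude 12 ms, period 5, AR 0.5, noise 10 ms |
| AF | i.i.d. truncated normal | 700 ± 180 ms — serially uncorrelated, high-entropy differences |
| CHF | low-sd AR(1) + rare jumps | 750 ms, base sd 8 ms, AR 0.7, jump prob 0.02, ±150 ms |
| APNEA | slow cyclic oscillation + AR(1) noise | 900 ms, amplitude 150 ms, period 40 beats, noise 15 ms |

Intervals are clipped to [200, 2500] ms. Record i of a corpus uses seed
(master_seed + i) mod 2³¹, so corpora are byte-reproducible and records
regenerable in isolation. The default record length is 2,000 intervals,
a deliberate scale-down that keeps a full five-class cross-validated run
in seconds; study-scale lengths (tens of thousands of beats) are
available by passing `length` to the presets.

The presets were chosen for class separability under per-record
symbolization: because per-record clustering adapts to each record's own
scale, classes must differ in the *shape and ordering* of their
difference dynamics, not merely in variance — hence distinct oscillation
periods (5 vs 40 beats), distinct noise-to-oscillation ratios (HY vs HE),
i.i.d. vs autocorrelated noise (AF/WNU vs CHF), and jump-vs-smooth
texture (CHF). What passing tests on this corpus shows is that the
pipeline recovers known, well-separated generative structure; it does
not show clinical-grade performance on real recordings, which carry
ectopy, artifacts, nonstationarity and between-subject overlap that the
surrogates deliberately omit.

## Numerical and design choices

* Internal unit is milliseconds everywhere; readers convert seconds at
  the boundary.
* Feature CSVs print probabilities with 12 significant digits and
  round-trip losslessly; column order is the canonical vocabulary order,
  so identical runs produce byte-identical files.
* The 1-D K-Means is implemented in the package rather than delegated:
  its determinism contract (quantile initialisation, lower-index
  tie-break, farthest-point re-seeding) is part of the method's
  specification and is not reproducible with library K-Means
  implementations, which are used instead as an independent cross-check
  in the tests.
* Gram-order comparisons (does adding order-3 grams help?) are run with
  the regularised logistic classifier. Under the reference naive Bayes
  the comparison is confounded: with ~1,000 rare trigram columns the
  floored class-conditional variances make the log-likelihood sum
  hypersensitive to grams unseen in a class's training rows, and
  accuracy *drops* when order 3 is added — a known naive-Bayes failure
  mode on sparse count features, not a property of the features
  themselves. The regularised linear model gains about one accuracy
  point from order 3 on the default corpus. This limitation is inherent
  to the reference classifier and is left visible rather than patched
  (e.g. by smoothing), since the reference model's variance floor is
  part of its specification.

## Known limitations

* The surrogates are statistical, not physiological: no IPFM-style
  pulse-frequency modulation, no annotated apnea episodes, no ectopic
  beats. Conclusions about real PhysioBank-style recordings require real
  recordings.
* Per-record symbolization discards absolute scale by construction; a
  record distinguished from another *only* by overall variance magnitude
  is invisible to it (the pooled scope exists for exactly that case).
* The reference naive Bayes degrades in high gram orders (above); use
  the logistic or SVM registry entries for order-3 work.
* K-Means letter boundaries are sample-dependent; two records with
  similar dynamics but different lengths can symbolize slightly
  differently near cluster boundaries.
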