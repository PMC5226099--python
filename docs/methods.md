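# Methods

This note documents the model, the choices behind every tunable, and what
the synthetic benchmarks do and do not demonstrate.

## Windowing and coordinates

All coordinates are 0-based half-open (BED convention); strand is ignored
(histone-mark peaks and enhancer calls are unstranded). Each chromosome is
tiled from position 0 into fixed-width windows (default 200 bp, the working
resolution of binned histone-modification data; the width is a parameter).
A chromosome tail shorter than the width is kept as a truncated final
window, so the tiling is a partition and no label near a chromosome end is
dropped.

## Feature construction

The feature of window *w* for mark *m* is the **maximum** `signalValue`
over mark-*m* peaks overlapping *w* by ≥ 1 bp, 0 when none. Maximum (not
sum or mean) because peak signal is an enrichment statistic: splitting one
peak into fragments should not change a window's value. `sum` and `count`
aggregation modes exist for comparison. Peaks on chromosomes absent from
the grid are skipped with a warning.

Columns are min-max normalized, x ← (x − x_min)/(x_max − x_min). A
constant column (x_max = x_min) maps to zeros with a warning — an
uninformative feature stays uninformative rather than raising. Each
tissue's matrix is normalized on its own min/max: tissues are separate
experiments on different signal scales, and this per-dataset scope
guarantees no statistic crosses the boundary between training tissues and
a later test tissue. `MinMaxNormalizer` also exposes fit/transform with
clipping to [0, 1] for callers who want to freeze parameters on one
portion of a dataset and apply them to another.

One caveat of per-tissue scaling is worth knowing: in a tissue where a
mark carries no real signal, min-max stretches its background noise over
[0, 1], so a base classifier trained where that mark was informative can
fire confidently on another tissue's background peaks. The stacking stage
is what absorbs this — the meta-classifier learns how much each base's
confidence is worth.

**Labels.** A window is an enhancer when a *single* label interval (EP300
peak or CAGE enhancer) covers ≥ 50% of the window's width (configurable).
The per-interval rule (not accumulated coverage across intervals) avoids
labeling windows brushed by scattered fragments; symmetric 50% avoids
1-bp-touch labels.

**k-mer mode.** For sequence-based features, each window yields the
concatenated frequencies of all 1-, 2-, 3- and 4-mers (340 features,
lexicographic order per k). Counts are divided by the number of k-length
sliding windows not containing N; N-containing windows are excluded from
numerator and denominator, so each block sums to 1 on N-free sequence.

## Imbalance reduction

Enhancers are ~2% of windows. Training uses a 1:10 positive:negative
ratio: all positives are kept and min(10 × n_pos, n_neg) negatives are
drawn without replacement. The draw is guided by k-means (k = 8 by
default, 5 seeded restarts) on the normalized negative feature vectors:
each cluster receives a quota proportional to its size via
largest-remainder rounding (ties: larger fractional part, then larger
cluster, then lower index), sampled uniformly within the cluster. This
keeps rare negative feature regimes represented instead of letting uniform
sampling drown them. Quotas never exceed cluster sizes (proportionality
guarantees it), so an empty cluster simply receives nothing. Clustering
runs on normalized features — sampling is about feature-space diversity,
which is only meaningful on a common scale.

## Base classifiers

One random forest per tissue, fit on a seeded *stratified* 60/40 split of
the balanced dataset (stratification keeps both portions usable at 2–9%
positive rates; plain random splits occasionally starve a fold). Forest
settings are the standard Breiman defaults: 100 trees on bootstrap
resamples, entropy (information-gain) split criterion, ceil(√p) candidate
features per node, unlimited depth, min_samples_split = 2 — all surfaced
in `ForestConfig`. Fitting is delegated to scikit-learn's
`RandomForestClassifier`; `entropy` and `info_gain` are also implemented
and tested as standalone operations since they define the split criterion.

The forest's soft output is the **confidence score** — the exact fraction
of trees voting "enhancer", computed by iterating the fitted trees (this
is deliberately *not* `predict_proba`, which averages per-leaf class
probabilities rather than counting votes). Scores live on a 1/n_trees
grid in [0, 1].

Held-out metrics use cut-off 0.5 (a window is called positive when at
least half the trees vote for it). If the held-out F-score is undefined
(no predicted or no true positives) the model stores 0.0 with a warning,
because the stacking stage multiplies by it; the metrics report itself
keeps the undefined marker.

## Meta-classifier

Every base model scores every window of the pooled held-out (40%)
portions of all training tissues — the only construction that yields a
complete matrix — and meta-feature (i, j) = confidence_j(i) × F-score_j,
so an unreliable base contributes a proportionally damped column.
Training the meta-SVM needs at least two base models.

The SVM is soft-margin with RBF kernel, solved by libsvm (through
scikit-learn's `SVC`, tolerance 1e-3, uniform class weights — imbalance
was already reduced upstream). The (C, γ) grid defaults to
C ∈ {2, 4, …, 50}, γ ∈ {2, 4, …, 200}; 0 is excluded from both because
C = 0 removes the misclassification penalty and γ = 0 degenerates the
kernel to a constant — neither defines a usable SVM. Selection minimizes
the mean balanced error rate, BER = 1 − (sensitivity + specificity)/2,
over seeded stratified 10-fold CV with the *same* folds for every pair;
ties go to the smallest C, then the smallest γ (prefer the least complex
model, deterministically). The full BER surface is kept on the model and
can be dumped as TSV. Predicted labels are the sign of the decision
function; the raw decision values are the ranking scores for ROC.

## Evaluation

Six metrics from the confusion counts: precision TP/(TP+FP), recall and
sensitivity TP/(TP+FN) (identical by definition, reported separately so
the identity is visible), specificity TN/(TN+FP), F-score
2PR/(P+R), accuracy (TP+TN)/(TP+TN+FP+FN). A 0/0 metric is *undefined*
(`None`), never an error, and an undefined precision or recall makes the
F-score undefined. The ROC curve sweeps the cut-off over distinct score
values (ties collapse to one step), starts at (0,0) and ends at (1,1);
AUC is its trapezoidal integral, which equals the Mann–Whitney pairwise
statistic — the test suite checks the two routes agree to 1e-12 and
cross-checks scikit-learn's implementation.

## Synthetic epigenomes

The generator emulates the structure the classifier assumes: ~2% of
windows are enhancers (exactly round(0.02 × n_windows) by construction);
a configurable fraction of enhancers is shared across tissues, the rest
tissue-specific. A mark is *informative* for a tissue iff its effect
there is > 0: informative marks emit one peak per enhancer window with
lognormal signal whose arithmetic mean is base + effect, plus scattered
background peaks (mean = base) over a configurable fraction of windows;
uninformative marks emit background only — so a zero-effect study carries
*no* label information, including through coverage, which is what makes
the null calibration meaningful. Per-(tissue, mark) multiplicative
lognormal jitter (sd 0.15) models tissue-to-tissue effect variation.
Signals are lognormal because enrichment statistics are positive and
right-skewed. The sequence generator plants a tetramer motif (default
GTCA, 10 copies per 200-bp enhancer window) in i.i.d. uniform background
so k-mer features are informative. All outputs are standard broadPeak /
BED / chrom.sizes / FASTA text, byte-identical for a fixed seed.

What the generator does **not** model: read-level noise, peak-caller
artifacts, GC composition, correlated mark co-occurrence, or distance
structure between enhancers and genes. Passing benchmarks therefore
demonstrate the pipeline's statistical machinery (featurization,
balancing, stacking, calibration), not performance on real epigenomes.

## Reference experiments (`enhancerstack.benchmarks`)

Problem sizes are desk-scale so the whole suite runs in well under a
minute on one CPU; the SVM grids used are 3×3 sub-grids of the full
default grid.

- **Strong-signal recovery**: 600-kb genome (3,000 windows), 4 tissues,
  effects 4.0/3.0 with sdlog 0.25 and peaks aligned to the grid
  (width exactly 200 bp). Expected: every base held-out F > 0.9, meta CV
  BER < 0.1, held-out-tissue AUC > 0.9, predicted positive fraction near
  2%.
- **Complementary-marks stacking**: 6 tissues in two triplets over a
  400-kb genome; tissue t and its held-out clone t+3 carry signal only on
  mark t (effect 4.0, sdlog 0.3, background rate 0.03). No single base
  can cover all three held-out tissues, so the meta-classifier should
  match or beat the best base's AUC (within 0.02) in ≥ 9/10 replicates.
  The low background rate matters: a background peak on mark j is
  indistinguishable in meta space from a tissue-j enhancer, so heavy
  background makes the pooled stacking problem ill-posed by construction
  rather than hard.
- **Zero-effect null**: all marks background-only; held-out-tissue AUC
  should sit at 0.5 within Monte-Carlo error across seeds.
- **Permutation null**: informative features with labels shuffled before
  training; held-out precision pooled over seeds should equal the
  positive prevalence (0.3 in the fixture).

## Numerical and degenerate-input conventions

- Seeds: one top-level seed, per-stage substreams derived as
  (seed × 1000003 + crc32(stage name)) mod 2³¹.
- Constant scores in ROC → single threshold step, AUC 0.5.
- broadPeak files missing optional columns parse with signalValue 1.0, so
  plain BED label files flow through the same reader.
- Prediction BED tracks squash decision values through a logistic to fit
  the 0–1000 BED score column; ranking uses the raw decision values from
  the scores TSV.
- Model bundles persist via joblib (scikit-learn's standard model
  persistence); the training manifest records the config, seed and SHA-256
  of every input for byte-identical reproduction.

## Known limitations

- Windows adjacent to enhancers inherit full peak signal whenever peaks
  are wider than one window (overlap-by-1-bp max mapping), capping
  precision at realistic peak widths; the worked example in the README
  shows the effect.
- The meta-feature space has no tissue identity, so systematic base-model
  disagreement patterns that depend on the source tissue cannot be
  exploited.
- Per-tissue min-max scaling can inflate background-only marks (see
  above); quantile or reference-based normalization is out of scope.
- The RBF decision surface is not monotone in the meta-features; score
  regions far from training support revert toward the bias term.
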