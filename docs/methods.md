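# Methods

`ringtex` quantifies the internal texture of ring-enhancing brain lesions on
MRI and classifies them as inflammatory or tumoral. The unit of analysis is a
10×10-pixel region of interest (ROI) placed inside the lesion core; a lesion
may contribute several ROIs, which are averaged into one feature vector. The
reference problem size is a cohort of 67 lesions (30 inflammatory, 37
tumoral) with 1–5 ROIs each — a deliberate choice that keeps every stage
exercised at realistic scale while remaining fast enough for exhaustive
testing.

## 1. Image preparation

Images (PNG, TIFF, or DICOM with rescale slope/intercept applied and
negative values clipped) are resized to 240×240 with bilinear interpolation
(edge-padded, no anti-aliasing, range preserved), then rescaled to 8 bits by
min–max normalization to [0, 255] with banker's rounding; a constant image
maps to 0. ROIs are addressed by their top-left corner in 0-based, half-open
pixel coordinates. For analyses at L < 256 gray levels the 8-bit values are
re-quantized by `level = (v * L) // 256`, so each level covers an equal slice
of the 8-bit range.

## 2. Feature catalogue (63 features)

The catalogue is fixed in name and order (families in the sequence below,
alphabetical within each family); the CSV header is the contract.

**First-order (6).** Mean, Std (sample, ddof = 1), Entropy (Shannon, bits,
over the L-bin histogram), Kurtosis (Pearson m4/m2², population moments),
Skewness (m3/m2^1.5), Correlation (lag-1 Pearson correlation of horizontal
neighbor pairs). Degenerate (constant) patches report 0 for skewness,
kurtosis, and correlation.

**Gray-level co-occurrence, GLCM (22, prefix `GLCM_`).** Pairs are counted
at distance 1 along 0°, 45°, 90°, 135° (offsets (0,1), (−1,1), (−1,0),
(−1,−1) in row/column convention), symmetrized by adding the transpose, and
normalized. Features use 1-based gray indices and log2 with 0·log 0 ≡ 0:
Entropy, Kurtosis and Skewness of the row marginal, Correlation, Contrast,
Variance, SumAverage, SumVariance, SumEntropy, DifferenceVariance,
DifferenceEntropy, IMC1, IMC2 (argument clipped at 0 before the square
root), Autocorrelation, Dissimilarity, Homogeneity, ClusterProminence,
ClusterShade, MaximumProbability, InverseDifference,
InverseDifferenceNormalized, InverseDifferenceMomentNormalized. Each feature
is the arithmetic mean over the four directions.

**Gray-level run length, GLRL (7, prefix `GLRL_`).** Runs of equal level are
counted along rows, columns, diagonals, and anti-diagonals (corner lines of
length 1 included). From the run-length matrix: SRE, LRE, GLN, RP, RLN,
LGRE, HGRE, with 1-based level weights. Pixel conservation — the run-length-
weighted sum of the matrix equals the pixel count — holds by construction
and is tested. Features are averaged over the four directions.

**Wavelet (28).** Two-level 2-D discrete wavelet decomposition (symmetric
boundary extension) for three families: haar, sym4, bior3.3. Per family:
approximation energy `Ea`, detail energies `Eh`, `Ev`, `Ed` at levels 1–2,
and per-level sums `E_soma_*_1/2`, all as percentages of the total
coefficient energy (they sum to 100 exactly). `EntropyWv` is the Shannon
entropy (bits) of the normalized squared-coefficient distribution of the
full haar pyramid.

## 3. Feature ranking and selection

Continuous features are discretized into 4 equal-frequency bins by
rank-block assignment: `bin = floor(min_rank · bins / n)`, where `min_rank`
is the rank of the value's first occurrence in sorted order. Tie groups
therefore share the lowest bin they touch, and low-cardinality features
(including binary ones) keep their distinct values separable.

Each feature receives two scores against the class label: gain ratio
(information gain divided by the feature's own entropy, bits) and Gini gain.
Features are ranked by each score, the two rank vectors are averaged
(`combine="mean"`; single-score variants available), and the top k = 5
features are selected. Ties break by higher gain ratio, then name.

## 4. Classification and evaluation

Three classifiers: kNN (5 neighbors, Euclidean, uniform weights; k capped at
the training-set size for tiny folds), SVM with RBF kernel (C = 1), and
Random Forest (10 trees, minimum split 5, seeded). Features are z-scored
with training-fold statistics only. The primary protocol is stratified
10-fold cross-validation (seeded shuffling; folds reduce with a warning if
the smaller class has fewer members than folds); a single stratified 75/25
holdout is available as `protocol="holdout"`.

In `top5` mode the ranking is recomputed inside each training fold, so
selection never sees held-out lesions; `leaky_top5=True` ranks once on the
full table for comparison with simpler protocols (it measurably inflates AUC
on pure-noise features).

Metrics are pooled over all cross-validated predictions, with the tumoral
class positive: AUC (threshold-sweep ROC integrated by the trapezoidal rule;
equal to the Mann-Whitney pairwise statistic, ties counted ½),
classification accuracy, F1, precision, recall. Zero-denominator metrics
warn and report 0. ROC points are retained for plotting.

## 5. Synthetic phantom cohorts

Because annotated clinical cohorts cannot ship with the package, a seeded
phantom generator produces ring-enhancing lesions whose *only* class
difference is core texture:

- 240×240 16-bit image; background: Gaussian noise, mean 60, SD 8.
- Ring: annulus of width 5 at a radius sampled in [25, 45], intensity +160,
  centered with jitter but guaranteed margins.
- Core: a correlated Gaussian field — white noise smoothed by a wrap-mode
  Gaussian filter of width `corr_length` and renormalized to the target SD —
  added to mean 120. Inflammatory cores are smooth and mild
  (corr_length 8 px, SD 12); tumoral cores are rough and strong
  (corr_length 2 px, SD 20).
- Additive sensor noise, Gaussian (default SD 3) or Rician.
- `separation ∈ [0, 1]` linearly interpolates the class parameters toward
  their common midpoint; at 0 the classes are statistically identical, which
  provides a built-in null experiment.
- 1–5 ROIs per lesion are placed uniformly among all 10×10 windows lying
  entirely inside the core (verified by an integral-image window sum).

The phantom emulates the *texture contrast* between lesion classes, not
anatomy: there is no skull, no partial-volume effect, no bias field, and the
ring is perfectly circular. It is a test instrument for the pipeline, not a
simulator of pathology. The default cohort (30 + 37, seeded) reproduces the
reference problem size.

At the defaults, the full pipeline recovers the classes nearly perfectly
(Random Forest on top-5 features, mean cross-validated AUC ≥ 0.9 across
seeds at separation 1.0) and stays at chance (AUC 0.5 ± 0.15) at
separation 0.

`synthetic_feature_table` additionally builds pure tabular cohorts (63
Gaussian features, 5 with a planted mean shift) for testing the ranking in
isolation; with a 2 SD shift the dual ranking recovers ≥ 4 of the 5 planted
features in ≥ 90 % of seeded runs.

## 6. Numerical conventions

- All logarithms in entropies are base 2; 0·log 0 ≡ 0 everywhere.
- GLCM/GLRL gray indices are 1-based inside feature formulas.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng` / seeded scikit-learn objects; the `pipeline`
  CLI command is byte-identical across runs with the same configuration.
- Degenerate inputs (constant patches, single-class folds, zero
  denominators) follow documented conventions rather than raising, except
  where the result would be meaningless (single-class cohorts, empty
  prediction frames).
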