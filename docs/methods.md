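# Methods

`nefwheat` classifies wheat varieties by nitrogen-use efficiency from canopy
hyperspectral reflectance. This note records the models and procedures, the
parameters that matter, what the synthetic trials do and do not emulate, and
the design choices made where the workflow was genuinely open.

## The trial and its quantities

The workflow targets a field trial with a panel of candidate varieties plus
two reference cultivars grown at three nitrogen applications — N0 = 0 kg/ha
(low-N stress), N1 = 225 kg/ha (normal), N2 = 450 kg/ha (high-N stress) —
with two replicate plots per variety × level and five canopy sampling
regions per plot. Four phenotypes are measured per plot: wheat yield (WY,
kg/ha), above-ground nitrogen accumulation (ANA, g/plant), dry matter mass
(WDMM, g/plant) and thousand-grain weight (TGW, g).

For a stress contrast (N0 vs N1 or N2 vs N1), replicate means are formed per
variety × level first, and eight indices are computed from the means:

* change rates of WY, ANA, WDMM, TGW: `(stress − control)/control`;
* `NUE = (WY_stress − WY_control)/ΔN` and `AENF = (ANA_stress −
  ANA_control)/ΔN`, where ΔN is the **absolute difference in application
  between the contrast levels** (225 kg/ha for both standard contrasts).
  The literal "applied nitrogen" at N0 is zero, which would make the low-N
  NUE undefined; the difference convention keeps both contrasts on the same
  scale and is the only reading under which the index is finite;
* `NFUE`, a dry-matter ratio statistic. The default is the centred ratio
  `WDMM_stress/WDMM_control − 1`, so "no response" maps to 0 like the change
  rates; a `literal` mode returns the plain ratio. The centred default is an
  inference (a literal ratio cannot be negative, yet the statistic is
  conventionally reported alongside signed change rates and takes negative
  typical values); both modes are computed by the same function;
* `NT = WY_stress/WY_control`, the nitrogen tolerance coefficient.

Summary tables report max, min, sample SD (n − 1 denominator — the
convention is not fixed by the field, sample SD is the conservative choice),
mean, and CV = SD/|mean| as a fraction and a percent, flagged undefined when
the mean is zero.

## Efficiency labeling

Per stress condition, the 8-index variety matrix is column-standardised
(z-scores, sample SD; constant columns map to zero), embedded with t-SNE,
cut into two clusters by complete-linkage agglomerative clustering
(Euclidean distance in embedding space), and the cluster containing the
condition's reference cultivar is labelled *efficient*. The reference is a
control, not a candidate, so it is excluded from the reported sets. The two
conditions combine into three groups — low-N-efficient, high-N-efficient,
inefficient — and a variety efficient under *both* conditions raises a
conflict error rather than being silently resolved: the two efficiency
definitions are disjoint by design, and an overlap means the labeling (or
the data) needs inspection, not a priority rule.

### t-SNE at n ≈ 13

Embedding a dozen points is far outside t-SNE's usual operating range and
the implementation defaults of sklearn are calibrated for thousands of
points. Three settings matter (all in `EmbeddingConfig`):

* **perplexity 2.5** — must satisfy perplexity < (n − 1)/3 (here < 4) and
  stay below the smallest expected cluster (the high-N-efficient group can
  be 3 points including the reference);
* **learning rate 5, early exaggeration 4, 2000 iterations** — the "auto"
  learning rate (floored at 50) and default exaggeration 12 scatter a
  13-point embedding before it converges; in sweeps on synthetic trials the
  default settings recovered the planted two-cluster split in as few as
  0/10 seeds, while the small fixed values recover it 10/10 on both
  contrasts across a broad neighbourhood (perplexity 2–3, rate 1–10);
* **3 output dimensions** by default (2 supported).

The embedding is seeded and deterministic (`method="exact"`, PCA
initialisation). A `skip_tsne` mode clusters the standardised indices
directly and is fully deterministic; it is the right choice when no
visualisation is wanted.

A reflectance-only baseline (`reflectance_cluster_baseline`) clusters the
raw sample-level spectra the same way, votes each variety by its majority
cluster, anchors on the reference, and reports agreement with the
index-based labels — the comparison that motivates supervised
classification over direct clustering of spectra.

## Characteristic-band selection

Canopy spectra (224 bands, 400–1000 nm) are highly collinear; selection
runs two stages in series, both on column-standardised reflectance with the
class target encoded 0/1 (±1 available; with k > 2 classes, ordinal codes —
the selectors are regression-based and an encoding had to be fixed).

**Lasso screening.** L1-penalised linear regression over a log-spaced alpha
grid (default 30 points, 1e-4…1), alpha chosen by minimum mean CV squared
error (5-fold, seeded; the plain CV minimum, not the 1-SE rule). Bands with
non-zero coefficients survive. If the optimum keeps nothing, the smallest
alpha with a non-empty set is used (with a warning).

**CARS refinement.** For runs i = 1…N (default N = 50):

1. draw 80% of samples without replacement;
2. fit PLS regression (A = 5 components, clipped to the retained-set and
   subsample sizes) on the retained bands;
3. weight each band `w_j = |b_j|/Σ|b_j|` from the PLS coefficients;
4. forced reduction: keep the top `⌈r_i·p⌉` bands by weight, where
   `r_i = a·e^(−k·i)` with a, k fixed by `r_1 = 1`, `r_N = 2/p`
   (closed form: `k = ln(p/2)/(N−1)`, `a = e^k`); ties break by ascending
   wavelength so reruns are deterministic;
5. adaptive reweighted sampling (ARS): draw p bands with replacement with
   probability w and retain the union (can be disabled — some published
   variants omit it);
6. score the retained set by 5-fold cross-validated PLS RMSE on all samples.

The retained set of the minimum-RMSECV run wins; the full per-run trace
(sets, ratios, RMSECV) is kept on the result. The Lasso-CARS composition
feeds Lasso survivors into CARS, so the final subset is always a subset of
the Lasso subset; a singleton Lasso result passes through unchanged.

The PLS backbone is sklearn's `PLSRegression` (NIPALS); at A = min(n−1, p)
on full-rank data its predictions coincide with OLS, which the tests use as
an oracle. Derivative/SNV spectral preprocessing is deliberately absent —
selection operates on plain standardised reflectance.

## The serial SVM→XGBoost classifier

Stage 1 standardises the selected-band features and fits an RBF SVM, tuned
by seeded stratified CV over C ∈ {0.1, 1, 10, 100} and gamma ∈ scale
heuristic × {0.1, 1, 10}. Stage 2 appends to the original features, per
sample:

* one-vs-rest decision values (one column per class; for two classes the
  single margin is expanded to ±d so the width is class-count stable), and
* per class, the max and mean RBF-kernel similarity of the sample to that
  class's support vectors (2 columns per class),

giving width `bands + 3·n_classes`, then fits an XGBoost classifier tuned
by seeded CV over depth {2, 3} × learning rate {0.1, 0.3} × 100/300 trees.
The deliberately small grid controls overfitting at n ≈ 120 and keeps
nested cross-validation tractable; wider grids are reachable through
`XgbConfig`.

**Cross-fitted augmentation.** The boosted stage trains on augmented rows
produced by *fold-held-out* SVMs (5-fold internal refit), while prediction
uses the full-data SVM stage. In-sample SVM outputs are systematically
cleaner than anything the model sees at prediction time — a training
support vector has self-similarity exactly 1 — and training the trees on
them teaches artefacts. On the frozen nonlinear fixture the in-sample
variant scores ~9 OA points below the SVM baseline while the cross-fitted
variant scores ~7 above it; cross-fitting is therefore the default and is
the package's reading of "repartitioning the dataset between the stages".

Baselines: SVM, random forest, XGBoost, AdaBoost, each behind the same
fit/predict surface with small seeded grids, scaler fitted on training data
only.

## Evaluation

Confusion counts x_ij (rows actual, columns predicted) give
`OA = 100·Σxᵢᵢ/N` and `Kappa = (N·Σxᵢᵢ − Σxᵢ₊·x₊ᵢ)/(N² − Σxᵢ₊·x₊ᵢ)`
(flagged NaN for the degenerate single-class matrix). Folds are stratified
by class nested within a treatment group: within each (group, class) cell,
shuffled samples are dealt to the currently least-filled folds, so per-fold
class counts within a cell deviate by at most one sample, and classes with
fewer than k members degrade gracefully instead of erroring. The headline
numbers are means over fold-wise OA/Kappa (pooled-matrix versions are
reported alongside). Comparison tables (models, band subsets) share one
fold assignment across rows, recorded as a hash on every row.

## The synthetic trial generator

`SyntheticDesign` defaults *are* the trial conditions: 12 candidate
varieties in field proportions 6 : 2 : 4 (low-N-efficient :
high-N-efficient : inefficient) plus the two references (each planted at
only its two relevant levels), 3 levels, 2 replicates, 5 regions per plot
(120 canopy samples per stress condition), 224 bands on an even 400–1000 nm
grid.

**Spectra** are a fixed vegetation template (dark visible region with a
green bump at 552 nm, logistic red edge at 718 nm, NIR plateau ≈ 0.46)
plus class signal plus noise, clipped to [0, 1]:

* the class signal lives in three signature windows (450–510, 610–660,
  850–900 nm — pigment-absorption and NIR structure regions) as
  raised-cosine bumps scaled by `effect_size` (default 0.05), a class ×
  level *vigor* score (thriving classes stand apart under their stress;
  at N1 all classes are muted — the reason stress treatments exist), and a
  per-variety × window jitter (sd 0.3, clipped ≥ 0.2). The jitter encodes
  varietal spectral idiosyncrasy: same-class varieties are similar, not
  identical, so no single window predicts class perfectly and the windows
  carry partially independent information — without it the windows are
  perfectly redundant and any selector can justifiably discard two of
  them;
* noise is white Gaussian smoothed along the band axis with a Gaussian
  kernel (`collinearity_length` 15 nm), rescaled to `noise_sd` (default
  0.01) via the exact discrete kernel norm; this reproduces the strong
  adjacent-band collinearity (mean |corr| ≈ 0.99) that motivates band
  selection, plus a multiplicative per-sample brightness jitter of the
  same sd.

**Phenotypes** are variety base values (WY ≈ 7000 kg/ha, ANA ≈ 2 g/plant,
WDMM ≈ 15 g/plant, TGW ≈ 45 g, ±8% between varieties) × class response
multipliers (low-N-efficient 1.06/1.00/0.85 across N0/N1/N2,
high-N-efficient 0.78/1.00/1.28, inefficient 0.80/1.00/0.86) ×
`exp(N(0, pheno_noise_sd))` (default 0.03). Noise-free, low-N-efficient
varieties have NT ≥ 1 under the low-N contrast and inefficient varieties
have negative change rates under both, by construction.

All randomness flows through one seeded generator; equal seeds give
bit-identical outputs.

**What the generator does not emulate:** radiative-transfer physics
(PROSAIL-class realism), soil background and atmospheric effects,
instrument-specific band centres, spatial autocorrelation between plot
regions, genotype × environment interaction beyond the class multipliers,
and measurement error in the phenotypes beyond lognormal noise. Passing
recovery tests therefore show the *pipeline* is sound — that the selectors
find planted signal and the labeling finds planted structure under
realistic collinearity and noise — not that field-data accuracies are
reproduced.

## Numerical choices and degenerate inputs

* Reflectance CSV round-trips use shortest-round-trip float headers, so
  read(write(x)) is exact.
* Raster extraction: 0-based row-major pixel indexing, point coordinates at
  pixel centres; an even window of size w at pixel (r, c) covers rows
  r − w/2 + 1 … r + w/2 (point at the lower-left of the central 2×2 block),
  making the block mean of a linear field `a·(r+0.5) + b·(c+0.5) + d` —
  tested against that closed form. The five sampling points are the plot
  centre plus, per vertex, the point 20% along the vertex→centre segment
  starting **at the vertex** (the centre-origin reading is available via
  `offset_origin="center"`). The sampling rule assumes quadrilateral plots.
* Per-band CV screening is diagnostic only; no bands are removed.
* Ties in CARS weights break by ascending wavelength; Lasso band order is
  canonicalised by wavelength, so column order cannot change a selection.
* Zero-variance guards: constant columns standardise to zero, constant
  targets give zero PLS coefficients, zero-mean bands get CV = NaN.

## Problem sizes

Simulation studies run at the trial's own scale (120 samples × 224 bands
per condition; 10 seeds for recovery rates; 20 seeds at 32 bands and 5
folds for the null-accuracy check — the null holds at any width, the
reduced width keeps repeated nested CV brisk). `scripts/acceptance.py`
prints each quantity with the problem size it used.

## Known limitations

* With ~13 varieties the labeling is a small-sample procedure; the t-SNE
  step is stabilised, not fundamentally robust, and `skip_tsne` is the
  conservative mode.
* CARS randomness means the selected subset varies across seeds; the trace
  records every run so a chosen subset is always auditable.
* The three-group partition errors on dual-efficient varieties by design;
  pipelines over noisy data should catch that error and re-examine the
  labeling seeds.
* The classifier predicts only classes seen in training; no probability
  calibration is attempted.
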