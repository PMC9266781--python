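# Methods

This note documents the models behind each stage, the defaults and why they
were chosen, what the synthetic data do and do not emulate, and the numerical
decisions a user should know before trusting or changing the defaults.

## Synthetic measurements

**Raman spectra.** All spectra live on a uniform half-open wavenumber grid
`[start, stop)`; the default 400–1800 cm⁻¹ at 4 cm⁻¹ sampling has exactly
350 points, matching a 600 g/mm-grating spectrometer over the fingerprint
region. Component reference spectra (mitochondria, nuclei, cytoplasm,
lipids, Matrigel, optional unknown, and the two solid drugs) are sums of
Lorentzian bands — the natural line shape of Raman transitions — with an
8 cm⁻¹ default FWHM, a smooth low-amplitude cosine background, and unit
maximum so that noise levels and effect sizes share one scale. The
diagnostic band positions (cytochrome c at 747/1125 cm⁻¹ for mitochondria,
the DNA phosphate pair at 798/1096 cm⁻¹ for nuclei, phenylalanine/amide I at
1001/1660 cm⁻¹ for cytoplasm, the ester C=C at 1750 cm⁻¹ for lipids) are the
assignments standard in cell Raman work; the solid-drug band positions are
synthetic stand-ins.

**Planted drug effects.** A labeled spectra set follows the study design —
three organoid models, three organoids each, classes control/cis/vtx at
three concentrations (cis 30/10/1 µM, vtx 10/4/1.5 µM) and two timepoints
(24/48 h), 20 spectra per organoid and condition (840 spectra per model).
Drug effects add Lorentzian deltas at marker wavenumbers: by default,
cisplatin raises the A-form-DNA/thymidine bands of nuclei (615, 702, 750,
815 cm⁻¹) and a cholesterol-ester band of mitochondria (705 cm⁻¹), while
venetoclax raises DNA/guanine bands of nuclei (1250, 1321, 1455 cm⁻¹) and
the cytochrome-c/CH₂ bands of mitochondria (747, 1125, 1315, 1450 cm⁻¹).
Marker amplitude defaults to 0.045 of the reference maximum — three times
the default relative noise (0.015), the regime in which selection should
succeed but single-band classification stays non-trivial. Dose and time
enter as linear multipliers (1.0/0.85/0.7 by dose rank; 0.9/1.0 for
24/48 h); the measurements report dose trends only qualitatively, so these
are free parameters. Noise is additive Gaussian relative to the reference
maximum (detector-limited regime); Poisson statistics are reserved for the
photon-counting decays, where they dominate.

**Hyperspectral cubes** place the components geometrically (Matrigel
exterior, cytoplasm body, nuclei blobs wrapped in mitochondria rings, lipid
droplets, optional diffuse drug) on a 50 × 50 µm grid at 1 µm pixels, smooth
the abundance maps slightly, and mix `cube = abundances · spectra + noise`.
There is no optics model: no depth sectioning, no detector afterpulsing, no
autofluorescence.

**TCSPC decays** are Poisson draws around the IRF-convolved biexponential
`a1·exp(−t/τ1) + (1−a1)·exp(−t/τ2)` on 1024 channels over 12.5 ns (the
usual TCSPC ADC resolution), with a Gaussian IRF (σ = 0.15 ns, centered at
1 ns).

**FLIM parameter tables** are condition averages: per model, 12 rows
(2 drugs × 3 concentrations × 2 timepoints) × 6 parameters (NADH and FAD
τ1/τ2/α1%), with controls kept separately for the heatmaps. Baselines place
the models in the reported order of metabolic state (NADH α1% ≈ 78 for the
cell line, lower for tissue- and urine-derived organoids). The planted drug
geometry concentrates the cis/vtx discrimination on the (NADH τ2, FAD τ2)
lifetime pair: venetoclax raises the long lifetimes, cisplatin lowers them,
and at the lowest (sub-effective) dose only one of the two lifetimes has
responded per timepoint, with a slight opposite drift in the other. This
last detail matters: it guarantees that no *single* parameter separates the
drugs — any one-dimensional threshold misplaces at least one low-dose
condition — while the pair does so with a wide margin, which is exactly the
structure the minimal-subspace search is meant to detect. Small flat side
effects (venetoclax raising both τ1s, cisplatin lowering both α1%s, the
latter as reported for tissue-derived organoids) stabilize the full
six-parameter clustering; a strict two-parameter variant
(`two_parameter_flim_effects`) keeps the other four parameters constant and
serves as the ground truth for subspace-recovery tests. Because the mining
chain z-normalizes every column, only the *geometry* of the effects matters,
not their absolute size; the design was validated over several hundred
generation seeds.

## Preprocessing

The chain is fixed: despike → baseline → crop → area-normalize, with
standardization applied only on the classifier input path. Cropping before
normalization means the unit integral refers to the cropped support; the two
steps do not commute.

* **Despiking** flags points whose modified z-score of the second difference
  exceeds 6, then confirms a candidate run as a cosmic ray only if it spans
  at most 4 bins and its peak exceeds 1.5× the spectrum maximum outside the
  run. Both guards are needed because at 4 cm⁻¹ sampling a genuine band is
  itself only a few bins wide: curvature alone cannot tell a band from a
  spike, but detector spikes dwarf any molecular band. The noise scale is
  floored at 0.17× the (spike-robust) spectral range so that noiseless
  spectra do not produce spurious candidates. Consequence: spikes below
  roughly twice the strongest band go undetected — acceptable, since real
  cosmic rays exceed the signal by orders of magnitude.
* **Baseline correction** is an iterative clamped polynomial fit (points
  above the fit are pulled down each iteration, so peaks are progressively
  excluded), default order 3; small negative residues are floored at zero.
* **Standardization** (zero mean, unit variance per wavenumber) is fit on
  the full set for feature selection — mirroring how the spectra were
  prepared for selection — but on training rows only inside classification,
  to avoid leakage into the held-out split.

## Unmixing and PCA

True-component analysis is non-negative matrix factorization of the
`pixels × features` matrix with multiplicative Frobenius updates, whose
objective is provably non-increasing (asserted every iteration).
Initialization uses the reference spectra when available, otherwise a
non-negative SVD split; convergence is declared when the residual change per
iteration falls below `tol` (default 1e−7) of the data norm. Components are
matched to references greedily by cosine similarity, one-to-one, with a 0.5
floor below which a component stays unassigned; abundances are not
constrained to sum to one per pixel. Organelle spectra are the raw pixel
spectra of the highest-abundance pixels of the matched component.

PCA delegates to scikit-learn (full SVD); loadings are unit-norm. The
"loading analysis" baseline selects, on the PC whose scores maximize the
between-class ANOVA F statistic (an automated proxy for reading score
separation off a plot), the n largest-|loading| wavenumbers subject to a
minimum mutual separation of one band width (8 cm⁻¹), so adjacent bins of
one band are not returned twice.

## Recursive entropy-based feature selection

One selection run couples a small feed-forward softmax classifier with input
pruning: train until the accuracy gate is passed, score every active feature
by the mean categorical cross-entropy of predictions with that feature
zero-masked (standardized data, so zero = the mean spectrum), keep the
highest-scoring features, and shrink the active set by 20% per pruning with
round-half-up — from 350 features this reaches the 10-feature target in
exactly 16 prunings. The same network is re-optimized across stages
(warm start); inactive features are zero-masked at the input rather than
removed. Ties in the entropy score break toward the lower wavenumber.

Two deliberate choices:

* **The accuracy gate watches training accuracy** (`monitor="train"`,
  validation optional). The gate exists to ensure the optimizer has
  extracted the class structure before a pruning decision, and with a rare
  control class plus hundreds of noise features a 0.98 *validation* accuracy
  is not statistically reachable at the full-feature stage even for an
  oracle-regularized linear model.
* **The default architecture is a single 4-unit hidden layer.** A bottleneck
  that narrow cannot memorize shuffled labels within the 150-epoch stage
  budget (verified empirically), so the gate is only passed by exploiting
  genuinely informative features — label-shuffled data correctly stalls at
  stage 0. It also forces the entropy scores to concentrate on the features
  the network actually needs.

The leave-feature-out entropy is evaluated on the held-out split by default
(`entropy_on`), the more conservative choice. Ensembles repeat the run with
seeds `base_seed + i`; failed runs (gate never passed) are skipped with a
warning. The frequency table reports selections per wavenumber with the
uniform baseline `n_runs · target / n_features` (≈1.43 for 50 runs); the
weighted Jaccard matrix is `J(i,j)·(c_i+c_j)/(2·n_runs)` over the top-m
features, with the plain Jaccard `|both|/|either|` and the selection
frequency on the diagonal — one defensible convention for
occurrence-weighting, isolated in a single function.

## Masked classification

The classifier is the rhomboidal 5-10-20-10-3 network: ReLU hidden layers,
per-node sigmoid output with argmax decision (softmax available), Adam at
η = 0.005, batch 128, 100 epochs, stratified 80/20 split, 10 repeats with
independent splits and initializations. The sigmoid output trains with
per-node binary cross-entropy — the standard pairing; a pure categorical
cross-entropy through independent sigmoids leaves non-true-class nodes
without gradient and collapses training. Metrics (ACC, macro one-vs-rest
SEN and SPE, in percent) are computed by default on the union of training
and validation data, the protocol reported for the original measurements; a
held-out-only mode is one flag away and is what the label-shuffling control
uses. Standardization statistics come from the training rows of each
repeat. Subgroup confusion matrices are resolved by (concentration,
timepoint) with control spectra of the matching timepoint pooled into every
concentration cell.

## FLIM analysis

Decays are fit by iterative reconvolution: the recorded IRF is convolved
with the two-exponential model and optimized by Levenberg–Marquardt (lmfit)
under Pearson weights `1/sqrt(model)`, multi-start (3 seeded restarts),
with the lifetime ordering τ1 ≤ τ2 enforced by swapping. Goodness of fit is
the Pearson reduced χ², with consecutive bins pooled until each pooled bin
expects at least 5 counts (the usual validity rule; this removes low-count
bias in the decay tail); fits are gated at χ² < 1.15. Background pixels are
removed by the 30% maximum-photon-count threshold. The free/bound naming of
NADH (τ1 free, τ2 bound) and FAD (τ1 bound, τ2 free) is applied at the
labeling layer only.

Parameter mining z-normalizes the 12-condition table (controls excluded, as
the question is cis-versus-vtx discrimination), clusters with k-means
(k = 2, best of 50 seeded initializations), and scores each parameter by its
permutation misclassification rate: permute the column, reassign rows to the
*frozen* centroids, and count assignment changes against the unpermuted
nearest-centroid assignment, averaged over 20 seeded repeats. A constant
column permutes to itself and scores exactly zero. The minimal informative
subspace is the shortest prefix of the importance ranking whose re-clustering
separates the drugs perfectly; if none does, the best prefix is returned
flagged.

## Quality control and reporting

Outliers are removed by the iterative two-sided Grubbs test (critical value
from the t-distribution at level α = 0.05); note the classical masking
caveat — two comparably extreme outliers can shield each other.
Normality (Kolmogorov–Smirnov) and one-way ANOVA checks delegate to scipy
and are only reported. `run_pipeline` executes every stage on the synthetic
benchmark, logs per-stage timing, and writes a manifest (config hash, seed,
package versions) plus a deterministic summary JSON — two runs with the same
configuration are byte-identical.

## Problem sizes of the shipped benchmarks

The test-suite and acceptance benchmarks use one organoid model
(840 spectra × 350 features), 10-run selection ensembles, 10 classifier
repeats, 100 simulated decays at 10⁵ photons, and 20 generation seeds for
the FLIM clustering properties. These sizes keep the full suite under a few
minutes on one CPU while leaving every statistical conclusion comfortably
away from its threshold; the ensemble size and all counts scale up by
configuration (`SelectorConfig.n_runs = 50` reproduces the full ensemble
protocol).

## Known limitations

* Synthetic spectra have iid Gaussian noise and fixed band shapes; real
  spectra show correlated baselines, intensity drift, and biological
  variability between organoids of one model. Passing tests demonstrate the
  correctness and statistical behavior of the algorithms, not instrument
  robustness.
* The despiking amplitude guard assumes cosmic rays dwarf the strongest
  band; modest spikes are left in place.
* The FLIM effect geometry is a designed hard case for subspace search;
  real drug responses need not be two-dimensional, and the importance
  ranking is only meaningful when the clustering itself is drug-aligned.
* Grubbs outlier removal assumes approximate normality and suffers from
  masking with multiple outliers.
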