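# ramanflim

Label-free drug-response profiling of tumor organoids couples two readouts:
Raman microspectroscopy (RMS), whose band intensities at specific wavenumbers
fingerprint molecular changes in nuclei and mitochondria, and fluorescence
lifetime imaging (FLIM) of the metabolic coenzymes NADH and FAD, whose
biexponential decay parameters (τ1, τ2, α1%) report the balance of free and
protein-bound coenzyme. `ramanflim` implements the full data-analysis
workflow for discovering spectral and metabolic biomarkers of
cisplatin (*cis*) versus venetoclax (*vtx*) response from such measurements,
exercised end-to-end on synthetic data with known ground truth:

* **Spectral preprocessing** — cosmic-ray removal, iterative polynomial
  baseline correction, cropping to the fingerprint region, area
  normalization and feature-axis standardization.
* **True component analysis** — non-negative matrix factorization
  (multiplicative updates) of hyperspectral cubes into endmember spectra and
  abundance heatmaps, with cosine matching to reference spectra and
  extraction of per-organelle pixel spectra; PCA scores/loadings analysis.
* **Recursive entropy-based feature selection** — a neural-network
  classifier whose input features are recursively pruned by 20% whenever its
  accuracy consistently surpasses τ_acc = 0.98, keeping the features whose
  zero-masking costs the most cross-entropy; 350 spectral features reduce to
  10 in 16 prunings. Repeated runs give per-wavenumber selection
  frequencies and weighted Jaccard co-selection matrices.
* **Masked classification** — a small rhomboidal network (5-10-20-10-3
  nodes, Adam, η = 0.005) trained on five selected wavenumbers, reporting
  accuracy / macro sensitivity / macro specificity over repeated trainings
  and concentration- and exposure-time-resolved confusion matrices.
* **FLIM analysis** — IRF-reconvolution biexponential fits of TCSPC decays
  gated at reduced χ² < 1.15, photon-count thresholding, mean-difference
  heatmaps against the 24 h control, and z-normalized k-means (k = 2) with
  permutation feature importance that identifies the minimal pair of FLIM
  parameters separating the two drugs.

## Worked example

```python
from ramanflim import (generate_component_library, generate_spectra_set,
                       default_effects, StudyDesign)
from ramanflim.selection import (SelectorConfig, ensemble_selection,
                                 prepare_training_data)
from ramanflim.classify import mask_features, train_and_evaluate

library = generate_component_library(seed=1)
design = StudyDesign(models=("RT112",))          # 3 organoids, 14 conditions
spectra = generate_spectra_set(library, default_effects(), design,
                               organelle="nuclei", noise_sd=0.015, seed=1)

data = prepare_training_data(spectra)            # standardize + encode labels
ensemble = ensemble_selection(data, SelectorConfig(n_runs=10), base_seed=1)
print(ensemble.top_table(5).to_string(index=False))

bands = [float(w) for w in ensemble.top_table(5)["wavenumber"]]
report = train_and_evaluate(mask_features(spectra, bands), base_seed=1)
m, s = report.mean, report.sd
print(f"ACC {m['acc']:.1f} +/- {s['acc']:.1f} %")
```

prints

```
 wavenumber  count  percent
     1320.0     10    100.0
     1456.0     10    100.0
      616.0      9     90.0
     1252.0      9     90.0
      700.0      8     80.0
ACC 96.5 +/- 0.4 %
```

The top-5 frequency table recovers the planted drug markers (the guanine /
DNA bands near 1250, 1321 and 1455 cm⁻¹ for venetoclax, the A-form-DNA and
thymidine bands near 615 and 702 cm⁻¹ for cisplatin; entries are grid
wavenumbers at 4 cm⁻¹ sampling), and a classifier seeing only those five
bands separates control / cis / vtx spectra with 96.5% accuracy.

The whole pipeline, from data generation to the summary report, runs from
the command line:

```
ramanflim pipeline --out report/          # or: --config cfg.yaml --seed 3
```

## Layout

| module | contents |
| --- | --- |
| `ramanflim.synthetic` | ground-truth generators: component library, labeled spectra, hyperspectral cubes, TCSPC decays, FLIM tables |
| `ramanflim.preprocess` | despiking, baseline, cropping, normalization, standardization |
| `ramanflim.unmixing` | NMF unmixing, abundance heatmaps, organelle extraction, PCA |
| `ramanflim.nnet` | minimal feed-forward classifier (ReLU, softmax/sigmoid, Adam) |
| `ramanflim.selection` | recursive entropy-based selection, ensembles, weighted Jaccard |
| `ramanflim.classify` | masked-band classifier, ACC/SEN/SPE, subgroup confusion |
| `ramanflim.flim` | decay fitting, heatmaps, k-means mining, permutation importance |
| `ramanflim.pipeline` | orchestration, Grubbs outlier QC, report generation |

See `docs/methods.md` for the models, parameter choices and limitations.
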