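"""End-to-end orchestration, QC statistics and report generation.

``run_pipeline`` executes the full synthetic benchmark: data generation,
preprocessing, TCA unmixing and organelle extraction, PCA, ensemble feature
selection with Jaccard co-selection analysis, masked classification with both
feature-selection methods, FLIM decay fitting, mean-difference heatmaps and
k-means/permutation-importance mining -- and writes a reproducible report
directory (summary JSON, tables, manifest).

QC helpers: iterative two-sided Grubbs outlier removal; normality
(Kolmogorov-Smirnov) and one-way ANOVA checks are delegated to scipy and only
reported.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import classify as _classify
from . import flim as _flim
from . import preprocess as _pre
from . import selection as _sel
from . import synthetic as _syn
from . import unmixing as _unmix

log = logging.getLogger("ramanflim.pipeline")


# ---------------------------------------------------------------------------
# Grubbs outlier test
# ---------------------------------------------------------------------------

def grubbs_critical_value(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value from the t-distribution."""
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t ** 2 / (n - 2 + t ** 2))


def grubbs_outliers(values: np.ndarray, alpha: float = 0.05
                    ) -> tuple[np.ndarray, list[int]]:
    """Iteratively remove the most extreme point while the Grubbs statistic
    ``G = max|x - mean| / sd`` exceeds its critical value at level *alpha*.

    Returns the kept values and the indices (into the original array) of the
    removed points.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("Grubbs test needs at least three values")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    idx = np.arange(x.size)
    removed: list[int] = []
    while x.size >= 3:
        s = x.std(ddof=1)
        if s == 0:
            break
        dev = np.abs(x - x.mean())
        i = int(np.argmax(dev))
        G = dev[i] / s
        if G > grubbs_critical_value(x.size, alpha):
            removed.append(int(idx[i]))
            x = np.delete(x, i)
            idx = np.delete(idx, i)
        else:
            break
    return x, removed


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Aggregated settings; defaults mirror the study protocol (tau_acc 0.98,
    20% reduction, 50 selection runs, 5 masked features, 10 classifier
    repeats, chi2 gate 1.15, 30% photon threshold, k = 2 with 20 importance
    repeats)."""

    seed: int = 0
    models: tuple[str, ...] = ("RT112",)
    organoids_per_model: int = 3
    spectra_per_condition: int = 20
    noise_sd: float = 0.015
    marker_amplitude: float = 0.045
    n_features_selected: int = 5
    cube_size: int = 30
    n_decays: int = 10
    decay_photons: int = 100_000
    selector: _sel.SelectorConfig = field(default_factory=_sel.SelectorConfig)
    classifier: _classify.ClassifierSpec = field(default_factory=_classify.ClassifierSpec)
    importance_repeats: int = 20
    photon_threshold: float = 0.3
    grubbs_alpha: float = 0.05
    spectra_csv: str | None = None   # optional externally supplied spectra
    spectra_labels: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        if "selector" in raw:
            raw["selector"] = _sel.SelectorConfig(**raw["selector"])
        if "classifier" in raw:
            raw["classifier"] = _classify.ClassifierSpec(**raw["classifier"])
        for key in ("models",):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _run_stage(name: str, fn, *args, **kwargs):
    start = time.perf_counter()
    log.info("stage %s: start", name)
    try:
        out = fn(*args, **kwargs)
    except Exception as exc:
        log.error("stage %s: failed (%s)", name, exc)
        raise StageError(name, exc) from exc
    log.info("stage %s: done in %.2fs", name, time.perf_counter() - start)
    return out


# ---------------------------------------------------------------------------
# The pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute every stage on the synthetic benchmark and write the report.

    Outputs: ``summary.json`` (every headline metric), ``manifest.json``
    (config hash, seed, package versions), selection frequency and Jaccard
    CSVs, classification metrics CSV, FLIM tables and heatmap CSV.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config
    summary: dict = {"seed": cfg.seed}

    # -- synthetic inputs -------------------------------------------------
    def _synth():
        library = _syn.generate_component_library(seed=cfg.seed)
        effects = _syn.default_effects(cfg.marker_amplitude)
        design = _syn.StudyDesign(models=cfg.models,
                                  organoids_per_model=cfg.organoids_per_model,
                                  spectra_per_condition=cfg.spectra_per_condition)
        if cfg.spectra_csv is not None:
            spectra = _syn.SpectraSet.from_csv(cfg.spectra_csv, cfg.spectra_labels)
        else:
            spectra = _syn.generate_spectra_set(library, effects, design,
                                                organelle="nuclei",
                                                noise_sd=cfg.noise_sd,
                                                seed=cfg.seed)
        return library, effects, design, spectra

    library, effects, design, raw_spectra = _run_stage(
        "synthesize" if cfg.spectra_csv is None else "read_spectra", _synth)
    summary["n_spectra"] = raw_spectra.n_spectra
    summary["n_features"] = raw_spectra.n_features

    # -- preprocessing ----------------------------------------------------
    clean = _run_stage("preprocess", _pre.preprocess_set, raw_spectra,
                       _pre.PreprocessConfig(crop_range=(raw_spectra.axis.start,
                                                         raw_spectra.axis.stop)))

    # -- unmixing of a demonstration cube --------------------------------
    def _unmix_stage():
        layout = _syn.CubeLayout(width=cfg.cube_size, height=cfg.cube_size,
                                 organoid_center=(cfg.cube_size / 2,) * 2,
                                 organoid_radii=(cfg.cube_size * 0.36,
                                                 cfg.cube_size * 0.3))
        cube = _syn.generate_hyperspectral_cube(library, layout, noise_sd=0.01,
                                                seed=cfg.seed)
        refs = {n: library[n] for n in cube.component_names}
        comps = _unmix.fit_tca(cube, k=len(refs), reference_spectra=refs,
                               seed=cfg.seed)
        extracted = _unmix.extract_organelle_spectra(cube, comps, "mitochondria",
                                                     n_spectra=20)
        return cube, comps, extracted

    _cube, comps, extracted = _run_stage("unmix", _unmix_stage)
    summary["tca_reconstruction_error"] = comps.reconstruction_error
    summary["tca_assignments"] = {str(n): round(c, 4)
                                  for n, c in comps.assignment if n}
    summary["extracted_mitochondria_spectra"] = extracted.n_spectra

    # -- PCA baseline selection ------------------------------------------
    data = _run_stage("standardize", _sel.prepare_training_data, clean)
    pca_features = _run_stage("pca_selection", _sel.pca_loading_selection,
                              data, cfg.n_features_selected)
    summary["pca_selected_wavenumbers"] = pca_features

    # -- ensemble feature selection --------------------------------------
    ensemble = _run_stage("feature_selection", _sel.ensemble_selection,
                          data, cfg.selector, cfg.seed)
    top = ensemble.top_table(cfg.n_features_selected)
    top.to_csv(out / "selection_frequency.csv", index=False)
    W, jac_wavenumbers = _sel.weighted_jaccard(
        ensemble, top_m=min(10, int(np.sum(ensemble.frequency > 0))))
    pd.DataFrame(W, index=jac_wavenumbers, columns=jac_wavenumbers).to_csv(
        out / "jaccard.csv")
    entropy_features = [float(w) for w in top["wavenumber"]]
    summary["entropy_selected_wavenumbers"] = entropy_features
    summary["selection_uniform_baseline"] = ensemble.uniform_baseline
    summary["selection_n_runs"] = ensemble.n_runs

    # -- masked classification, both feature sets ------------------------
    def _classify_stage():
        reports = {}
        for method, feats in (("entropy", entropy_features),
                              ("pca", pca_features)):
            masked = _classify.mask_features(clean, feats)
            rep = _classify.train_and_evaluate(masked, cfg.classifier,
                                               base_seed=cfg.seed)
            rep.dataset = "nuclei"
            reports[method] = rep
        delta = _classify.compare_selection_methods(reports["entropy"],
                                                    reports["pca"])
        return reports, delta

    reports, delta = _run_stage("classification", _classify_stage)
    rows = []
    for method, rep in reports.items():
        m, s = rep.mean, rep.sd
        rows.append({"method": method, **{f"{k}_mean": m[k] for k in m.index},
                     **{f"{k}_sd": s[k] for k in s.index}})
    pd.DataFrame(rows).to_csv(out / "classification_metrics.csv", index=False)
    summary["classification"] = {m: {k: round(v, 2) for k, v in rep.mean.items()}
                                 for m, rep in reports.items()}
    summary["entropy_vs_pca_delta"] = {
        r["metric"]: round(r["delta_mean"], 2) for _i, r in delta.iterrows()}

    # -- FLIM decay fits --------------------------------------------------
    def _flim_fit_stage():
        truths, fits = [], []
        for i in range(cfg.n_decays):
            d = _syn.generate_decay((0.4, 2.5, 0.78), n_photons=cfg.decay_photons,
                                    seed=cfg.seed * 10_000 + i)
            truths.append(d.ground_truth)
            fits.append(_flim.fit_biexponential(d, seed=cfg.seed * 10_000 + i))
        return truths, fits

    truths, fits = _run_stage("flim_fit", _flim_fit_stage)
    fit_df = pd.DataFrame([{"tau1": f.tau1, "tau2": f.tau2,
                            "alpha1_percent": f.alpha1_percent,
                            "reduced_chi2": f.reduced_chi2} for f in fits])
    fit_df.to_csv(out / "flim_fits.csv", index=False)
    summary["flim_fit"] = {
        "chi2_pass_rate": float(np.mean(fit_df["reduced_chi2"] < _flim.CHI2_GATE)),
        "median_tau1": float(fit_df["tau1"].median()),
        "median_tau2": float(fit_df["tau2"].median()),
        "median_alpha1_percent": float(fit_df["alpha1_percent"].median()),
    }

    # -- FLIM tables, heatmaps, clustering -------------------------------
    def _flim_mining_stage():
        results = {}
        for i, model in enumerate(_syn.MODELS):
            table = _syn.generate_flim_table(model=model, seed=cfg.seed + 100 + i)
            heat = _flim.mean_difference_heatmap(table)
            heat.to_csv(out / f"flim_heatmap_{model}.csv")
            mined = _flim.flim_clustering_analysis(
                table, n_repeats=cfg.importance_repeats, base_seed=cfg.seed)
            results[model] = {
                "values_per_model": int(table.values().size),
                "purity": mined["purity"],
            }
        # minimal-subspace search on the two-parameter ground-truth benchmark
        pair_table = _syn.generate_flim_table(
            effects=_syn.two_parameter_flim_effects(), seed=cfg.seed + 200)
        mined = _flim.flim_clustering_analysis(
            pair_table, n_repeats=cfg.importance_repeats, base_seed=cfg.seed)
        results["two_parameter_benchmark"] = {
            "subspace": list(mined["subspace"].params),
            "subspace_purity": mined["subspace"].purity,
            "planted_pair": list(pair_table.ground_truth_pair),
        }
        return results

    summary["flim_mining"] = _run_stage("flim_mining", _flim_mining_stage)

    # -- QC: Grubbs + delegated normality/ANOVA --------------------------
    def _qc_stage():
        col = fit_df["tau2"].to_numpy()
        kept, removed = grubbs_outliers(col, cfg.grubbs_alpha)
        z = (col - col.mean()) / col.std(ddof=1) if col.std(ddof=1) > 0 else col * 0
        ks = stats.kstest(z, "norm")
        groups = [rep.per_repeat["acc"].to_numpy() for rep in reports.values()]
        anova = stats.f_oneway(*groups)
        return {"grubbs_removed": removed,
                "ks_p": round(float(ks.pvalue), 4),
                "anova_acc_p": round(float(anova.pvalue), 6)}

    summary["qc"] = _run_stage("qc", _qc_stage)

    # -- figure analogues -------------------------------------------------
    def _figures():
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 3.5))
        im = ax.imshow(W, cmap="Blues", vmin=0, vmax=1)
        ax.set_xticks(range(len(jac_wavenumbers)),
                      [f"{w:.0f}" for w in jac_wavenumbers], rotation=90,
                      fontsize=6)
        ax.set_yticks(range(len(jac_wavenumbers)),
                      [f"{w:.0f}" for w in jac_wavenumbers], fontsize=6)
        ax.set_title("Weighted Jaccard co-selection")
        fig.colorbar(im)
        fig.tight_layout()
        fig.savefig(out / "jaccard.png", dpi=120)
        plt.close(fig)

        fig, ax = plt.subplots(figsize=(4, 3.5))
        amap = _unmix.abundance_heatmap(comps, "mitochondria")
        ax.imshow(amap, cmap="inferno")
        ax.set_title("Mitochondria abundance")
        ax.axis("off")
        fig.tight_layout()
        fig.savefig(out / "abundance_mitochondria.png", dpi=120)
        plt.close(fig)

    _run_stage("figures", _figures)

    # -- manifest and summary --------------------------------------------
    cfg_json = json.dumps(asdict(cfg), sort_keys=True, default=str)
    manifest = {
        "config": json.loads(cfg_json),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": cfg.seed,
        "versions": {m: __import__(m).__version__
                     for m in ("numpy", "scipy", "pandas", "sklearn", "lmfit")},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return out
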