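"""Classification of drug response from a handful of masked Raman bands.

The classifier is the small rhomboidal fully-connected network
(5-10-20-10-3 nodes, ReLU hidden layers, per-node sigmoid output with argmax
decision) trained with Adam at eta = 0.005, batch size 128, 100 epochs and an
80/20 train/validation split.  Performance -- accuracy (ACC), macro one-vs-
rest sensitivity (SEN) and specificity (SPE), in percent -- is averaged over
repeated independent trainings; by default the metrics are computed on the
union of training and validation data (the protocol reported for the original
measurements), with a held-out-only alternative one configuration flag away.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nnet import MLP
from .selection import stratified_split
from .synthetic import CLASSES, SpectraSet


@dataclass
class ClassifierSpec:
    hidden: tuple[int, ...] = (10, 20, 10)
    output: str = "sigmoid"      # per-node sigmoid, argmax decision
    learning_rate: float = 0.005
    batch_size: int = 128
    epochs: int = 100
    train_fraction: float = 0.8
    n_repeats: int = 10
    evaluate_on: str = "union"   # "union" (train + validation) or "heldout"


@dataclass
class MaskedSet:
    """Spectra restricted to a list of selected wavenumbers."""

    wavenumbers: np.ndarray   # selected bands, order as requested
    X: np.ndarray             # n_spectra x n_selected
    labels: pd.DataFrame
    class_names: tuple[str, ...] = CLASSES

    @property
    def y(self) -> np.ndarray:
        return np.array([self.class_names.index(c) for c in self.labels["class"]])


def mask_features(spectra_set: SpectraSet, wavenumbers: list[float]) -> MaskedSet:
    """Restrict the spectra to the listed wavenumbers (nearest grid point,
    order preserved); a wavenumber off the axis by more than half a step is
    rejected."""
    cols = [spectra_set.axis.index_of(w) for w in wavenumbers]
    grid = spectra_set.axis.values[cols]
    return MaskedSet(wavenumbers=grid, X=spectra_set.intensities[:, cols],
                     labels=spectra_set.labels.copy())


@dataclass
class TrainedClassifier:
    model: MLP
    mean: np.ndarray
    sd: np.ndarray
    class_names: tuple[str, ...]

    def predict(self, X: np.ndarray) -> np.ndarray:
        sd = np.where(self.sd == 0, 1.0, self.sd)
        return self.model.predict((X - self.mean) / sd)


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray,
                     n_classes: int = 3) -> np.ndarray:
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def metrics_from_confusion(cm: np.ndarray) -> tuple[float, float, float]:
    """(ACC, macro SEN, macro SPE) in percent from a confusion matrix.

    Sensitivity and specificity are one-vs-rest per class, averaged with
    equal class weight; classes absent from the truth are skipped.
    """
    total = cm.sum()
    acc = 100.0 * np.trace(cm) / total
    sens, specs = [], []
    for c in range(cm.shape[0]):
        tp = cm[c, c]
        fn = cm[c].sum() - tp
        fp = cm[:, c].sum() - tp
        tn = total - tp - fn - fp
        if tp + fn > 0:
            sens.append(tp / (tp + fn))
        if tn + fp > 0:
            specs.append(tn / (tn + fp))
    return acc, 100.0 * float(np.mean(sens)), 100.0 * float(np.mean(specs))


@dataclass
class MetricsReport:
    per_repeat: pd.DataFrame          # columns: repeat, acc, sen, spe
    confusion: np.ndarray             # pooled over repeats
    models: list[TrainedClassifier] = field(default_factory=list, repr=False)
    dataset: str = ""

    @property
    def mean(self) -> pd.Series:
        return self.per_repeat[["acc", "sen", "spe"]].mean()

    @property
    def sd(self) -> pd.Series:
        return self.per_repeat[["acc", "sen", "spe"]].std(ddof=1)


def train_and_evaluate(masked: MaskedSet, spec: ClassifierSpec | None = None,
                       base_seed: int = 0) -> MetricsReport:
    """Train the masked classifier ``n_repeats`` times with independent
    stratified splits and initializations; standardization statistics are fit
    on the training rows of each repeat and applied everywhere."""
    spec = spec or ClassifierSpec()
    y = masked.y
    classes = np.unique(y)
    if classes.size < 3:
        raise ValueError("all three classes must be present")
    if np.any(np.bincount(y) < 2):
        raise ValueError("each class needs at least two samples")
    rows, models = [], []
    pooled = np.zeros((3, 3), dtype=int)
    for rep in range(spec.n_repeats):
        rng = np.random.default_rng(base_seed + rep)
        tr, va = stratified_split(y, spec.train_fraction, rng)
        if np.unique(y[tr]).size < classes.size:  # pragma: no cover
            warnings.warn("class missing from a split; resplitting", stacklevel=2)
            tr, va = stratified_split(y, spec.train_fraction, rng)
        mean = masked.X[tr].mean(axis=0)
        sd = masked.X[tr].std(axis=0, ddof=0)
        safe = np.where(sd == 0, 1.0, sd)
        Xz = (masked.X - mean) / safe
        model = MLP(masked.X.shape[1], spec.hidden, 3, output=spec.output,
                    learning_rate=spec.learning_rate, seed=base_seed + rep)
        for _ in range(spec.epochs):
            model.train_epoch(Xz[tr], y[tr], spec.batch_size)
        eval_idx = np.concatenate([tr, va]) if spec.evaluate_on == "union" else va
        cm = confusion_matrix(y[eval_idx], model.predict(Xz[eval_idx]))
        acc, sen, spe = metrics_from_confusion(cm)
        rows.append({"repeat": rep, "acc": acc, "sen": sen, "spe": spe})
        pooled += cm
        models.append(TrainedClassifier(model, mean, sd, masked.class_names))
    return MetricsReport(pd.DataFrame(rows), pooled, models)


def confusion_by_subgroup(clf: TrainedClassifier, masked: MaskedSet,
                          ) -> dict[tuple[float, int], dict]:
    """Per (concentration, timepoint) confusion matrices and per-class
    accuracies, with control spectra pooled across concentrations (controls of
    the matching timepoint enter every concentration cell)."""
    labels = masked.labels
    y = masked.y
    pred = clf.predict(masked.X)
    out: dict[tuple[float, int], dict] = {}
    concs = sorted(labels.loc[labels["concentration"].notna(),
                              "concentration"].unique())
    tps = sorted(labels["timepoint"].unique())
    for conc in concs:
        for tp in tps:
            sel = ((labels["timepoint"] == tp)
                   & ((labels["concentration"] == conc)
                      | (labels["class"] == "control"))).to_numpy()
            if not sel.any():
                warnings.warn(f"empty subgroup ({conc}, {tp})", stacklevel=2)
                out[(conc, tp)] = {"confusion": np.zeros((3, 3), dtype=int),
                                   "per_class_accuracy": {}}
                continue
            cm = confusion_matrix(y[sel], pred[sel])
            acc = {masked.class_names[c]: 100.0 * cm[c, c] / cm[c].sum()
                   for c in range(3) if cm[c].sum() > 0}
            out[(conc, tp)] = {"confusion": cm, "per_class_accuracy": acc}
    return out


def compare_selection_methods(report_a: MetricsReport, report_b: MetricsReport
                              ) -> pd.DataFrame:
    """Difference of metric means (A minus B) with the pooled repeat-to-repeat
    standard deviation; both reports must describe the same dataset."""
    if report_a.dataset != report_b.dataset:
        raise ValueError("reports describe different datasets")
    rows = []
    for metric in ("acc", "sen", "spe"):
        da = report_a.per_repeat[metric]
        db = report_b.per_repeat[metric]
        rows.append({
            "metric": metric,
            "delta_mean": da.mean() - db.mean(),
            "pooled_sd": float(np.sqrt((da.var(ddof=1) + db.var(ddof=1)) / 2.0)),
        })
    return pd.DataFrame(rows)
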