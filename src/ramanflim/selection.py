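"""Recursive entropy-based input-feature selection with ensemble statistics.

The selector couples a small feed-forward classifier with recursive input
pruning: the network is (re)trained on the masked spectrum until its
classification accuracy consistently surpasses a threshold (tau_acc = 0.98 by
default); then each still-active feature is zero-masked in turn and the mean
categorical cross-entropy of the predictions is measured -- features whose
masking costs the most information score highest and are kept; the active set
shrinks by a fixed 20% per pruning until 10 features remain (for a 350-point
spectrum, 16 prunings).  Because network initialization is random, the
selection is repeated over an ensemble of runs and evaluated statistically:
per-wavenumber selection frequencies, a top-5 table, and weighted Jaccard
co-selection matrices.

Standardized input puts the mean spectrum at zero, so zero-masking a feature
replaces it with its dataset mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nnet import MLP
from .preprocess import standardize
from .synthetic import CLASSES, SpectraSet
from .unmixing import PCAResult, discriminant_component, pca, top_loading_features


# ---------------------------------------------------------------------------
# Configuration and data container
# ---------------------------------------------------------------------------

@dataclass
class SelectorConfig:
    """Settings of the recursive selector.

    The selection network is deliberately narrow (a single 4-unit hidden
    layer by default): a bottleneck that small cannot memorize label noise
    within the per-stage epoch budget, so the accuracy gate is only passed
    when the optimizer exploits genuinely informative features.  ``monitor``
    chooses the accuracy the gate watches -- the optimizer's own training
    accuracy by default, with held-out validation accuracy as the
    alternative.
    """

    accuracy_threshold: float = 0.98
    reduction_rate: float = 0.2
    target_n_features: int = 10
    consecutive_hits: int = 3
    max_epochs_per_stage: int = 150
    n_runs: int = 50
    architecture: tuple[int, ...] = (4,)
    learning_rate: float = 0.005
    batch_size: int = 128
    train_fraction: float = 0.8
    monitor: str = "train"   # accuracy gate on "train" or "val" rows
    entropy_on: str = "val"  # evaluate leave-feature-out loss on "val" or "train"

    def __post_init__(self) -> None:
        if not 0 < self.accuracy_threshold <= 1 and self.accuracy_threshold != 0:
            raise ValueError("accuracy_threshold must lie in [0, 1]")
        if not 0 < self.reduction_rate < 1:
            raise ValueError("reduction_rate must lie in (0, 1)")
        if self.target_n_features < 1:
            raise ValueError("target_n_features must be >= 1")


@dataclass
class TrainingData:
    """Standardized feature matrix with integer class labels."""

    X: np.ndarray
    y: np.ndarray
    wavenumbers: np.ndarray
    class_names: tuple[str, ...] = CLASSES


def prepare_training_data(spectra_set: SpectraSet,
                          class_names: tuple[str, ...] = CLASSES) -> TrainingData:
    """Standardize along the feature axis and encode class labels."""
    std_set, _stats = standardize(spectra_set)
    y = np.array([class_names.index(c) for c in std_set.labels["class"]])
    return TrainingData(std_set.intensities, y, std_set.axis.values, class_names)


def stratified_split(y: np.ndarray, train_fraction: float,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Seeded stratified train/validation index split."""
    train_idx, val_idx = [], []
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        n_train = max(1, int(round(train_fraction * len(idx))))
        n_train = min(n_train, len(idx) - 1) if len(idx) > 1 else n_train
        train_idx.append(idx[:n_train])
        val_idx.append(idx[n_train:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(val_idx))


# ---------------------------------------------------------------------------
# The pruning machinery
# ---------------------------------------------------------------------------

def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def prune_schedule(n_start: int, reduction_rate: float, target: int,
                   max_steps: int = 10_000) -> list[int]:
    """Stage sizes of the recursive pruning: repeatedly shrink by the
    reduction rate with round-half-up, clamping the last step to the target.

    350 features at 20% reduction reach 10 features in 16 prunings.
    """
    if target < 1 or n_start < target:
        raise ValueError("need n_start > target >= 1")
    sizes: list[int] = []
    n = n_start
    while n > target:
        nxt = _round_half_up(n * (1.0 - reduction_rate))
        if nxt >= n:
            raise ValueError("reduction_rate too small to ever reach the target")
        n = max(nxt, target) if nxt < target else nxt
        sizes.append(n)
        if len(sizes) > max_steps:
            raise ValueError("pruning schedule did not terminate")
    return sizes


def build_selection_classifier(n_inputs: int,
                               architecture: tuple[int, ...] = (32, 16),
                               learning_rate: float = 0.005,
                               seed: int = 0) -> MLP:
    """Feed-forward selection network with ReLU hidden layers and a 3-way
    softmax output, reproducibly initialized."""
    return MLP(n_inputs, tuple(architecture), n_outputs=3, output="softmax",
               learning_rate=learning_rate, seed=seed)


@dataclass
class TrainHistory:
    val_accuracy: list[float]
    reached: bool

    @property
    def epochs(self) -> int:
        return len(self.val_accuracy)


def train_until_threshold(model: MLP, X_train: np.ndarray, y_train: np.ndarray,
                          X_val: np.ndarray, y_val: np.ndarray,
                          config: SelectorConfig) -> TrainHistory:
    """Train with Adam until the monitored accuracy stays at or above tau_acc
    for ``consecutive_hits`` consecutive epoch evaluations, or the per-stage
    epoch budget runs out (``reached`` flag False)."""
    if len(np.unique(y_train)) < 2:
        raise ValueError("training split contains a single class")
    counts = np.bincount(y_train)
    if np.any(counts[counts > 0] < 2):
        raise ValueError("need at least two training samples per class")
    X_mon, y_mon = ((X_train, y_train) if config.monitor == "train"
                    else (X_val, y_val))
    history: list[float] = []
    hits = 0
    for _ in range(config.max_epochs_per_stage):
        model.train_epoch(X_train, y_train, config.batch_size)
        acc = model.accuracy(X_mon, y_mon)
        history.append(acc)
        hits = hits + 1 if acc >= config.accuracy_threshold else 0
        if hits >= config.consecutive_hits:
            return TrainHistory(history, True)
    return TrainHistory(history, False)


def feature_entropy(model: MLP, X_eval: np.ndarray, y_eval: np.ndarray,
                    active_mask: np.ndarray) -> np.ndarray:
    """Leave-feature-out loss for every active feature.

    For feature *f*, predictions are recomputed with column *f* zero-masked
    (all other active columns intact); the score is the mean categorical
    cross-entropy of those predictions.  The higher the score, the more
    information is lost when *f* is removed.
    """
    if X_eval.shape[0] == 0:
        raise ValueError("empty evaluation data")
    Xm = X_eval * active_mask
    active = np.flatnonzero(active_mask)
    scores = np.empty(active.size)
    for i, f in enumerate(active):
        saved = Xm[:, f].copy()
        Xm[:, f] = 0.0
        scores[i] = model.loss(Xm, y_eval)
        Xm[:, f] = saved
    return scores


def prune_step(active_mask: np.ndarray, scores: np.ndarray,
               next_size: int) -> np.ndarray:
    """Keep the ``next_size`` highest-scoring active features; ties break
    toward the lower wavenumber (lower feature index)."""
    if next_size <= 0:
        raise ValueError("next_size must be positive")
    active = np.flatnonzero(active_mask)
    if next_size >= active.size:
        raise ValueError("next_size must be below the active feature count")
    # sort by (-score, index): stable preference for the lower wavenumber
    order = np.lexsort((active, -scores))
    keep = active[order[:next_size]]
    new_mask = np.zeros_like(active_mask)
    new_mask[keep] = True
    return new_mask


# ---------------------------------------------------------------------------
# Full runs and ensembles
# ---------------------------------------------------------------------------

class SelectionStageError(RuntimeError):
    """A pruning stage failed (threshold not reached within the epoch budget)."""

    def __init__(self, stage: int, message: str) -> None:
        super().__init__(f"stage {stage}: {message}")
        self.stage = stage


@dataclass
class SelectionRun:
    mask_history: list[np.ndarray]
    final_mask: np.ndarray
    entropy_history: list[np.ndarray]
    seed: int
    epochs_per_stage: list[int] = field(default_factory=list)


def run_selection(data: TrainingData, config: SelectorConfig | None = None,
                  seed: int = 0) -> SelectionRun:
    """One recursive selection run: train-to-threshold, entropy scoring and
    pruning along the schedule until the target mask size is reached.

    The same network is re-optimized across stages (warm start), mirroring the
    optimizer adapting to the shrinking input; inactive features are
    zero-masked at the input rather than removed.
    """
    config = config or SelectorConfig()
    n_features = data.X.shape[1]
    if len(np.unique(data.y)) != len(data.class_names):
        raise ValueError("all classes must be present")
    rng = np.random.default_rng(seed)
    tr, va = stratified_split(data.y, config.train_fraction, rng)
    model = build_selection_classifier(n_features, config.architecture,
                                       config.learning_rate, seed=seed)
    mask = np.ones(n_features, dtype=bool)
    schedule = prune_schedule(n_features, config.reduction_rate,
                              config.target_n_features)
    masks, entropies, epochs = [], [], []
    for stage, next_size in enumerate(schedule):
        hist = train_until_threshold(model, data.X[tr] * mask, data.y[tr],
                                     data.X[va] * mask, data.y[va], config)
        epochs.append(hist.epochs)
        if not hist.reached:
            raise SelectionStageError(
                stage, f"accuracy threshold {config.accuracy_threshold} not "
                       f"reached within {config.max_epochs_per_stage} epochs")
        ev = va if config.entropy_on == "val" else tr
        scores = feature_entropy(model, data.X[ev], data.y[ev], mask)
        mask = prune_step(mask, scores, next_size)
        masks.append(mask.copy())
        entropies.append(scores)
    return SelectionRun(mask_history=masks, final_mask=mask,
                        entropy_history=entropies, seed=seed,
                        epochs_per_stage=epochs)


@dataclass
class SelectionEnsemble:
    runs: list[SelectionRun]
    frequency: np.ndarray           # selections per feature over the ensemble
    wavenumbers: np.ndarray
    n_runs: int                     # successful runs

    @property
    def uniform_baseline(self) -> float:
        """Expected selections per feature under uniform random masks."""
        target = int(self.runs[0].final_mask.sum())
        return self.n_runs * target / self.frequency.size

    def top_table(self, n: int = 5) -> pd.DataFrame:
        """(wavenumber, count, percent) of the *n* most-selected features."""
        order = np.lexsort((self.wavenumbers, -self.frequency))[:n]
        return pd.DataFrame({
            "wavenumber": self.wavenumbers[order],
            "count": self.frequency[order].astype(int),
            "percent": 100.0 * self.frequency[order] / self.n_runs,
        })


def ensemble_selection(data: TrainingData, config: SelectorConfig | None = None,
                       base_seed: int = 0) -> SelectionEnsemble:
    """Repeat :func:`run_selection` with seeds ``base_seed + run index`` and
    accumulate per-wavenumber selection frequencies.  Failed runs are skipped
    with a warning."""
    config = config or SelectorConfig()
    if config.n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    runs: list[SelectionRun] = []
    for i in range(config.n_runs):
        try:
            runs.append(run_selection(data, config, seed=base_seed + i))
        except SelectionStageError as exc:  # pragma: no cover - data dependent
            warnings.warn(f"selection run {i} skipped: {exc}", stacklevel=2)
    if not runs:
        raise RuntimeError("every selection run failed")
    frequency = np.sum([r.final_mask for r in runs], axis=0).astype(float)
    return SelectionEnsemble(runs=runs, frequency=frequency,
                             wavenumbers=data.wavenumbers, n_runs=len(runs))


def weighted_jaccard(ensemble: SelectionEnsemble, top_m: int = 10
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Co-selection matrix over the *top_m* most frequent features.

    ``J(i, j) = |runs selecting both| / |runs selecting either|`` weighted by
    occurrence counts: ``W(i, j) = J(i, j) (c_i + c_j) / (2 n_runs)``, so the
    diagonal is the selection frequency ``c_i / n_runs``.  Rows/columns are
    ordered by descending frequency; returns ``(W, wavenumbers)``.
    """
    if top_m <= 0:
        raise ValueError("top_m must be positive")
    ever = np.flatnonzero(ensemble.frequency > 0)
    if top_m > ever.size:
        raise ValueError(f"top_m={top_m} exceeds the {ever.size} features ever selected")
    order = np.lexsort((ensemble.wavenumbers, -ensemble.frequency))[:top_m]
    masks = np.stack([r.final_mask for r in ensemble.runs])  # runs x features
    sel = masks[:, order]  # runs x top_m
    counts = sel.sum(axis=0).astype(float)
    both = sel.T.astype(float) @ sel
    either = counts[:, None] + counts[None, :] - both
    with np.errstate(invalid="ignore", divide="ignore"):
        J = np.where(either > 0, both / np.where(either > 0, either, 1.0), 0.0)
    W = J * (counts[:, None] + counts[None, :]) / (2.0 * ensemble.n_runs)
    return W, ensemble.wavenumbers[order]


def pca_loading_selection(data: TrainingData | SpectraSet, n: int = 5) -> list[float]:
    """Baseline comparator: wavenumbers with the largest absolute PCA loadings
    on the most class-discriminating component."""
    if isinstance(data, SpectraSet):
        data = prepare_training_data(data)
    n_comp = min(5, data.X.shape[0] - 1, data.X.shape[1])
    result: PCAResult = pca(data.X, n_components=n_comp,
                            wavenumbers=data.wavenumbers)
    comp = discriminant_component(result, data.y)
    return top_loading_features(result, comp, n)
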