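"""FLIM analysis: biexponential decay fitting and metabolic-parameter mining.

Decay fitting uses iterative reconvolution: the measured instrument response
is convolved with a two-component exponential ``a1 exp(-t/tau1) +
a2 exp(-t/tau2)`` and fit to the TCSPC histogram by weighted least squares
with Poisson weights (lmfit/Levenberg-Marquardt, multi-start).  Fits are
gated on a Pearson reduced chi-square below 1.15; background pixels are
removed by a photon-count threshold (30% of the image maximum).  Lifetimes
follow the internal ordering tau1 <= tau2; the free/bound naming of NADH and
FAD is a labeling convention on top of that.

The parameter-mining half z-normalizes condition-averaged FLIM tables,
clusters drug-treated conditions with k-means (k = 2), scores each of the six
parameters by its permutation misclassification rate against frozen
centroids, and searches the importance ranking greedily for the smallest
parameter subset whose re-clustering separates the two drugs perfectly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import lmfit
import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .synthetic import FLIM_PARAMS, DecayHistogram, FLIMParameterTable, biexponential_model

CHI2_GATE = 1.15


# ---------------------------------------------------------------------------
# Pixel thresholding and decay fitting
# ---------------------------------------------------------------------------

def threshold_pixels(photon_image: np.ndarray, fraction: float = 0.3) -> np.ndarray:
    """Boolean mask of pixels with counts at or above ``fraction`` of the
    image maximum (background removal)."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    img = np.asarray(photon_image)
    peak = img.max()
    if peak <= 0:
        raise ValueError("image contains no photons")
    return img >= fraction * peak


def alpha1_percent(a1: float, a2: float) -> float:
    """Amplitude fraction of the first component, ``100 a1 / (a1 + a2)``."""
    if a1 + a2 <= 0:
        raise ValueError("amplitudes must not both be zero")
    return 100.0 * a1 / (a1 + a2)


@dataclass
class FLIMFitResult:
    tau1: float
    tau2: float
    alpha1: float
    alpha2: float
    alpha1_percent: float
    reduced_chi2: float
    converged: bool

    def __post_init__(self) -> None:
        if self.tau1 > self.tau2:
            raise ValueError("lifetime ordering tau1 <= tau2 violated")

    @property
    def accepted(self) -> bool:
        return self.reduced_chi2 < CHI2_GATE


def _pearson_reduced_chi2(observed: np.ndarray, fitted: np.ndarray,
                          n_params: int, min_expected: float = 5.0) -> float:
    """Pearson chi-square with Poisson variance ~ fitted counts.

    Consecutive bins are pooled until each pooled bin has an expected count of
    at least ``min_expected`` (the usual validity rule for Pearson's
    statistic), which protects the tail of the decay from low-count bias.
    """
    obs_p, fit_p = [], []
    acc_o = acc_f = 0.0
    for o, f in zip(observed.astype(float), fitted.astype(float)):
        acc_o += o
        acc_f += f
        if acc_f >= min_expected:
            obs_p.append(acc_o)
            fit_p.append(acc_f)
            acc_o = acc_f = 0.0
    if acc_f > 0 and fit_p:
        obs_p[-1] += acc_o
        fit_p[-1] += acc_f
    obs = np.asarray(obs_p)
    fit = np.asarray(fit_p)
    dof = obs.size - n_params
    if dof <= 0:
        raise ValueError("too few bins for a chi-square")
    return float(np.sum((obs - fit) ** 2 / fit) / dof)


def fit_biexponential(decay: DecayHistogram, n_restarts: int = 3,
                      seed: int = 0, mono: bool = False) -> FLIMFitResult:
    """Fit the IRF-reconvolved biexponential model to a TCSPC histogram.

    With ``mono=True`` the second component is switched off (a1 fixed at 1),
    fitting a single lifetime.

    Weighted least squares with Poisson (Pearson) weights ``1/sqrt(model)``;
    the best of ``n_restarts`` seeded starting points is kept.  Parameters are
    returned with ``tau1 <= tau2``; non-convergence after all restarts yields
    the best attempt with ``converged=False``.
    """
    t, counts, irf = decay.bin_times, decay.counts.astype(float), decay.irf
    total = counts.sum()
    if total < 1e3:
        warnings.warn("fewer than 1000 photons; fit may be unstable", stacklevel=2)

    def residual(params: lmfit.Parameters) -> np.ndarray:
        model = params["scale"].value * total * biexponential_model(
            t, irf, params["tau1"].value, params["tau2"].value,
            params["a1"].value)
        return (counts - model) / np.sqrt(np.maximum(model, 1.0))

    # moment-based starting guess: mean arrival delay past the IRF centroid
    centroid = float(np.sum(t * irf))
    mean_tau = max(float(np.sum(t * counts) / total - centroid), 0.1)
    rng = np.random.default_rng(seed)
    best = None
    for attempt in range(n_restarts):
        jitter = rng.uniform(0.7, 1.3, size=2) if attempt else np.ones(2)
        params = lmfit.Parameters()
        params.add("tau1", value=(1.0 if mono else 0.4) * mean_tau * jitter[0],
                   min=1e-3, max=50.0)
        params.add("tau2", value=2.0 * mean_tau * jitter[1], min=1e-3, max=50.0,
                   vary=not mono)
        params.add("a1", value=1.0 if mono else 0.6, min=0.0, max=1.0,
                   vary=not mono)
        params.add("scale", value=1.0, min=0.1, max=10.0)
        try:
            res = lmfit.minimize(residual, params, method="leastsq")
        except Exception:  # pragma: no cover - optimizer failure path
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
        if res.success:
            break
    if best is None:
        raise RuntimeError("decay fit failed on every restart")
    p = best.params
    tau1, tau2, a1 = p["tau1"].value, p["tau2"].value, p["a1"].value
    if tau1 > tau2:
        tau1, tau2, a1 = tau2, tau1, 1.0 - a1
    fitted = p["scale"].value * total * biexponential_model(t, irf, tau1, tau2, a1)
    chi2 = _pearson_reduced_chi2(counts, fitted, n_params=4)
    alpha1 = a1 * total
    alpha2 = (1.0 - a1) * total
    return FLIMFitResult(tau1=tau1, tau2=tau2, alpha1=alpha1, alpha2=alpha2,
                         alpha1_percent=alpha1_percent(alpha1, alpha2),
                         reduced_chi2=chi2, converged=bool(best.success))


# ---------------------------------------------------------------------------
# Parameter tables: heatmaps, z-norm, clustering, importance
# ---------------------------------------------------------------------------

def mean_difference_heatmap(table: FLIMParameterTable,
                            reference_timepoint: int = 24) -> pd.DataFrame:
    """Per (drug, concentration, timepoint) condition and parameter: mean of
    the condition minus mean of the reference control (24 h by default)."""
    ref = table.controls[table.controls["timepoint"] == reference_timepoint]
    if ref.empty:
        raise ValueError(f"no control rows at {reference_timepoint} h")
    ref_mean = ref[list(FLIM_PARAMS)].mean()
    grouped = table.data.groupby(["drug", "concentration", "timepoint"])[
        list(FLIM_PARAMS)].mean()
    return grouped - ref_mean


def znorm_table(values: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Scale every parameter column to zero mean and unit standard deviation;
    zero-variance columns become zeros with a warning."""
    X = values[list(FLIM_PARAMS)].to_numpy() if isinstance(values, pd.DataFrame) \
        else np.asarray(values, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least two rows to z-normalize")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        warnings.warn("zero-variance columns z-normalized to 0", stacklevel=2)
    Z = (X - mean) / np.where(sd == 0, 1.0, sd)
    Z[:, sd == 0] = 0.0
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(Z, columns=list(FLIM_PARAMS), index=values.index)
    return Z


@dataclass
class ClusterResult:
    labels: np.ndarray
    centroids: np.ndarray
    inertia: float


def cluster_k2(values: np.ndarray | pd.DataFrame, seed: int = 0,
               n_init: int = 50) -> ClusterResult:
    """k-means with k = 2 (Lloyd's algorithm, best of ``n_init`` seeded
    initializations by within-cluster sum of squares)."""
    X = np.asarray(values, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] < 2:
        raise ValueError("need at least two rows to cluster")
    if np.allclose(X, X[0]):
        raise ValueError("all rows identical; clustering is degenerate")
    km = KMeans(n_clusters=2, n_init=n_init, random_state=seed).fit(X)
    return ClusterResult(labels=km.labels_, centroids=km.cluster_centers_,
                         inertia=float(km.inertia_))


def cluster_purity(cluster_labels: np.ndarray, group_labels: np.ndarray) -> float:
    """Fraction of rows in agreement under the best cluster-to-group matching."""
    groups = pd.factorize(np.asarray(group_labels))[0]
    agree = np.mean(cluster_labels == groups)
    return float(max(agree, 1.0 - agree))


@dataclass
class ImportanceResult:
    param_names: tuple[str, ...]
    rates: np.ndarray          # mean permutation misclassification rate per parameter
    per_repeat: np.ndarray     # n_repeats x n_params
    ranking: tuple[str, ...]   # parameters by descending importance


def permutation_importance(values: np.ndarray | pd.DataFrame,
                           clustering: ClusterResult,
                           n_repeats: int = 20, base_seed: int = 0,
                           param_names: tuple[str, ...] = FLIM_PARAMS
                           ) -> ImportanceResult:
    """Permutation misclassification rate per parameter against the frozen
    k-means centroids.

    For each repeat (seeded ``base_seed + repeat``) and each parameter, the
    parameter's column is permuted, every row is reassigned to the nearest
    centroid, and the fraction of rows changing cluster relative to the
    unpermuted nearest-centroid assignment is recorded; the mean over repeats
    is the parameter's importance.  A constant column permutes to itself, so
    its importance is exactly zero.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    X = np.asarray(values, dtype=float)
    n, p = X.shape
    cent = clustering.centroids

    def nearest(A: np.ndarray) -> np.ndarray:
        d = ((A[:, None, :] - cent[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d, axis=1)

    baseline = nearest(X)
    rates = np.zeros((n_repeats, p))
    for r in range(n_repeats):
        rng = np.random.default_rng(base_seed + r)
        for j in range(p):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            rates[r, j] = np.mean(nearest(Xp) != baseline)
    mean_rates = rates.mean(axis=0)
    order = np.argsort(-mean_rates, kind="stable")
    return ImportanceResult(param_names=tuple(param_names), rates=mean_rates,
                            per_repeat=rates,
                            ranking=tuple(param_names[i] for i in order))


@dataclass
class SubspaceResult:
    params: tuple[str, ...]
    purity: float
    achieved: bool


def minimal_informative_subspace(table: FLIMParameterTable,
                                 importance: ImportanceResult,
                                 seed: int = 0, n_init: int = 50) -> SubspaceResult:
    """Smallest prefix of the importance ranking on which re-clustering the
    z-normalized table yields drug-pure clusters (purity 1.0).  If no prefix
    reaches purity 1.0 the best one is returned flagged ``achieved=False``."""
    Z = znorm_table(table.data)
    drugs = table.data["drug"].to_numpy()
    best: SubspaceResult | None = None
    for size in range(1, len(importance.ranking) + 1):
        subset = importance.ranking[:size]
        sub = Z[list(subset)].to_numpy()
        result = cluster_k2(sub, seed=seed, n_init=n_init)
        purity = cluster_purity(result.labels, drugs)
        if best is None or purity > best.purity:
            best = SubspaceResult(params=tuple(subset), purity=purity,
                                  achieved=purity >= 1.0)
        if purity >= 1.0:
            return SubspaceResult(params=tuple(subset), purity=1.0, achieved=True)
    assert best is not None
    return best


def flim_clustering_analysis(table: FLIMParameterTable, n_repeats: int = 20,
                             base_seed: int = 0, n_init: int = 50) -> dict:
    """Full mining chain on one model's table: z-norm, k-means (k = 2) on the
    drug-treated rows, permutation importance, minimal informative subspace.
    Returns a dict with the intermediate results and drug purity."""
    Z = znorm_table(table.data)
    clustering = cluster_k2(Z.to_numpy(), seed=base_seed, n_init=n_init)
    purity = cluster_purity(clustering.labels, table.data["drug"].to_numpy())
    importance = permutation_importance(Z.to_numpy(), clustering,
                                        n_repeats=n_repeats, base_seed=base_seed)
    subspace = minimal_informative_subspace(table, importance, seed=base_seed,
                                            n_init=n_init)
    return {"znormed": Z, "clustering": clustering, "purity": purity,
            "importance": importance, "subspace": subspace}
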