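"""TCA-style spectral unmixing and PCA of Raman data.

True component analysis (TCA) is modeled as non-negative matrix factorization
of the ``pixels x features`` matrix with multiplicative Frobenius updates:
``X ~ W H`` where the rows of ``H`` are non-negative endmember spectra and the
columns of ``W`` are per-pixel abundances.  Recovered components are matched
one-to-one to library reference spectra by cosine similarity, abundances are
rendered as false-color heatmaps, and the highest-abundance pixels provide
the per-organelle spectra used downstream.

PCA (scores, unit-norm loadings, explained variance) delegates to
scikit-learn; the loading analysis mimics the conventional manual reading of
loading plots by returning the strongest-loading wavenumbers of the most
class-discriminating component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA as _SKPCA

from .synthetic import HyperspectralCube, SpectraSet

_EPS = 1e-12


# ---------------------------------------------------------------------------
# Non-negative matrix factorization (multiplicative updates)
# ---------------------------------------------------------------------------

@dataclass
class ComponentSet:
    """NMF endmembers with abundances and reference assignments."""

    spectra: np.ndarray            # k x n_features, >= 0
    abundances: np.ndarray         # height x width x k, >= 0
    assignment: list[tuple[str | None, float]]  # per component: (name, cosine)
    reconstruction_error: float    # relative Frobenius residual
    objective_history: np.ndarray
    converged: bool

    def index_of(self, name: str) -> int:
        for i, (n, _c) in enumerate(self.assignment):
            if n == name:
                return i
        raise KeyError(f"no component assigned to {name!r}")


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def _nndsvd_init(X: np.ndarray, k: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Non-negative SVD-based initialization (positive/negative part split)."""
    rng = np.random.default_rng(seed)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    W = np.zeros((X.shape[0], k))
    H = np.zeros((k, X.shape[1]))
    W[:, 0] = np.sqrt(S[0]) * np.abs(U[:, 0])
    H[0] = np.sqrt(S[0]) * np.abs(Vt[0])
    for j in range(1, min(k, len(S))):
        u, v = U[:, j], Vt[j]
        up, un = np.maximum(u, 0), np.maximum(-u, 0)
        vp, vn = np.maximum(v, 0), np.maximum(-v, 0)
        if np.linalg.norm(up) * np.linalg.norm(vp) >= np.linalg.norm(un) * np.linalg.norm(vn):
            uu, vv = up, vp
        else:
            uu, vv = un, vn
        nu, nv = np.linalg.norm(uu), np.linalg.norm(vv)
        if nu * nv == 0:
            uu = rng.uniform(0, 1, X.shape[0])
            vv = rng.uniform(0, 1, X.shape[1])
            nu, nv = np.linalg.norm(uu), np.linalg.norm(vv)
        W[:, j] = np.sqrt(S[j] * nu * nv) * uu / nu
        H[j] = np.sqrt(S[j] * nu * nv) * vv / nv
    mean = X.mean()
    W[W < _EPS] = mean * 1e-3
    H[H < _EPS] = mean * 1e-3
    return W, H


def fit_tca(cube: HyperspectralCube, k: int,
            reference_spectra: dict[str, np.ndarray] | None = None,
            max_iter: int = 500, tol: float = 1e-7, seed: int = 0,
            match_threshold: float = 0.5) -> ComponentSet:
    """Unmix a hyperspectral cube into *k* non-negative components.

    With ``reference_spectra`` given, the endmember matrix is initialized from
    the references (in dict order) and the recovered components are matched to
    the reference names greedily by maximal cosine similarity, one-to-one;
    components below ``match_threshold`` stay unassigned.  Without references,
    a non-negative SVD-based initialization is used.  The multiplicative
    updates guarantee a non-increasing Frobenius objective, which is asserted
    per iteration.
    """
    X = cube.pixels()
    n_pixels, n_features = X.shape
    if k < 1 or k > n_pixels or k > n_features:
        raise ValueError(f"k={k} must lie in [1, min(n_pixels, n_features)]")
    if np.any(X < 0):
        raise ValueError("cube intensities must be non-negative")
    rng = np.random.default_rng(seed)
    names = list(reference_spectra) if reference_spectra else []
    if reference_spectra is not None:
        if len(reference_spectra) < k:
            raise ValueError("need at least k reference spectra for initialization")
        H = np.stack([np.asarray(reference_spectra[n], dtype=float)
                      for n in names[:k]])
        H = np.maximum(H, _EPS)
        W = rng.uniform(0.1, 1.0, size=(n_pixels, k)) * X.mean() / max(H.mean(), _EPS)
    else:
        W, H = _nndsvd_init(X, k, seed)

    norm_X = np.linalg.norm(X)
    objective = [float(np.linalg.norm(X - W @ H))]
    converged = False
    for _ in range(max_iter):
        W *= (X @ H.T) / (W @ (H @ H.T) + _EPS)
        H *= (W.T @ X) / ((W.T @ W) @ H + _EPS)
        obj = float(np.linalg.norm(X - W @ H))
        assert obj <= objective[-1] * (1 + 1e-9), "NMF objective increased"
        rel_change = (objective[-1] - obj) / max(norm_X, _EPS)
        objective.append(obj)
        if rel_change < tol:
            converged = True
            break
    if not converged:
        warnings.warn("NMF did not converge within max_iter", stacklevel=2)

    # normalize endmembers to unit max, fold scale into abundances
    scale = H.max(axis=1)
    scale[scale == 0] = 1.0
    H = H / scale[:, None]
    W = W * scale[None, :]

    assignment: list[tuple[str | None, float]] = [(None, 0.0)] * k
    if reference_spectra is not None:
        sim = np.array([[_cosine(H[i], np.asarray(reference_spectra[n]))
                         for n in names] for i in range(k)])
        free_comp, free_ref = set(range(k)), set(range(len(names)))
        while free_comp and free_ref:
            i, j = max(((i, j) for i in free_comp for j in free_ref),
                       key=lambda ij: sim[ij])
            if sim[i, j] < match_threshold:
                break
            assignment[i] = (names[j], float(sim[i, j]))
            free_comp.remove(i)
            free_ref.remove(j)

    h, w, _f = cube.shape
    return ComponentSet(spectra=H, abundances=W.reshape(h, w, k),
                        assignment=assignment,
                        reconstruction_error=objective[-1] / max(norm_X, _EPS),
                        objective_history=np.asarray(objective),
                        converged=converged)


def abundance_heatmap(component_set: ComponentSet, name: str) -> np.ndarray:
    """Min-max scaled ([0, 1]) abundance map of the named component."""
    idx = component_set.index_of(name)
    amap = component_set.abundances[..., idx]
    if np.all(amap == 0):
        warnings.warn(f"component {name!r} has an all-zero abundance map",
                      stacklevel=2)
        return np.zeros_like(amap)
    lo, hi = amap.min(), amap.max()
    if hi == lo:
        return np.ones_like(amap)
    return (amap - lo) / (hi - lo)


def extract_organelle_spectra(cube: HyperspectralCube,
                              component_set: ComponentSet,
                              name: str, n_spectra: int = 20,
                              condition: dict | None = None) -> SpectraSet:
    """Pixel spectra of the *n_spectra* highest-abundance pixels of the named
    component, labeled with the cube's condition metadata."""
    idx = component_set.index_of(name)
    amap = component_set.abundances[..., idx].ravel()
    available = int(np.sum(amap > 0))
    if n_spectra > available:
        raise ValueError(f"requested {n_spectra} spectra but only {available} "
                         f"pixels have positive {name!r} abundance")
    order = np.argsort(amap)[::-1][:n_spectra]
    X = cube.pixels()[order]
    meta = {"class": "control", "model": "RT112", "organoid_id": "RT112-0",
            "concentration": None, "timepoint": 24}
    meta.update(cube.metadata or {})
    meta.update(condition or {})
    meta.pop("drug", None)
    labels = pd.DataFrame([{**meta, "organelle": name} for _ in range(n_spectra)])
    return SpectraSet(cube.axis, X, labels[list(
        ("class", "model", "organelle", "organoid_id", "concentration",
         "timepoint"))])


# ---------------------------------------------------------------------------
# PCA and loading analysis
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    scores: np.ndarray                    # n_spectra x n_components
    loadings: np.ndarray                  # n_components x n_features, unit norm
    explained_variance_percent: np.ndarray
    wavenumbers: np.ndarray


def pca(spectra: SpectraSet | np.ndarray, n_components: int = 5,
        wavenumbers: np.ndarray | None = None) -> PCAResult:
    """Mean-centered PCA with unit-norm loadings and explained variance %."""
    if isinstance(spectra, SpectraSet):
        X = spectra.intensities
        wavenumbers = spectra.axis.values
    else:
        X = np.asarray(spectra, dtype=float)
        if wavenumbers is None:
            wavenumbers = np.arange(X.shape[1], dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least two spectra")
    if n_components > min(X.shape[0] - 1, X.shape[1]):
        raise ValueError("n_components exceeds the data rank bound")
    model = _SKPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    return PCAResult(scores=scores, loadings=model.components_,
                     explained_variance_percent=100 * model.explained_variance_ratio_,
                     wavenumbers=np.asarray(wavenumbers, dtype=float))


def top_loading_features(result: PCAResult, component_index: int, n: int,
                         min_separation: float = 8.0) -> list[float]:
    """The *n* wavenumbers with largest absolute loading on the chosen PC,
    greedily enforcing a pairwise separation of one band width so adjacent
    bins of the same band are not returned twice."""
    if not 0 <= component_index < result.loadings.shape[0]:
        raise ValueError("component does not exist")
    if n > result.loadings.shape[1]:
        raise ValueError("n exceeds the number of features")
    loading = np.abs(result.loadings[component_index])
    order = np.argsort(loading)[::-1]
    chosen: list[float] = []
    for idx in order:
        w = result.wavenumbers[idx]
        if all(abs(w - c) >= min_separation for c in chosen):
            chosen.append(float(w))
        if len(chosen) == n:
            return chosen
    raise ValueError(f"could not find {n} wavenumbers separated by "
                     f">= {min_separation} cm^-1")


def discriminant_component(result: PCAResult, classes: np.ndarray | pd.Series) -> int:
    """Index of the PC whose scores best separate the classes (one-way ANOVA
    F-statistic) -- an automated stand-in for choosing the loading plot whose
    score axis shows treatment separation."""
    classes = np.asarray(classes)
    best, best_f = 0, -np.inf
    for j in range(result.scores.shape[1]):
        groups = [result.scores[classes == c, j] for c in np.unique(classes)]
        if len(groups) < 2:
            raise ValueError("need at least two classes")
        f = stats.f_oneway(*groups).statistic
        if np.isfinite(f) and f > best_f:
            best, best_f = j, float(f)
    return best
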