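"""Raman spectral preprocessing: despiking, baseline removal, cropping,
area normalization and feature-axis standardization.

The chain runs in a fixed order -- despike -> baseline -> crop ->
area-normalize -> (standardize, for classifier input only).  Cropping before
normalization matters: the unit integral is computed on the cropped support,
so the two steps do not commute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .synthetic import SpectraSet, WavenumberAxis


@dataclass
class PreprocessConfig:
    despike_z_threshold: float = 6.0
    baseline_order: int = 3
    crop_range: tuple[float, float] = (400.0, 1800.0)
    normalization: str = "area"
    standardize: bool = False

    def __post_init__(self) -> None:
        if self.baseline_order < 0:
            raise ValueError("baseline_order must be >= 0")
        lo, hi = self.crop_range
        if lo >= hi:
            raise ValueError("crop_range must satisfy lo < hi")


def remove_cosmic_rays(spectrum: np.ndarray, z_threshold: float = 6.0,
                       amplitude_factor: float = 1.5,
                       max_run: int = 4) -> np.ndarray:
    """Replace cosmic-ray spikes by linear interpolation of clean neighbors.

    Candidate points are those whose modified z-score
    (0.6745 |d - median| / MAD) of the second difference exceeds
    *z_threshold*.  Because genuine Raman bands can be only a few bins wide
    at typical sampling, curvature alone cannot separate them from spikes; a
    candidate run is confirmed as a cosmic ray only when it is at most
    ``max_run`` bins long (spikes hit one or two detector pixels) AND its
    peak exceeds ``amplitude_factor`` times the spectrum maximum outside the
    run -- detector spikes dwarf any molecular band.
    """
    s = np.asarray(spectrum, dtype=float)
    if s.size < 5:
        raise ValueError("spectrum too short to despike")
    d2 = np.zeros_like(s)
    d2[1:-1] = s[:-2] - 2 * s[1:-1] + s[2:]
    med = np.median(d2)
    mad = np.median(np.abs(d2 - med))
    # floor the noise scale at a fraction of the (spike-robust) spectral
    # range: a narrow molecular band curves by at most ~its own height, a
    # detector spike by orders of magnitude more, so this keeps bands out of
    # the candidate set even in (near-)noiseless spectra
    span = float(np.percentile(s, 98) - np.percentile(s, 2))
    mad_eff = max(mad, 0.17 * span)
    if mad_eff == 0:
        return s.copy()
    z = 0.6745 * np.abs(d2 - med) / mad_eff
    candidates = z > z_threshold
    flagged = np.zeros_like(candidates)
    i = 0
    while i < s.size:
        if candidates[i]:
            j = i
            while j + 1 < s.size and candidates[j + 1]:
                j += 1
            rest = np.delete(s, np.s_[i:j + 1])
            if (j - i + 1 <= max_run
                    and s[i:j + 1].max() > amplitude_factor * rest.max()):
                flagged[i:j + 1] = True
            i = j + 1
        else:
            i += 1
    if flagged.all():
        raise ValueError("every point flagged as a spike; degenerate spectrum")
    if not flagged.any():
        return s.copy()
    idx = np.arange(s.size)
    out = s.copy()
    out[flagged] = np.interp(idx[flagged], idx[~flagged], s[~flagged])
    return out


def subtract_baseline(spectrum: np.ndarray, order: int = 3,
                      n_iter: int = 50, tol: float = 1e-6) -> np.ndarray:
    """Iteratively reweighted polynomial baseline subtraction.

    A degree-*order* polynomial is fit, points above the fit are clamped down
    to it (so peaks are progressively excluded), and the fit repeats until the
    working signal stabilizes.  The final polynomial is subtracted and small
    negative residues are floored at zero.
    """
    s = np.asarray(spectrum, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("spectrum contains non-finite values")
    if order >= s.size:
        raise ValueError("polynomial order must be below the spectrum length")
    x = np.linspace(-1.0, 1.0, s.size)
    work = s.copy()
    scale = max(np.ptp(s), 1.0)
    baseline = np.zeros_like(s)
    for _ in range(n_iter):
        coef = np.polynomial.polynomial.polyfit(x, work, order)
        baseline = np.polynomial.polynomial.polyval(x, coef)
        clipped = np.minimum(work, baseline)
        if np.max(np.abs(clipped - work)) < tol * scale:
            work = clipped
            break
        work = clipped
    out = s - baseline
    return np.where(out < 0, 0.0, out)


def crop(spectra_set: SpectraSet, lo: float, hi: float) -> SpectraSet:
    """Restrict the axis and intensity columns to ``[lo, hi)``; labels pass
    through untouched."""
    v = spectra_set.axis.values
    keep = (v >= lo) & (v < hi)
    if not keep.any():
        raise ValueError(f"crop [{lo}, {hi}) does not overlap the axis")
    new_axis = WavenumberAxis(float(v[keep][0]),
                              float(v[keep][-1]) + spectra_set.axis.step,
                              spectra_set.axis.step)
    return SpectraSet(new_axis, spectra_set.intensities[:, keep],
                      spectra_set.labels.copy())


def normalize_area(spectrum: np.ndarray, axis: WavenumberAxis | np.ndarray) -> np.ndarray:
    """Scale so the trapezoidal integral over the wavenumber axis equals 1."""
    v = axis.values if isinstance(axis, WavenumberAxis) else np.asarray(axis)
    s = np.asarray(spectrum, dtype=float)
    area = np.trapezoid(s, v)
    if area <= 0:
        raise ValueError("integrated intensity must be positive")
    return s / area


@dataclass
class StandardizationStats:
    mean: np.ndarray
    sd: np.ndarray


def standardize(spectra_set: SpectraSet,
                stats: StandardizationStats | None = None
                ) -> tuple[SpectraSet, StandardizationStats]:
    """Zero-mean unit-variance scaling along the feature axis.

    With ``stats=None`` the statistics are fit on the given rows; passing
    stored stats applies them to held-out rows (no leakage).  Zero-variance
    features are set to 0 with a warning.
    """
    X = spectra_set.intensities
    if stats is None:
        if X.shape[0] < 2:
            raise ValueError("need at least two spectra to fit statistics")
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        if np.any(sd == 0):
            warnings.warn("zero-variance features standardized to 0", stacklevel=2)
        stats = StandardizationStats(mean=mean, sd=sd)
    safe_sd = np.where(stats.sd == 0, 1.0, stats.sd)
    Z = (X - stats.mean) / safe_sd
    Z[:, stats.sd == 0] = 0.0
    return SpectraSet(spectra_set.axis, Z, spectra_set.labels.copy()), stats


def preprocess_set(spectra_set: SpectraSet,
                   config: PreprocessConfig | None = None) -> SpectraSet:
    """Run despike -> baseline -> crop -> area-normalize on every spectrum.

    Standardization is not applied here; it belongs to the classifier input
    path where the statistics must come from training rows only.
    """
    config = config or PreprocessConfig()
    cleaned = np.vstack([
        subtract_baseline(remove_cosmic_rays(row, config.despike_z_threshold),
                          config.baseline_order)
        for row in spectra_set.intensities])
    out = SpectraSet(spectra_set.axis, cleaned, spectra_set.labels.copy())
    out = crop(out, *config.crop_range)
    normed = np.vstack([normalize_area(row, out.axis) for row in out.intensities])
    return SpectraSet(out.axis, normed, out.labels.copy())
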