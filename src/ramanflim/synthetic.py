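"""Synthetic data generation for the organoid drug-response pipeline.

Everything the downstream analysis consumes can be generated here with known
ground truth: a library of cellular component reference spectra (Lorentzian
band models), labeled organelle spectra with planted drug-effect markers,
hyperspectral organoid cubes built from abundance maps, TCSPC fluorescence
decays with Poisson photon noise, and tables of FLIM fit parameters with
planted drug effects.

Conventions
-----------
* Wavenumber axes are uniform half-open grids ``[start, stop)``; the default
  400-1800 cm^-1 at 4 cm^-1 sampling has exactly 350 points.
* Raman bands are Lorentzian profiles (width parameter = FWHM, default
  8 cm^-1); reference spectra are scaled to unit maximum so that relative
  noise levels and marker amplitudes share one scale.
* All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

CLASSES = ("control", "cis", "vtx")
MODELS = ("RT112", "BCO", "UCO")
ORGANELLES = ("nuclei", "mitochondria")

#: FLIM parameter column order: NADH tau1/tau2/a1%, FAD tau1/tau2/a1%.
FLIM_PARAMS = ("nadh_tau1", "nadh_tau2", "nadh_a1", "fad_tau1", "fad_tau2", "fad_a1")

DEFAULT_PEAK_WIDTH = 8.0  # cm^-1, FWHM of a Raman band


# ---------------------------------------------------------------------------
# Wavenumber axis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WavenumberAxis:
    """Uniform half-open wavenumber grid ``[start, stop)`` in cm^-1."""

    start: float = 400.0
    stop: float = 1800.0
    step: float = 4.0

    def __post_init__(self) -> None:
        if self.step <= 0 or self.stop <= self.start:
            raise ValueError("axis requires stop > start and step > 0")

    @property
    def values(self) -> np.ndarray:
        n = int(np.floor((self.stop - self.start) / self.step))
        return self.start + self.step * np.arange(n)

    def __len__(self) -> int:
        return int(np.floor((self.stop - self.start) / self.step))

    def index_of(self, wavenumber: float) -> int:
        """Index of the grid point nearest *wavenumber* (must lie on the axis)."""
        v = self.values
        if wavenumber < v[0] - self.step / 2 or wavenumber > v[-1] + self.step / 2:
            raise ValueError(f"wavenumber {wavenumber} cm^-1 is off the axis "
                             f"[{v[0]}, {v[-1]}]")
        return int(np.argmin(np.abs(v - wavenumber)))


def lorentzian(x: np.ndarray, center: float, width: float, amplitude: float) -> np.ndarray:
    """Lorentzian band with unit-*amplitude* peak height and FWHM *width*."""
    hw = width / 2.0
    return amplitude * hw ** 2 / ((x - center) ** 2 + hw ** 2)


# ---------------------------------------------------------------------------
# Component spectral library
# ---------------------------------------------------------------------------

# Band positions (cm^-1) with relative amplitudes.  The marker bands of the
# cellular components (cytochrome c for mitochondria, DNA phosphate for
# nuclei, phenylalanine/amide I for cytoplasm, ester C=C for lipids) dominate;
# the remaining bands provide generic biological background.
_PEAK_TABLES: dict[str, list[tuple[float, float, float]]] = {
    "mitochondria": [(747, 8, 1.0), (1125, 8, 0.9), (1315, 10, 0.5),
                     (1585, 12, 0.35), (1450, 12, 0.3)],
    "nuclei": [(798, 8, 1.0), (1096, 8, 0.9), (785, 10, 0.45), (1578, 12, 0.4),
               (1340, 14, 0.3)],
    "cytoplasm": [(1001, 6, 1.0), (1660, 18, 0.85), (1450, 14, 0.5),
                  (1250, 20, 0.3), (855, 10, 0.25)],
    "lipids": [(1750, 10, 1.0), (1440, 14, 0.8), (1300, 12, 0.6), (1080, 12, 0.3)],
    "matrigel": [(857, 12, 0.7), (940, 12, 0.6), (1246, 16, 0.8),
                 (1450, 14, 0.5), (1665, 16, 1.0)],
    "unknown": [(1167, 10, 1.0), (1593, 10, 0.95), (1360, 14, 0.3)],
    # solid drug reference spectra (positions are synthetic stand-ins)
    "cis": [(520, 10, 1.0), (560, 10, 0.7), (1630, 12, 0.3)],
    "vtx": [(745, 8, 0.5), (1230, 10, 0.8), (1606, 10, 1.0), (1365, 10, 0.6)],
}


@dataclass
class ComponentLibrary:
    """Non-negative reference spectra of cellular components on a shared axis."""

    axis: WavenumberAxis
    names: tuple[str, ...]
    spectra: dict[str, np.ndarray]
    peak_table: dict[str, list[tuple[float, float, float]]]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.spectra[name]


def generate_component_library(axis: WavenumberAxis | None = None,
                               seed: int = 0,
                               include_unknown: bool = False) -> ComponentLibrary:
    """Build the component reference library as sums of Lorentzian bands.

    Each component is its tabulated bands plus a smooth low-amplitude
    background (seeded, fixed per component), scaled to unit maximum.
    The ``unknown`` component (seen only in urine-derived organoids) is
    optional and off by default.
    """
    axis = axis or WavenumberAxis()
    v = axis.values
    rng = np.random.default_rng(seed)
    names = tuple(n for n in _PEAK_TABLES if include_unknown or n != "unknown")
    spectra: dict[str, np.ndarray] = {}
    for name in names:
        peaks = _PEAK_TABLES[name]
        for center, _w, _a in peaks:
            if not (axis.start <= center < axis.stop):
                raise ValueError(
                    f"axis [{axis.start}, {axis.stop}) does not cover the "
                    f"{name} band at {center} cm^-1")
        s = np.zeros_like(v)
        for center, width, amp in peaks:
            s += lorentzian(v, center, width, amp)
        # smooth background: slowly varying positive cosine mixture
        phase = rng.uniform(0, 2 * np.pi, size=2)
        span = axis.stop - axis.start
        bg = 0.03 * (2.0 + np.cos(2 * np.pi * (v - axis.start) / span + phase[0])
                     + 0.5 * np.cos(4 * np.pi * (v - axis.start) / span + phase[1]))
        s = s + bg
        spectra[name] = s / s.max()
    return ComponentLibrary(axis=axis, names=names, spectra=spectra,
                            peak_table={n: list(_PEAK_TABLES[n]) for n in names})


# ---------------------------------------------------------------------------
# Ground-truth drug effects on organelle spectra
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthEffects:
    """Planted spectral drug effects per (class, organelle).

    ``markers`` maps ``(class, organelle)`` to a list of
    ``(wavenumber cm^-1, amplitude delta, band shift cm^-1)``. A marker adds a
    Lorentzian of height *delta* at *wavenumber*; a non-zero *shift* instead
    moves an existing band by subtracting at *wavenumber* and adding at
    ``wavenumber + shift``.  Control classes carry no markers.
    ``concentration_scaling`` multiplies deltas by dose rank (highest first);
    ``time_scaling`` maps exposure timepoint (h) to a multiplier.
    """

    markers: dict[tuple[str, str], list[tuple[float, float, float]]]
    concentration_scaling: tuple[float, ...] = (1.0, 0.85, 0.7)
    time_scaling: dict[int, float] = field(default_factory=lambda: {24: 0.9, 48: 1.0})

    def marker_wavenumbers(self, organelle: str) -> list[float]:
        out: list[float] = []
        for (cls, org), marks in self.markers.items():
            if org == organelle and cls != "control":
                out.extend(w for w, _d, _s in marks)
        return sorted(set(out))

    def delta_profile(self, axis: WavenumberAxis, cls: str, organelle: str,
                      scale: float, width: float = DEFAULT_PEAK_WIDTH) -> np.ndarray:
        v = axis.values
        profile = np.zeros_like(v)
        for w, delta, shift in self.markers.get((cls, organelle), []):
            if not (axis.start <= w < axis.stop):
                raise ValueError(f"effect wavenumber {w} cm^-1 is off the axis")
            if shift:
                profile += scale * delta * (lorentzian(v, w + shift, width, 1.0)
                                            - lorentzian(v, w, width, 1.0))
            else:
                profile += scale * delta * lorentzian(v, w, width, 1.0)
        return profile


def default_effects(amplitude: float = 0.045) -> GroundTruthEffects:
    """Drug-effect markers at the band positions reported for cisplatin
    (A-form DNA / thymidine bands in nuclei) and venetoclax (cytochrome c and
    CH2 bands in mitochondria, DNA/guanine bands in nuclei).

    *amplitude* is the full-dose marker height relative to the unit-max
    reference spectrum; the default is three times the default relative noise
    level (0.015).
    """
    a = amplitude
    return GroundTruthEffects(markers={
        ("cis", "nuclei"): [(615, a, 0), (702, a, 0), (750, a, 0), (815, a, 0)],
        ("vtx", "nuclei"): [(1250, a, 0), (1321, a, 0), (1455, a, 0)],
        ("vtx", "mitochondria"): [(747, a, 0), (1125, a, 0), (1315, a, 0), (1450, a, 0)],
        ("cis", "mitochondria"): [(705, a, 0)],
    })


# ---------------------------------------------------------------------------
# Study design and labeled spectra sets
# ---------------------------------------------------------------------------

@dataclass
class StudyDesign:
    """Measurement design: which organoids, conditions and replicate counts."""

    models: tuple[str, ...] = MODELS
    organoids_per_model: int = 3
    spectra_per_condition: int = 20
    concentrations: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {"cis": (30.0, 10.0, 1.0), "vtx": (10.0, 4.0, 1.5)})
    timepoints: tuple[int, ...] = (24, 48)

    def conditions(self) -> list[tuple[str, float | None, int]]:
        """All (class, concentration, timepoint) cells; controls have no dose."""
        out: list[tuple[str, float | None, int]] = []
        for tp in self.timepoints:
            out.append(("control", None, tp))
        for drug, concs in self.concentrations.items():
            for c in concs:
                for tp in self.timepoints:
                    out.append((drug, c, tp))
        return out

    def dose_rank(self, drug: str, concentration: float) -> int:
        concs = sorted(self.concentrations[drug], reverse=True)
        return concs.index(concentration)


LABEL_COLUMNS = ("class", "model", "organelle", "organoid_id", "concentration",
                 "timepoint")


@dataclass
class SpectraSet:
    """Labeled spectra on a shared wavenumber axis.

    ``intensities`` is ``n_spectra x n_features``; ``labels`` is a DataFrame
    with one row per spectrum and the columns of :data:`LABEL_COLUMNS`.
    """

    axis: WavenumberAxis
    intensities: np.ndarray
    labels: pd.DataFrame

    def __post_init__(self) -> None:
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be 2-D")
        if self.intensities.shape[1] != len(self.axis):
            raise ValueError("intensity columns must match the axis length")
        if len(self.labels) != self.intensities.shape[0]:
            raise ValueError("one label row per spectrum required")
        bad = (self.labels["class"] == "control") & self.labels["concentration"].notna()
        if bad.any():
            raise ValueError("control spectra must not carry a concentration")

    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    def select(self, mask: pd.Series | np.ndarray) -> "SpectraSet":
        mask = np.asarray(mask)
        return SpectraSet(self.axis, self.intensities[mask],
                          self.labels.loc[mask].reset_index(drop=True))

    # -- plain-text round trip -------------------------------------------
    def to_csv(self, spectra_path: str | Path, labels_path: str | Path) -> None:
        """Write wavenumber-by-spectrum CSV plus a JSON label sidecar."""
        df = pd.DataFrame(self.intensities.T,
                          columns=[f"s{i}" for i in range(self.n_spectra)])
        df.insert(0, "wavenumber", self.axis.values)
        df.to_csv(spectra_path, index=False)
        records = self.labels.where(pd.notna(self.labels), None).to_dict("records")
        Path(labels_path).write_text(json.dumps(records, indent=1))

    @classmethod
    def from_csv(cls, spectra_path: str | Path, labels_path: str | Path) -> "SpectraSet":
        df = pd.read_csv(spectra_path)
        v = df["wavenumber"].to_numpy()
        step = float(v[1] - v[0])
        axis = WavenumberAxis(float(v[0]), float(v[-1]) + step, step)
        intensities = df.drop(columns="wavenumber").to_numpy().T
        labels = pd.DataFrame(json.loads(Path(labels_path).read_text()))
        labels["concentration"] = labels["concentration"].astype(float)
        return cls(axis, intensities, labels)


def generate_spectra_set(library: ComponentLibrary,
                         effects: GroundTruthEffects,
                         design: StudyDesign,
                         organelle: str = "nuclei",
                         noise_sd: float = 0.015,
                         seed: int = 0) -> SpectraSet:
    """Generate labeled organelle spectra with planted drug-effect markers.

    Each spectrum is the organelle reference plus class-, dose- and
    time-scaled marker deltas plus additive Gaussian noise with standard
    deviation ``noise_sd * max(reference)``.
    """
    if design.spectra_per_condition < 1 or design.organoids_per_model < 1:
        raise ValueError("design counts must be positive")
    covered = {cls for cls, _org in effects.markers}
    missing = [d for d in design.concentrations if d not in covered]
    if missing:
        raise ValueError(f"effects do not cover classes {missing}")
    ref = library[organelle]
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for model in design.models:
        for oid in range(design.organoids_per_model):
            for cls, conc, tp in design.conditions():
                if cls == "control":
                    scale = 0.0
                else:
                    scale = (effects.concentration_scaling[design.dose_rank(cls, conc)]
                             * effects.time_scaling[tp])
                delta = effects.delta_profile(library.axis, cls, organelle, scale)
                n = design.spectra_per_condition
                noise = rng.normal(0.0, noise_sd * ref.max(), size=(n, len(ref)))
                rows.append(ref[None, :] + delta[None, :] + noise)
                labels.extend(
                    {"class": cls, "model": model, "organelle": organelle,
                     "organoid_id": f"{model}-{oid}",
                     "concentration": conc, "timepoint": tp}
                    for _ in range(n))
    return SpectraSet(library.axis, np.vstack(rows), pd.DataFrame(labels))


# ---------------------------------------------------------------------------
# Hyperspectral cubes
# ---------------------------------------------------------------------------

@dataclass
class CubeLayout:
    """Spatial layout of a synthetic organoid scan (pixel units, 1 um grid)."""

    width: int = 50
    height: int = 50
    organoid_center: tuple[float, float] = (25.0, 25.0)
    organoid_radii: tuple[float, float] = (18.0, 15.0)
    n_nuclei: int = 4
    nucleus_radius: float = 4.0
    mito_ring_width: float = 2.5
    n_lipid_droplets: int = 3
    droplet_radius: float = 1.8
    components: tuple[str, ...] = ("matrigel", "cytoplasm", "nuclei",
                                   "mitochondria", "lipids")

    def validate(self) -> None:
        cx, cy = self.organoid_center
        rx, ry = self.organoid_radii
        if cx - rx < 0 or cx + rx > self.width or cy - ry < 0 or cy + ry > self.height:
            raise ValueError("organoid ellipse extends outside the image bounds")


@dataclass
class HyperspectralCube:
    """``height x width x n_features`` intensities with ground-truth abundances."""

    axis: WavenumberAxis
    cube: np.ndarray
    ground_truth_abundances: np.ndarray  # height x width x n_components
    component_names: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.cube.shape

    def pixels(self) -> np.ndarray:
        """Flattened ``(n_pixels, n_features)`` view of the cube."""
        h, w, f = self.cube.shape
        return self.cube.reshape(h * w, f)

    def save_npz(self, path: str | Path) -> None:
        np.savez(path, cube=self.cube, abundances=self.ground_truth_abundances,
                 axis=np.array([self.axis.start, self.axis.stop, self.axis.step]),
                 names=np.array(self.component_names))

    @classmethod
    def load_npz(cls, path: str | Path) -> "HyperspectralCube":
        z = np.load(path, allow_pickle=False)
        a = z["axis"]
        return cls(WavenumberAxis(*a.tolist()), z["cube"], z["abundances"],
                   tuple(str(n) for n in z["names"]))


def _disk(h: int, w: int, cx: float, cy: float, rx: float, ry: float) -> np.ndarray:
    y, x = np.mgrid[0:h, 0:w]
    return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 <= 1.0


def generate_hyperspectral_cube(library: ComponentLibrary,
                                layout: CubeLayout | None = None,
                                noise_sd: float = 0.01,
                                seed: int = 0,
                                drug: str | None = None) -> HyperspectralCube:
    """Render a synthetic organoid scan: matrigel exterior, cytoplasm body,
    nuclei blobs each wrapped in a mitochondria ring, lipid droplets, and
    optionally an accumulated drug component.

    ``cube = abundances . library spectra + clipped Gaussian noise``.
    """
    from scipy.ndimage import gaussian_filter

    layout = layout or CubeLayout()
    layout.validate()
    names = layout.components + ((drug,) if drug else ())
    missing = [n for n in names if n not in library.names]
    if missing:
        raise ValueError(f"layout components {missing} not in the library")
    h, w = layout.height, layout.width
    rng = np.random.default_rng(seed)
    cx, cy = layout.organoid_center
    rx, ry = layout.organoid_radii
    organoid = _disk(h, w, cx, cy, rx, ry)

    maps = {n: np.zeros((h, w)) for n in names}
    maps["matrigel"][~organoid] = 1.0
    maps["cytoplasm"][organoid] = 1.0
    for _ in range(layout.n_nuclei):
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0.2, 0.6)
        nx, ny = cx + rad * rx * np.cos(ang), cy + rad * ry * np.sin(ang)
        r = layout.nucleus_radius
        nuc = _disk(h, w, nx, ny, r, r) & organoid
        ring = (_disk(h, w, nx, ny, r + layout.mito_ring_width,
                      r + layout.mito_ring_width) & ~nuc & organoid)
        maps["nuclei"][nuc] = 1.0
        maps["mitochondria"][ring] = 1.0
    for _ in range(layout.n_lipid_droplets):
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0.4, 0.85)
        lx, ly = cx + rad * rx * np.cos(ang), cy + rad * ry * np.sin(ang)
        maps["lipids"][_disk(h, w, lx, ly, layout.droplet_radius,
                             layout.droplet_radius) & organoid] = 1.0
    if drug:
        maps[drug][organoid] = 0.3  # diffuse accumulation

    abund = np.stack([gaussian_filter(maps[n], 0.8) for n in names], axis=-1)
    abund = np.clip(abund, 0.0, None)
    spectra = np.stack([library[n] for n in names])  # k x f
    cube = abund @ spectra
    if noise_sd > 0:
        cube = cube + rng.normal(0.0, noise_sd * cube.max(), size=cube.shape)
        cube = np.clip(cube, 0.0, None)
    return HyperspectralCube(library.axis, cube, abund, tuple(names),
                             metadata={"drug": drug})


# ---------------------------------------------------------------------------
# TCSPC decays
# ---------------------------------------------------------------------------

@dataclass
class DecayHistogram:
    """TCSPC photon-arrival histogram with its instrument response function."""

    bin_times: np.ndarray  # ns, bin centers, strictly increasing
    counts: np.ndarray     # non-negative integer counts
    irf: np.ndarray        # normalized IRF on the same bins (sums to 1)
    ground_truth: tuple[float, float, float] | None = None  # (tau1, tau2, a1_frac)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.bin_times) <= 0):
            raise ValueError("bin_times must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    def to_csv(self, decay_path: str | Path, irf_path: str | Path) -> None:
        pd.DataFrame({"time_ns": self.bin_times, "counts": self.counts}
                     ).to_csv(decay_path, index=False)
        payload = {"irf": self.irf.tolist()}
        if self.ground_truth is not None:
            payload["ground_truth"] = list(self.ground_truth)
        Path(irf_path).write_text(json.dumps(payload))

    @classmethod
    def from_csv(cls, decay_path: str | Path, irf_path: str | Path) -> "DecayHistogram":
        df = pd.read_csv(decay_path)
        payload = json.loads(Path(irf_path).read_text())
        gt = payload.get("ground_truth")
        return cls(df["time_ns"].to_numpy(), df["counts"].to_numpy().astype(int),
                   np.asarray(payload["irf"]),
                   tuple(gt) if gt is not None else None)


def biexponential_model(t: np.ndarray, irf: np.ndarray, tau1: float, tau2: float,
                        a1_fraction: float) -> np.ndarray:
    """IRF-convolved ``a1 exp(-t/tau1) + (1-a1) exp(-t/tau2)`` on the bin grid,
    normalized to unit sum (a probability profile over bins)."""
    decay = a1_fraction * np.exp(-t / tau1) + (1.0 - a1_fraction) * np.exp(-t / tau2)
    model = np.convolve(irf, decay)[: len(t)]
    total = model.sum()
    if total <= 0:
        raise ValueError("degenerate decay model")
    return model / total


def gaussian_irf(t: np.ndarray, center: float, sigma: float) -> np.ndarray:
    irf = np.exp(-0.5 * ((t - center) / sigma) ** 2)
    return irf / irf.sum()


def generate_decay(params: tuple[float, float, float],
                   irf_sigma: float = 0.15,
                   n_photons: int = 100_000,
                   n_bins: int = 1024,
                   t_max: float = 12.5,
                   irf_center: float = 1.0,
                   seed: int = 0) -> DecayHistogram:
    """Simulate a TCSPC histogram for a biexponential decay.

    ``params`` is ``(tau1 ns, tau2 ns, a1_fraction)``; counts per bin are
    Poisson draws around ``n_photons`` times the IRF-convolved decay profile.
    """
    tau1, tau2, a1 = params
    if tau1 <= 0 or tau2 <= 0:
        raise ValueError("lifetimes must be positive")
    if not 0.0 <= a1 <= 1.0:
        raise ValueError("a1_fraction must lie in [0, 1]")
    if n_photons <= 0:
        raise ValueError("n_photons must be positive")
    if t_max <= 0 or n_bins < 8:
        raise ValueError("need t_max > 0 and at least 8 bins")
    dt = t_max / n_bins
    t = dt * (np.arange(n_bins) + 0.5)
    irf = gaussian_irf(t, irf_center, irf_sigma)
    p = biexponential_model(t, irf, tau1, tau2, a1)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(n_photons * p)
    return DecayHistogram(t, counts, irf, ground_truth=(tau1, tau2, a1))


# ---------------------------------------------------------------------------
# FLIM parameter tables
# ---------------------------------------------------------------------------

#: Baseline six-parameter vectors per organoid model: (NADH tau1, NADH tau2,
#: NADH a1%, FAD tau1, FAD tau2, FAD a1%).  NADH a1% baselines follow the
#: reported ordering RT112 ~78% > BCO > UCO.
DEFAULT_FLIM_BASELINES: dict[str, tuple[float, ...]] = {
    "RT112": (0.40, 2.50, 78.0, 0.35, 2.80, 65.0),
    "BCO": (0.45, 2.30, 70.0, 0.40, 2.60, 55.0),
    "UCO": (0.50, 2.20, 60.0, 0.45, 2.50, 50.0),
}

#: Per-parameter measurement noise scale (ns for lifetimes, percentage points
#: for a1%) of a condition average over biological replicas.
FLIM_NOISE_SCALE = np.array([0.02, 0.04, 1.0, 0.02, 0.04, 1.0])


#: Pair-effect templates per (dose rank, timepoint h): the shift of the two
#: informative lifetimes in units of ``pair_amplitude``, with venetoclax sign
#: (cisplatin is mirrored).  High and mid doses respond on both lifetimes; at
#: the lowest (sub-effective) dose one lifetime per timepoint has not yet
#: responded (showing a slight opposite drift) while the other overshoots,
#: which makes each lifetime alone insufficient to separate the drugs while
#: the pair remains cleanly separable.
DEFAULT_PAIR_TEMPLATES: dict[tuple[int, int], tuple[float, float]] = {
    (0, 24): (0.7, 0.7), (0, 48): (0.7, 0.7),
    (1, 24): (0.7, 0.7), (1, 48): (0.7, 0.7),
    (2, 24): (-0.15, 1.4), (2, 48): (1.4, -0.15),
}


@dataclass
class FlimEffects:
    """Planted drug effects on the six FLIM parameters.

    The cis/vtx discrimination is concentrated on an informative lifetime
    ``pair`` (NADH tau2, FAD tau2 by default): venetoclax raises the two long
    lifetimes (mitochondrial apoptosis), cisplatin lowers them, following
    ``pair_templates`` per dose rank and timepoint.  ``vtx_extra`` and
    ``cis_extra`` are flat (dose-independent) shifts of the remaining
    parameters: venetoclax additionally raises both short lifetimes, and
    cisplatin lowers both amplitude fractions.  ``noise_scale`` optionally
    overrides the per-parameter measurement noise of the generated table.
    """

    pair: tuple[str, str] = ("nadh_tau2", "fad_tau2")
    pair_amplitude: float = 0.5  # ns; full-dose drug separation scale
    pair_templates: dict[tuple[int, int], tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PAIR_TEMPLATES))
    vtx_extra: np.ndarray = field(
        default_factory=lambda: np.array([0.07, 0, 0, 0.07, 0, 0]))
    cis_extra: np.ndarray = field(
        default_factory=lambda: np.array([0, 0, -0.8, 0, 0, -0.8]))
    noise_scale: np.ndarray | None = None

    @property
    def informative_pair(self) -> tuple[str, str]:
        return self.pair

    def effect(self, drug: str, dose_rank: int, timepoint: int) -> np.ndarray:
        eff = np.zeros(len(FLIM_PARAMS))
        i, j = (FLIM_PARAMS.index(p) for p in self.pair)
        tx, ty = self.pair_templates[(dose_rank, timepoint)]
        sign = 1.0 if drug == "vtx" else -1.0
        eff[i] = sign * self.pair_amplitude * tx
        eff[j] = sign * self.pair_amplitude * ty
        eff += self.vtx_extra if drug == "vtx" else self.cis_extra
        return eff


def default_flim_effects() -> FlimEffects:
    """Planted effects of the full benchmark table: informative-pair geometry
    plus the flat venetoclax tau1 rise and cisplatin a1% decrease."""
    return FlimEffects()


def two_parameter_flim_effects() -> FlimEffects:
    """Effects confined strictly to the informative lifetime pair: the other
    four parameters carry neither drug effects nor measurement noise, so they
    are constant columns.  This is the ground-truth configuration for testing
    the minimal-subspace search."""
    noise = np.zeros(len(FLIM_PARAMS))
    noise[[1, 4]] = FLIM_NOISE_SCALE[[1, 4]]
    return FlimEffects(vtx_extra=np.zeros(6), cis_extra=np.zeros(6),
                       noise_scale=noise)


@dataclass
class FLIMParameterTable:
    """Condition-averaged FLIM parameters: 12 drug rows (2 drugs x 3
    concentrations x 2 timepoints) per model, plus control rows kept
    separately for the mean-difference heatmaps."""

    data: pd.DataFrame       # columns: drug, concentration, timepoint, model + FLIM_PARAMS
    controls: pd.DataFrame   # columns: timepoint, model + FLIM_PARAMS
    ground_truth_pair: tuple[str, str] | None = None

    def values(self) -> np.ndarray:
        return self.data[list(FLIM_PARAMS)].to_numpy()

    def to_csv(self, path: str | Path, controls_path: str | Path | None = None) -> None:
        self.data.to_csv(path, index=False)
        if controls_path is not None:
            self.controls.to_csv(controls_path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path,
                 controls_path: str | Path | None = None) -> "FLIMParameterTable":
        controls = (pd.read_csv(controls_path) if controls_path is not None
                    else pd.DataFrame(columns=["timepoint", "model", *FLIM_PARAMS]))
        return cls(pd.read_csv(path), controls)


def generate_flim_table(effects: FlimEffects | None = None,
                        baseline: tuple[float, ...] | None = None,
                        model: str = "RT112",
                        design: StudyDesign | None = None,
                        noise_sd: float = 1.0,
                        n_control_replicates: int = 3,
                        seed: int = 0) -> FLIMParameterTable:
    """Generate the per-model clustering dataset: 12 condition rows x 6 FLIM
    parameters (= 72 values) with planted drug effects, plus separate control
    rows for heatmaps.  ``noise_sd`` scales :data:`FLIM_NOISE_SCALE`."""
    effects = effects if effects is not None else default_flim_effects()
    baseline = np.asarray(baseline if baseline is not None
                          else DEFAULT_FLIM_BASELINES[model], dtype=float)
    if not 0.0 <= baseline[2] <= 100.0 or not 0.0 <= baseline[5] <= 100.0:
        raise ValueError("baseline a1% must lie in [0, 100]")
    design = design or StudyDesign()
    rng = np.random.default_rng(seed)
    scale = (effects.noise_scale if effects.noise_scale is not None
             else FLIM_NOISE_SCALE)
    rows = []
    for drug, concs in design.concentrations.items():
        for conc in concs:
            for tp in design.timepoints:
                eff = effects.effect(drug, design.dose_rank(drug, conc), tp)
                vals = baseline + eff + noise_sd * scale * rng.normal(size=6)
                vals = _clip_alpha(vals)
                rows.append({"drug": drug, "concentration": conc, "timepoint": tp,
                             "model": model,
                             **dict(zip(FLIM_PARAMS, vals))})
    controls = []
    for tp in design.timepoints:
        for _ in range(n_control_replicates):
            vals = baseline + noise_sd * scale * rng.normal(size=6)
            vals = _clip_alpha(vals)
            controls.append({"timepoint": tp, "model": model,
                             **dict(zip(FLIM_PARAMS, vals))})
    controls_df = (pd.DataFrame(controls) if controls else
                   pd.DataFrame(columns=["timepoint", "model", *FLIM_PARAMS]))
    return FLIMParameterTable(pd.DataFrame(rows), controls_df,
                              ground_truth_pair=effects.informative_pair)


def _clip_alpha(vals: np.ndarray) -> np.ndarray:
    out = vals.copy()
    for idx in (2, 5):
        if out[idx] < 0.0 or out[idx] > 100.0:
            warnings.warn("a1% clipped to [0, 100]", stacklevel=3)
            out[idx] = np.clip(out[idx], 0.0, 100.0)
    if np.any(out[[0, 1, 3, 4]] <= 0):
        raise ValueError("generated lifetimes must stay positive")
    return out
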