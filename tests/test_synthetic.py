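"""Generators: axes, component spectra, labeled sets, cubes, decays, tables."""

import numpy as np
import pandas as pd
import pytest

from ramanflim import synthetic as syn


class TestWavenumberAxis:
    def test_default_axis_has_350_points(self):
        axis = syn.WavenumberAxis(400, 1800, 4)
        v = axis.values
        assert len(axis) == 350
        assert v[0] == 400 and v[-1] == 1796  # half-open [400, 1800)
        assert np.all(np.diff(v) == 4)

    def test_index_of_rejects_off_axis(self):
        axis = syn.WavenumberAxis()
        with pytest.raises(ValueError, match="off the axis"):
            axis.index_of(9999)

    def test_invalid_axis_rejected(self):
        with pytest.raises(ValueError):
            syn.WavenumberAxis(400, 300, 4)


class TestComponentLibrary:
    def test_deterministic_for_fixed_seed(self):
        a = syn.generate_component_library(seed=7)
        b = syn.generate_component_library(seed=7)
        for name in a.names:
            np.testing.assert_array_equal(a[name], b[name])

    def test_spectra_non_negative_unit_max(self, library):
        for name in library.names:
            assert library[name].min() >= 0
            assert library[name].max() == pytest.approx(1.0)

    @pytest.mark.parametrize("peak", [747, 1125])
    def test_mitochondria_cytochrome_bands_are_local_maxima(self, library, peak):
        s = library["mitochondria"]
        i = library.axis.index_of(peak)
        assert s[i] > s[i - 1] and s[i] > s[i + 1]

    def test_nuclei_dna_band_dominates_780_820(self, library):
        v = library.axis.values
        window = (v >= 780) & (v <= 820)
        peak = v[window][np.argmax(library["nuclei"][window])]
        assert abs(peak - 798) <= library.axis.step

    def test_axis_not_covering_band_rejected(self):
        with pytest.raises(ValueError, match="cm"):
            syn.generate_component_library(syn.WavenumberAxis(800, 1000, 4))


class TestSpectraSet:
    def test_single_model_count(self, five_marker_set):
        # 3 organoids x 14 conditions x 20 spectra
        assert five_marker_set.n_spectra == 840
        assert five_marker_set.n_features == 350

    def test_zero_noise_zero_effect_reproduces_reference(self, library,
                                                         single_model_design):
        effects = syn.GroundTruthEffects(markers={("cis", "nuclei"): [],
                                                  ("vtx", "nuclei"): []})
        ss = syn.generate_spectra_set(library, effects, single_model_design,
                                      noise_sd=0.0, seed=0)
        np.testing.assert_allclose(ss.intensities,
                                   np.tile(library["nuclei"], (ss.n_spectra, 1)))

    def test_planted_signal_contract(self, library, single_model_design):
        """With zero noise, treated-minus-control differences are nonzero
        exactly around the planted marker wavenumbers."""
        effects = syn.default_effects()
        ss = syn.generate_spectra_set(library, effects, single_model_design,
                                      noise_sd=0.0, seed=0)
        cls = ss.labels["class"]
        diff = (ss.intensities[cls == "cis"].mean(axis=0)
                - ss.intensities[cls == "control"].mean(axis=0))
        v = ss.axis.values
        markers = [w for (c, o), ms in effects.markers.items()
                   if c == "cis" and o == "nuclei" for w, _d, _s in ms]
        near = np.zeros(len(v), dtype=bool)
        for m in markers:
            near |= np.abs(v - m) <= 4 * syn.DEFAULT_PEAK_WIDTH
        assert diff[near].max() > 0.01
        assert np.abs(diff[~near]).max() < 0.002  # Lorentzian tails only

    def test_control_rows_carry_no_concentration(self, five_marker_set):
        ctrl = five_marker_set.labels.query("`class` == 'control'")
        assert ctrl["concentration"].isna().all()

    def test_csv_round_trip_lossless(self, five_marker_set, tmp_path):
        sub = five_marker_set.select(np.arange(30))
        sub.to_csv(tmp_path / "s.csv", tmp_path / "l.json")
        back = syn.SpectraSet.from_csv(tmp_path / "s.csv", tmp_path / "l.json")
        np.testing.assert_allclose(back.intensities, sub.intensities, rtol=1e-9)
        np.testing.assert_array_equal(back.axis.values, sub.axis.values)
        pd.testing.assert_frame_equal(back.labels, sub.labels,
                                      check_dtype=False)

    def test_off_axis_effect_rejected(self, library, single_model_design):
        bad = syn.GroundTruthEffects(markers={
            ("cis", "nuclei"): [(3000.0, 0.05, 0)],
            ("vtx", "nuclei"): []})
        with pytest.raises(ValueError, match="off the axis"):
            syn.generate_spectra_set(library, bad, single_model_design)


class TestHyperspectralCube:
    def test_default_cube_shape(self, library):
        cube = syn.generate_hyperspectral_cube(library, seed=0)
        assert cube.shape == (50, 50, 350)

    def test_deterministic(self, library):
        a = syn.generate_hyperspectral_cube(library, seed=3)
        b = syn.generate_hyperspectral_cube(library, seed=3)
        np.testing.assert_array_equal(a.cube, b.cube)

    def test_pure_pixels_match_reference(self, library):
        layout = syn.CubeLayout(width=12, height=12, organoid_center=(6, 6),
                                organoid_radii=(1.5, 1.5), n_nuclei=0,
                                n_lipid_droplets=0)
        cube = syn.generate_hyperspectral_cube(library, layout, noise_sd=0.0,
                                               seed=0)
        corner = cube.cube[0, 0]  # pure matrigel, far from any boundary
        ref = library["matrigel"]
        cos = corner @ ref / (np.linalg.norm(corner) * np.linalg.norm(ref))
        assert cos == pytest.approx(1.0, abs=1e-9)

    def test_layout_outside_bounds_rejected(self, library):
        layout = syn.CubeLayout(width=20, height=20, organoid_center=(18, 10),
                                organoid_radii=(8, 8))
        with pytest.raises(ValueError, match="outside"):
            syn.generate_hyperspectral_cube(library, layout)

    def test_npz_round_trip(self, library, tmp_path):
        cube = syn.generate_hyperspectral_cube(
            library, syn.CubeLayout(width=16, height=16,
                                    organoid_center=(8, 8),
                                    organoid_radii=(5, 4)), seed=1)
        cube.save_npz(tmp_path / "cube.npz")
        back = syn.HyperspectralCube.load_npz(tmp_path / "cube.npz")
        np.testing.assert_array_equal(back.cube, cube.cube)
        assert back.component_names == cube.component_names


class TestDecayHistogram:
    def test_monoexponential_mean_delay(self):
        tau, t0 = 2.0, 1.0
        d = syn.generate_decay((tau, tau, 1.0), irf_center=t0,
                               n_photons=500_000, seed=0)
        mean_t = np.sum(d.bin_times * d.counts) / d.counts.sum()
        assert mean_t == pytest.approx(tau + t0, rel=0.05)

    def test_counts_are_integers_near_n_photons(self):
        n = 100_000
        d = syn.generate_decay((0.4, 2.5, 0.78), n_photons=n, seed=1)
        assert d.counts.dtype.kind == "i"
        assert abs(d.counts.sum() - n) < 5 * np.sqrt(n)

    def test_amplitude_weighted_mean_lifetime(self):
        tau1, tau2, a1 = 0.4, 2.5, 0.78
        d = syn.generate_decay((tau1, tau2, a1), n_photons=100_000, seed=2)
        # subtract the IRF centroid, compare to the closed-form mixture mean
        centroid = np.sum(d.bin_times * d.irf)
        emp = np.sum(d.bin_times * d.counts) / d.counts.sum() - centroid
        # photon-weighted mean arrival = (a1 tau1^2 + a2 tau2^2)/(a1 tau1 + a2 tau2)
        a2 = 1 - a1
        expected = (a1 * tau1**2 + a2 * tau2**2) / (a1 * tau1 + a2 * tau2)
        assert emp == pytest.approx(expected, rel=0.05)

    def test_poisson_noise_scaling(self):
        """Relative bin-wise noise shrinks like the square root of the photon
        budget."""
        def rel_noise(n_photons, seed):
            d = syn.generate_decay((0.4, 2.5, 0.78), n_photons=n_photons,
                                   n_bins=256, seed=seed)
            p = syn.biexponential_model(d.bin_times, d.irf, 0.4, 2.5, 0.78)
            keep = 10_000 * p > 20  # same well-populated bins at both budgets
            expected = n_photons * p
            return np.std((d.counts[keep] - expected[keep]) / expected[keep])

        ratio = rel_noise(10_000, 3) / rel_noise(10_000_000, 3)
        assert ratio == pytest.approx(np.sqrt(1000), rel=0.3)

    @pytest.mark.parametrize("params", [(0, 2.5, 0.5), (0.4, 2.5, 1.5)])
    def test_invalid_parameters_rejected(self, params):
        with pytest.raises(ValueError):
            syn.generate_decay(params)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_decay((0.4, 2.5, 0.5), n_bins=4)

    def test_csv_round_trip(self, tmp_path):
        d = syn.generate_decay((0.4, 2.5, 0.78), n_photons=10_000, seed=4)
        d.to_csv(tmp_path / "d.csv", tmp_path / "irf.json")
        back = syn.DecayHistogram.from_csv(tmp_path / "d.csv",
                                           tmp_path / "irf.json")
        np.testing.assert_array_equal(back.counts, d.counts)
        np.testing.assert_allclose(back.irf, d.irf)
        assert back.ground_truth == pytest.approx(d.ground_truth)


class TestFLIMParameterTable:
    def test_twelve_conditions_six_parameters(self):
        table = syn.generate_flim_table(seed=0)
        assert table.data.shape[0] == 12
        assert table.values().shape == (12, 6)
        assert table.values().size == 72

    def test_zero_effect_zero_noise_equals_baseline(self):
        effects = syn.FlimEffects(pair_amplitude=0.0,
                                  vtx_extra=np.zeros(6),
                                  cis_extra=np.zeros(6))
        table = syn.generate_flim_table(effects=effects, model="RT112",
                                        noise_sd=0.0, seed=0)
        expected = np.asarray(syn.DEFAULT_FLIM_BASELINES["RT112"])
        np.testing.assert_allclose(table.values(),
                                   np.tile(expected, (12, 1)))

    def test_rt112_control_nadh_alpha_near_78(self):
        table = syn.generate_flim_table(model="RT112", seed=1,
                                        n_control_replicates=10)
        assert table.controls["nadh_a1"].mean() == pytest.approx(78.0, abs=2.0)

    def test_alpha_outside_range_clipped_with_warning(self):
        effects = syn.FlimEffects(cis_extra=np.array([0, 0, -120.0, 0, 0, 0]))
        with pytest.warns(UserWarning, match="clipped"):
            table = syn.generate_flim_table(effects=effects, seed=0)
        assert (table.data["nadh_a1"] >= 0).all()

    def test_csv_round_trip(self, tmp_path):
        table = syn.generate_flim_table(seed=2)
        table.to_csv(tmp_path / "t.csv", tmp_path / "c.csv")
        back = syn.FLIMParameterTable.from_csv(tmp_path / "t.csv",
                                               tmp_path / "c.csv")
        pd.testing.assert_frame_equal(back.data, table.data)
        pd.testing.assert_frame_equal(back.controls, table.controls)
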