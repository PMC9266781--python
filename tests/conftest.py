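"""Shared fixtures: synthetic benchmarks generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from ramanflim import selection as sel
from ramanflim import synthetic as syn

@pytest.fixture(scope="session")
def library() -> syn.ComponentLibrary:
    return syn.generate_component_library(seed=0)


@pytest.fixture(scope="session")
def single_model_design() -> syn.StudyDesign:
    return syn.StudyDesign(models=("RT112",))


def five_marker_effects(amplitude: float = 0.045) -> syn.GroundTruthEffects:
    """Exactly five planted nuclei markers at flat dose/time scaling."""
    a = amplitude
    return syn.GroundTruthEffects(
        markers={
            ("cis", "nuclei"): [(702, a, 0), (815, a, 0)],
            ("vtx", "nuclei"): [(1250, a, 0), (1321, a, 0), (1455, a, 0)],
        },
        concentration_scaling=(1.0, 1.0, 1.0),
        time_scaling={24: 1.0, 48: 1.0},
    )


@pytest.fixture(scope="session")
def five_marker_set(library, single_model_design) -> syn.SpectraSet:
    """840 nuclei spectra, five markers at three times the noise level."""
    return syn.generate_spectra_set(library, five_marker_effects(),
                                    single_model_design, organelle="nuclei",
                                    noise_sd=0.015, seed=0)


@pytest.fixture(scope="session")
def five_marker_data(five_marker_set) -> sel.TrainingData:
    return sel.prepare_training_data(five_marker_set)


@pytest.fixture(scope="session")
def default_nuclei_set(library, single_model_design) -> syn.SpectraSet:
    """The default benchmark: dose- and time-scaled marker effects."""
    return syn.generate_spectra_set(library, syn.default_effects(),
                                    single_model_design, organelle="nuclei",
                                    noise_sd=0.015, seed=0)
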