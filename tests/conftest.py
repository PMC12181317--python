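"""Shared fixtures and cohort builders for the test suite."""

from dataclasses import replace

import numpy as np
import pytest

from irclass import synthetic as syn
from irclass.core import Spectrum, SpectrumMeta, SpectrumSet
from irclass.preprocessing import minmax_normalize, preprocess_set


@pytest.fixture
def grid():
    return syn.DEFAULT_GRID


def make_spectrum(grid, values, patient="P1", sample="S1", slice_id="C1",
                  label="normal", state=("raw",)):
    meta = SpectrumMeta(patient_id=patient, sample_id=sample, slice_id=slice_id,
                        class_label=label, preprocessing_state=list(state))
    return Spectrum(grid, np.asarray(values, dtype=float), meta)


def planted_band_cohort(seed, n_patients=15, spectra=10, factor=0.4, planted=True):
    """Binary cohort whose only class difference is the 1154 cm⁻¹ glycogen
    band (scaled by *factor* in the tumor class); *planted=False* gives the
    null cohort with identical class models."""
    base = syn.default_class_models()["normal"]
    model_a = replace(base, label="normal")
    model_b = replace(base.scale_band(1154.0, factor) if planted else base,
                      label="tumor")
    design = syn.CohortDesign(
        per_class={
            "normal": syn.ClassDesign(n_patients=n_patients, spectra_per_sample=spectra),
            "tumor": syn.ClassDesign(n_patients=n_patients, spectra_per_sample=spectra),
        },
        seed=seed,
    )
    cohort = syn.simulate_cohort(design, models={"normal": model_a, "tumor": model_b})
    return preprocess_set(cohort).map(minmax_normalize)


def separable_models(noise_sd=0.0):
    """Four class models with distinct band amplitudes and no variability —
    downstream classification should be perfect on these."""
    return syn.default_class_models(
        patient_sigma=0.0, spectrum_sigma=0.0, noise_sd=noise_sd,
        baseline_offset=(0.0, 0.0), baseline_slope=(0.0, 0.0),
    )


@pytest.fixture
def tiny_set(grid):
    rng = np.random.default_rng(0)
    spectra = [
        make_spectrum(grid, 0.1 + 0.01 * rng.random(len(grid)),
                      patient=f"P{i}", sample=f"S{i % 2}", slice_id=f"C{i}")
        for i in range(4)
    ]
    return SpectrumSet(spectra)
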