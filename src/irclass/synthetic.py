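"""Synthetic liver-tissue IR spectrum generator.

Emulates the biochemical contrasts that separate normal liver tissue from the
three tumor entities (HCC, CCC, metastasis) in the fingerprint region:

* glycogen bands (~1030, 1080, 1108, 1154 cm⁻¹) strongest in normal tissue,
  intermediate in HCC, low in CCC and metastases;
* amide-III / collagen bands (1240, 1282, 1340 cm⁻¹) strongest in CCC,
  reflecting its desmoplastic, collagen-rich stroma;
* CH₂/CH₃ deformation bands (1360–1480 cm⁻¹) nearly identical across classes;
* amide I/II (1654, 1550 cm⁻¹) dominating every tissue spectrum.

Band amplitudes are invented calibration constants chosen to reproduce these
qualitative orderings; they are not estimates of real tissue chemistry.
Biovariability enters as lognormal per-band multipliers shared across a
patient's spectra (patient effect) plus independent per-spectrum multipliers,
additive white noise, a random linear baseline and, optionally, a comb of
narrow water-vapor lines between 1300 and 1800 cm⁻¹.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .core import Spectrum, SpectrumMeta, SpectrumSet, SpectralImage, WavenumberGrid

__all__ = [
    "BandSpec",
    "ClassBandModel",
    "ClassDesign",
    "CohortDesign",
    "default_class_models",
    "default_binary_design",
    "default_three_class_design",
    "default_cohort_design",
    "water_vapor_reference",
    "simulate_spectrum",
    "simulate_cohort",
    "simulate_image",
]

#: Default ATR grid: 950–1800 cm⁻¹ at 2 cm⁻¹ point spacing (4 cm⁻¹ optical
#: resolution with twofold zero filling).  The imaging grid uses 3 cm⁻¹.
DEFAULT_GRID = WavenumberGrid.regular(950.0, 1800.0, 2.0)
IMAGING_GRID = WavenumberGrid.regular(950.0, 1800.0, 3.0)

#: FPA tile edge in pixels and the physical tile edge in µm.
FPA_TILE = 64
TILE_EDGE_UM = 175.0


@dataclass(frozen=True)
class BandSpec:
    """One absorption band: center and FWHM in cm⁻¹, peak amplitude in AU."""

    center: float
    fwhm: float
    amplitude: float
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown band shape {self.shape!r}")

    def profile(self, wavenumbers: np.ndarray) -> np.ndarray:
        x = wavenumbers - self.center
        if self.shape == "gaussian":
            return self.amplitude * np.exp(-4.0 * math.log(2.0) * (x / self.fwhm) ** 2)
        hw = self.fwhm / 2.0
        return self.amplitude * hw**2 / (x**2 + hw**2)


# Water-vapor interference: fixed comb of narrow rotational lines.  The
# relative line strengths are an arbitrary fixed pattern so that a scaled
# reference subtraction has a well-defined target.
_WATER_LINE_CENTERS = np.arange(1310.0, 1800.0, 28.0)
_WATER_LINE_WEIGHTS = 0.4 + 0.6 * np.abs(np.sin(1.7 * np.arange(len(_WATER_LINE_CENTERS))))


def water_vapor_reference(grid: WavenumberGrid) -> np.ndarray:
    """Unit-scale water-vapor line spectrum on *grid* (max line height 1)."""
    out = np.zeros(len(grid))
    for c, w in zip(_WATER_LINE_CENTERS, _WATER_LINE_WEIGHTS):
        out += BandSpec(c, 4.0, w).profile(grid.values)
    return out


@dataclass
class ClassBandModel:
    """Band catalogue plus variability parameters for one tissue class."""

    label: str
    bands: list[BandSpec]
    patient_sigma: float = 0.15
    spectrum_sigma: float = 0.08
    noise_sd: float = 0.003
    baseline_offset: tuple[float, float] = (0.02, 0.01)  # mean, sd
    baseline_slope: tuple[float, float] = (0.0, 2e-5)  # per cm⁻¹
    water_vapor_amp: float = 0.0

    def __post_init__(self) -> None:
        for name in ("patient_sigma", "spectrum_sigma", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def noise_free(self, grid: WavenumberGrid,
                   band_multipliers: np.ndarray | None = None) -> np.ndarray:
        for b in self.bands:
            if not grid.values[0] <= b.center <= grid.values[-1]:
                raise ValueError(
                    f"grid does not cover band center {b.center} cm-1"
                )
        m = np.ones(len(self.bands)) if band_multipliers is None else band_multipliers
        out = np.zeros(len(grid))
        for mult, b in zip(m, self.bands):
            out += mult * b.profile(grid.values)
        return out

    def scale_band(self, center: float, factor: float) -> "ClassBandModel":
        """Copy of the model with the band at *center* scaled by *factor*."""
        bands = [
            replace(b, amplitude=b.amplitude * factor) if b.center == center else b
            for b in self.bands
        ]
        return replace(self, bands=bands)


# (center, fwhm, amplitude per class) — classes ordered normal, HCC, CCC, met.
_BAND_TABLE = [
    # center, fwhm,  normal,  HCC,   CCC,   metastasis
    (970.0, 12.0, 0.040, 0.040, 0.050, 0.070),  # unassigned / water content
    (1000.0, 14.0, 0.050, 0.090, 0.090, 0.090),  # unassigned / water content
    (1030.0, 40.0, 0.300, 0.240, 0.120, 0.120),  # glycogen C-O stretch
    (1080.0, 30.0, 0.220, 0.180, 0.120, 0.130),  # DNA/phospholipid phosphate
    (1108.0, 16.0, 0.120, 0.090, 0.050, 0.050),  # glycogen
    (1154.0, 18.0, 0.160, 0.120, 0.060, 0.060),  # glycogen CO-O-C stretch
    (1162.0, 16.0, 0.060, 0.060, 0.060, 0.090),  # C-OH, amino acids
    (1240.0, 40.0, 0.140, 0.140, 0.220, 0.170),  # amide III / phosphate
    (1282.0, 20.0, 0.050, 0.050, 0.100, 0.050),  # collagen
    (1312.0, 18.0, 0.060, 0.060, 0.060, 0.060),  # amide III (weak)
    (1340.0, 20.0, 0.050, 0.050, 0.090, 0.050),  # collagen
    (1400.0, 24.0, 0.180, 0.180, 0.175, 0.185),  # CH3 symmetric deformation
    (1452.0, 26.0, 0.200, 0.200, 0.200, 0.200),  # CH2/CH3 deformation
    (1550.0, 50.0, 0.550, 0.600, 0.600, 0.600),  # amide II
    (1654.0, 55.0, 0.850, 0.920, 0.920, 0.920),  # amide I
]

_CLASS_COLUMNS = {"normal": 2, "HCC": 3, "CCC": 4, "metastasis": 5}


def default_class_models(**overrides) -> dict[str, ClassBandModel]:
    """The default four-class band catalogue.

    Keyword overrides (e.g. ``noise_sd=0``) are applied to every class.
    """
    models = {}
    for label, col in _CLASS_COLUMNS.items():
        bands = [BandSpec(row[0], row[1], row[col]) for row in _BAND_TABLE]
        models[label] = replace(ClassBandModel(label, bands), **overrides)
    return models


@dataclass
class ClassDesign:
    """Cohort arm for one class.

    ``total_spectra``, when given, overrides ``spectra_per_sample`` and is
    distributed as evenly as possible over the patients' samples.
    """

    n_patients: int
    samples_per_patient: int = 1
    spectra_per_sample: int = 5
    total_spectra: int | None = None

    def __post_init__(self) -> None:
        if min(self.n_patients, self.samples_per_patient, self.spectra_per_sample) < 1:
            raise ValueError("design counts must be >= 1")

    def spectra_per_patient(self) -> list[int]:
        if self.total_spectra is None:
            return [self.samples_per_patient * self.spectra_per_sample] * self.n_patients
        base, extra = divmod(self.total_spectra, self.n_patients)
        return [base + (1 if i < extra else 0) for i in range(self.n_patients)]


@dataclass
class CohortDesign:
    per_class: dict[str, ClassDesign]
    seed: int

    def __post_init__(self) -> None:
        if not self.per_class:
            raise ValueError("cohort design needs at least one class")


def default_binary_design(seed: int = 0) -> CohortDesign:
    """Cohort mirroring the binary training-set composition: 135 normal
    spectra and 147 tumor spectra (49 per entity)."""
    return CohortDesign(
        per_class={
            "normal": ClassDesign(n_patients=27, spectra_per_sample=5),
            "HCC": ClassDesign(n_patients=7, spectra_per_sample=7),
            "CCC": ClassDesign(n_patients=7, spectra_per_sample=7),
            "metastasis": ClassDesign(n_patients=7, spectra_per_sample=7),
        },
        seed=seed,
    )


def default_three_class_design(seed: int = 0) -> CohortDesign:
    """Tumor-entity cohort sized like the 3-class training set:
    38 metastasis, 39 CCC and 37 HCC spectra from 6 patients per class."""
    return CohortDesign(
        per_class={
            "metastasis": ClassDesign(n_patients=6, total_spectra=38),
            "CCC": ClassDesign(n_patients=6, total_spectra=39),
            "HCC": ClassDesign(n_patients=6, total_spectra=37),
        },
        seed=seed,
    )


def default_cohort_design(seed: int = 0, task: str = "binary") -> CohortDesign:
    """Full train+test cohort for the end-to-end experiments."""
    if task == "binary":
        return CohortDesign(
            per_class={
                "normal": ClassDesign(n_patients=24, samples_per_patient=1,
                                      spectra_per_sample=5),
                "HCC": ClassDesign(n_patients=8, spectra_per_sample=6),
                "CCC": ClassDesign(n_patients=8, spectra_per_sample=6),
                "metastasis": ClassDesign(n_patients=8, spectra_per_sample=6),
            },
            seed=seed,
        )
    if task == "three_class":
        return CohortDesign(
            per_class={
                "metastasis": ClassDesign(n_patients=12, spectra_per_sample=6),
                "CCC": ClassDesign(n_patients=12, spectra_per_sample=6),
                "HCC": ClassDesign(n_patients=12, spectra_per_sample=6),
            },
            seed=seed,
        )
    raise ValueError(f"unknown task {task!r}")


def simulate_spectrum(
    model: ClassBandModel,
    patient_effect: np.ndarray | None,
    grid: WavenumberGrid,
    rng: np.random.Generator,
    meta: SpectrumMeta | None = None,
) -> Spectrum:
    """Draw one spectrum: band sum × (patient, spectrum multipliers) plus
    baseline, water lines and white noise.  Values are *not* clipped at zero;
    real baseline-corrected spectra can dip below zero too."""
    n_bands = len(model.bands)
    if patient_effect is None:
        patient_effect = np.ones(n_bands)
    spectrum_mult = (
        rng.lognormal(mean=0.0, sigma=model.spectrum_sigma, size=n_bands)
        if model.spectrum_sigma > 0
        else np.ones(n_bands)
    )
    a = model.noise_free(grid, patient_effect * spectrum_mult)
    off_mean, off_sd = model.baseline_offset
    slope_mean, slope_sd = model.baseline_slope
    offset = off_mean + (off_sd * rng.standard_normal() if off_sd > 0 else 0.0)
    slope = slope_mean + (slope_sd * rng.standard_normal() if slope_sd > 0 else 0.0)
    center = 0.5 * (grid.values[0] + grid.values[-1])
    a = a + offset + slope * (grid.values - center)
    if model.water_vapor_amp > 0:
        a = a + model.water_vapor_amp * water_vapor_reference(grid)
    if model.noise_sd > 0:
        a = a + model.noise_sd * rng.standard_normal(len(grid))
    return Spectrum(grid, a, meta or SpectrumMeta(patient_id="SIM", class_label=model.label))


def _patient_effect(model: ClassBandModel, rng: np.random.Generator) -> np.ndarray:
    if model.patient_sigma == 0:
        return np.ones(len(model.bands))
    return rng.lognormal(mean=0.0, sigma=model.patient_sigma, size=len(model.bands))


def simulate_cohort(
    design: CohortDesign,
    models: dict[str, ClassBandModel] | None = None,
    grid: WavenumberGrid = DEFAULT_GRID,
) -> SpectrumSet:
    """Generate a labelled cohort.  Patient IDs are unique across classes and
    each patient's spectra share one per-band effect vector."""
    if models is None:
        models = default_class_models()
    rng = np.random.default_rng(design.seed)
    spectra = []
    for label in sorted(design.per_class):
        cdesign = design.per_class[label]
        model = models[label]
        per_patient = cdesign.spectra_per_patient()
        for p in range(cdesign.n_patients):
            pid = f"{label}-P{p:03d}"
            effect = _patient_effect(model, rng)
            n_total = per_patient[p]
            n_samples = min(cdesign.samples_per_patient, n_total)
            base, extra = divmod(n_total, n_samples)
            counts = [base + (1 if s < extra else 0) for s in range(n_samples)]
            for s, n_spec in enumerate(counts):
                for k in range(n_spec):
                    meta = SpectrumMeta(
                        patient_id=pid,
                        sample_id=f"S{s:02d}",
                        slice_id=f"C{k:02d}",
                        class_label=label,
                    )
                    spectra.append(simulate_spectrum(model, effect, grid, rng, meta))
    return SpectrumSet(spectra)


def simulate_image(
    model: ClassBandModel,
    shape: tuple[int, int],
    gap_fraction: float,
    rng: np.random.Generator,
    grid: WavenumberGrid = IMAGING_GRID,
    tissue_sum: float = 40.0,
) -> SpectralImage:
    """Simulate an FPA mosaic of ``shape`` = (tile rows, tile cols) 64×64
    tiles.

    The noise-free class spectrum is rescaled so a typical tissue pixel has a
    per-pixel absorbance sum of ``tissue_sum`` (raw transmission-mode levels,
    where the standard outlier rules on the absorbance sum and the amide-I
    height are meaningful).  A ``gap_fraction`` of pixels is drawn with
    near-zero absorbance, emulating holes in the tissue section; their
    positions are recorded on the returned image as ``gap_mask``.
    """
    if not 0.0 <= gap_fraction <= 1.0:
        raise ValueError("gap_fraction must be in [0, 1]")
    rows, cols = shape[0] * FPA_TILE, shape[1] * FPA_TILE
    base = model.noise_free(grid)
    base = base * (tissue_sum / base.sum())
    # per-pixel thickness/contact multiplier
    mult = rng.lognormal(mean=0.0, sigma=max(model.spectrum_sigma, 1e-12), size=(rows, cols))
    gap_mask = rng.random((rows, cols)) < gap_fraction
    mult[gap_mask] = 1e-4
    cube = mult[:, :, None] * base[None, None, :]
    if model.noise_sd > 0:
        cube += model.noise_sd * rng.standard_normal(cube.shape)
    image = SpectralImage(cube=cube, grid=grid, pixel_size_um=TILE_EDGE_UM / FPA_TILE)
    image.gap_mask = gap_mask
    return image
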