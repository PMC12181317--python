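"""Spectral preprocessing chain for ATR point spectra and imaging pixels.

The chain, in order: atmospheric compensation (optional) → range restriction
to 950–1800 cm⁻¹ → linear two-point baseline correction → restriction to the
classification range 950–1480 cm⁻¹ → area normalization over that range.
Min-max normalization is applied separately to training/test sets immediately
before classification (see :func:`minmax_normalize`).

"Area" here is the discrete sum of absorbance values over the stated range,
not a trapezoidal integral; after normalization this sum equals 1 regardless
of grid spacing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import GridError, Spectrum, SpectrumSet, WavenumberGrid

__all__ = [
    "PreprocessSpec",
    "absorbance_from_single_beam",
    "restrict_range",
    "baseline_correct_two_point",
    "area_normalize",
    "minmax_normalize",
    "atmospheric_compensation",
    "preprocess_spectrum",
    "preprocess_set",
]

#: Cap applied when a sample single-beam value is nonpositive (saturated or
#: dead detector point): the absorbance there is clamped to this maximum.
ABSORBANCE_CAP = 10.0


@dataclass
class PreprocessSpec:
    """Parameters of the preprocessing chain."""

    range_full: tuple[float, float] = (950.0, 1800.0)
    range_classify: tuple[float, float] = (950.0, 1480.0)
    baseline_anchors: tuple[float, float] | None = None  # default: range_full ends
    area_norm_range: tuple[float, float] = (950.0, 1480.0)
    atmospheric: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.range_full
        clo, chi = self.range_classify
        if not (lo <= clo < chi <= hi):
            raise ValueError("range_classify must lie within range_full")
        anchors = self.baseline_anchors or self.range_full
        if not all(lo <= a <= hi for a in anchors):
            raise ValueError("baseline anchors must lie inside range_full")

    @property
    def anchors(self) -> tuple[float, float]:
        return self.baseline_anchors or self.range_full


def absorbance_from_single_beam(sample: Spectrum, reference: Spectrum) -> Spectrum:
    """A(ν) = −log10(S(ν)/R(ν)); the standard ratio against the bare-crystal
    (or bare-window) background."""
    if sample.grid != reference.grid:
        raise GridError("sample and reference must share one grid")
    r = reference.absorbance
    if np.any(r <= 0):
        raise ValueError("reference single-beam spectrum must be strictly positive")
    s = sample.absorbance
    bad = s <= 0
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} nonpositive sample values; absorbance capped at "
            f"{ABSORBANCE_CAP}",
            stacklevel=2,
        )
    a = np.full_like(s, ABSORBANCE_CAP)
    ok = ~bad
    a[ok] = -np.log10(s[ok] / r[ok])
    np.minimum(a, ABSORBANCE_CAP, out=a)
    return sample.with_values(a)


def restrict_range(spectrum: Spectrum, lo: float, hi: float) -> Spectrum:
    """Closed-interval slice [lo, hi] of the spectrum."""
    if hi <= lo:
        raise GridError(f"invalid range [{lo}, {hi}]")
    idx = spectrum.grid.window_indices(lo, hi)
    if idx.size == 0:
        raise GridError(f"range [{lo}, {hi}] contains no grid points")
    grid = WavenumberGrid(spectrum.grid.values[idx])
    return spectrum.with_values(
        spectrum.absorbance[idx], append_state="range_restricted", grid=grid
    )


def baseline_correct_two_point(
    spectrum: Spectrum, anchors: tuple[float, float]
) -> Spectrum:
    """Subtract the straight line through the two anchor points.

    Anchors are snapped to the nearest grid points; the corrected absorbance
    is exactly zero at both.
    """
    lo, hi = anchors
    i = spectrum.grid.nearest_index(lo)
    j = spectrum.grid.nearest_index(hi)
    if i == j:
        raise ValueError("baseline anchors coincide on the grid")
    v = spectrum.grid.values
    a = spectrum.absorbance
    line = a[i] + (a[j] - a[i]) * (v - v[i]) / (v[j] - v[i])
    return spectrum.with_values(a - line, append_state="baseline_corrected")


def area_normalize(spectrum: Spectrum, norm_range: tuple[float, float]) -> Spectrum:
    """Divide the spectrum by the discrete absorbance sum over *norm_range*.

    Removes section-thickness / contact-pressure scaling; afterwards the sum
    over the range equals 1.
    """
    idx = spectrum.grid.window_indices(*norm_range)
    if idx.size == 0:
        raise GridError(f"normalization range {norm_range} contains no grid points")
    area = float(spectrum.absorbance[idx].sum())
    if area <= 0:
        raise ValueError("nonpositive area: empty or failed measurement")
    return spectrum.with_values(spectrum.absorbance / area, append_state="area_normalized")


def minmax_normalize(spectrum: Spectrum) -> Spectrum:
    """Map the absorbance affinely so min → 0 and max → 1."""
    a = spectrum.absorbance
    lo, hi = float(a.min()), float(a.max())
    if hi <= lo:
        raise ValueError("constant spectrum cannot be min-max normalized")
    return spectrum.with_values((a - lo) / (hi - lo), append_state="minmax_normalized")


def atmospheric_compensation(
    spectrum: Spectrum,
    water_reference: np.ndarray,
    fit_range: tuple[float, float] = (1300.0, 1800.0),
) -> Spectrum:
    """Remove water-vapor lines by subtracting a least-squares-scaled
    reference line spectrum.

    The scale α is a least-squares match of the *second differences* of
    spectrum and reference over *fit_range*: differencing twice suppresses the
    broad tissue bands while the narrow (≈4 cm⁻¹) water lines survive, so the
    fit locks onto the line structure alone.  α is clipped at zero.
    """
    w = np.asarray(water_reference, dtype=float)
    if w.shape != spectrum.absorbance.shape:
        raise GridError("water reference must be on the spectrum grid")
    idx = spectrum.grid.window_indices(*fit_range)
    if idx.size < 5 or not np.any(w[idx] != 0):
        return spectrum
    d2w = np.diff(w[idx], 2)
    denom = float(d2w @ d2w)
    if denom == 0:
        return spectrum
    d2a = np.diff(spectrum.absorbance[idx], 2)
    alpha = max(0.0, float(d2w @ d2a) / denom)
    return spectrum.with_values(spectrum.absorbance - alpha * w)


def preprocess_spectrum(
    spectrum: Spectrum,
    spec: PreprocessSpec,
    water_reference: np.ndarray | None = None,
) -> Spectrum:
    """Apply the full chain (without min-max) to one spectrum."""
    s = spectrum
    if spec.atmospheric and water_reference is not None:
        s = atmospheric_compensation(s, water_reference)
    s = restrict_range(s, *spec.range_full)
    s = baseline_correct_two_point(s, spec.anchors)
    s = restrict_range(s, *spec.range_classify)
    s = area_normalize(s, spec.area_norm_range)
    return s


def preprocess_set(
    sset: SpectrumSet,
    spec: PreprocessSpec | None = None,
    water_reference: np.ndarray | None = None,
) -> SpectrumSet:
    spec = spec or PreprocessSpec()
    return sset.map(lambda s: preprocess_spectrum(s, spec, water_reference))
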