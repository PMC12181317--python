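"""Core domain types and file I/O for infrared tissue spectra.

The unit of data throughout the package is an absorbance spectrum on a shared
wavenumber grid, carrying patient/sample/slice metadata and a record of the
preprocessing steps applied to it.  Grids are stored strictly ascending even
though FT-IR instruments conventionally write spectra with descending
wavenumbers; readers normalize the order and remember the original one, so a
window such as 995–1005 cm⁻¹ always means the same index range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "CLASS_LABELS",
    "CLASS_PALETTE",
    "WavenumberGrid",
    "SpectrumMeta",
    "Spectrum",
    "SpectrumSet",
    "SpectralImage",
    "FormatError",
    "GridError",
    "MetadataError",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_cube",
    "write_cube",
]

#: Tissue entity labels used throughout; "tumor" is the union class of the
#: three malignant entities, "unknown" marks unlabelled test spectra.
CLASS_LABELS = ("normal", "HCC", "CCC", "metastasis", "tumor", "unknown")

#: Fixed display colors for classification figures.
CLASS_PALETTE = {
    "normal": "green",
    "tumor": "black",
    "metastasis": "red",
    "CCC": "yellow",
    "HCC": "blue",
}

PREPROCESS_STATES = (
    "raw",
    "range_restricted",
    "baseline_corrected",
    "area_normalized",
    "minmax_normalized",
)


class FormatError(ValueError):
    """Malformed file content (ragged columns, missing dataset...)."""


class GridError(ValueError):
    """Wavenumber axis violates the grid contract."""


class MetadataError(ValueError):
    """Spectrum column without matching metadata row (or vice versa)."""


@dataclass(frozen=True)
class WavenumberGrid:
    """Uniform, strictly ascending wavenumber axis in cm⁻¹."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise GridError("grid needs at least two wavenumber points")
        d = np.diff(v)
        if np.any(d <= 0):
            raise GridError("wavenumbers must be strictly ascending")
        step = d.mean()
        if np.max(np.abs(d - step)) > 1e-6 * step:
            raise GridError("wavenumber grid is not uniform")
        object.__setattr__(self, "values", v)

    @classmethod
    def regular(cls, lo: float, hi: float, spacing: float) -> "WavenumberGrid":
        n = int(round((hi - lo) / spacing)) + 1
        return cls(lo + spacing * np.arange(n))

    @property
    def spacing(self) -> float:
        return float(np.diff(self.values).mean())

    def __len__(self) -> int:
        return len(self.values)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, WavenumberGrid) and np.array_equal(
            self.values, other.values
        )

    def __hash__(self) -> int:
        return hash((len(self.values), float(self.values[0]), float(self.values[-1])))

    def nearest_index(self, wavenumber: float) -> int:
        """Index of the grid point closest to *wavenumber*."""
        return int(np.argmin(np.abs(self.values - wavenumber)))

    def window_indices(self, lo: float, hi: float) -> np.ndarray:
        """Indices of all grid points in the closed interval [lo, hi]."""
        if hi < lo:
            raise GridError(f"empty window [{lo}, {hi}]")
        return np.nonzero((self.values >= lo) & (self.values <= hi))[0]


@dataclass
class SpectrumMeta:
    patient_id: str = ""
    sample_id: str = ""
    slice_id: str = ""
    class_label: str = "unknown"
    original_label: str = ""
    preprocessing_state: list[str] = field(default_factory=lambda: ["raw"])

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise MetadataError(f"unknown class label {self.class_label!r}")
        seen = set()
        for s in self.preprocessing_state:
            if s not in PREPROCESS_STATES:
                raise MetadataError(f"unknown preprocessing state {s!r}")
            if s in seen:
                raise MetadataError(f"repeated preprocessing state {s!r}")
            seen.add(s)

    @property
    def spectrum_id(self) -> str:
        return f"{self.patient_id}.{self.sample_id}.{self.slice_id}"


@dataclass
class Spectrum:
    """One absorbance spectrum with its metadata."""

    grid: WavenumberGrid
    absorbance: np.ndarray
    meta: SpectrumMeta = field(default_factory=SpectrumMeta)

    def __post_init__(self) -> None:
        a = np.asarray(self.absorbance, dtype=float)
        if a.shape != (len(self.grid),):
            raise GridError("absorbance length does not match grid")
        if not np.all(np.isfinite(a)):
            raise ValueError("absorbance contains non-finite values")
        self.absorbance = a

    def with_values(self, absorbance: np.ndarray, append_state: str | None = None,
                    grid: WavenumberGrid | None = None) -> "Spectrum":
        """New spectrum with replaced values, optionally recording a step."""
        meta = self.meta
        if append_state is not None and append_state not in meta.preprocessing_state:
            meta = replace(meta,
                           preprocessing_state=meta.preprocessing_state + [append_state])
        return Spectrum(grid or self.grid, absorbance, meta)


class SpectrumSet:
    """Collection of spectra sharing one grid, indexable by patient/sample."""

    def __init__(self, spectra: list[Spectrum]):
        if not spectra:
            raise ValueError("SpectrumSet needs at least one spectrum")
        grid = spectra[0].grid
        for s in spectra:
            if s.grid != grid:
                raise GridError("all spectra in a set must share one grid")
            if not s.meta.patient_id:
                raise MetadataError("every spectrum needs a non-empty patient_id")
        self.spectra = list(spectra)
        self.grid = grid

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def __getitem__(self, i):
        if isinstance(i, (list, np.ndarray)):
            return SpectrumSet([self.spectra[j] for j in np.asarray(i)])
        return self.spectra[i]

    def to_matrix(self) -> np.ndarray:
        """(n_spectra, n_points) absorbance matrix."""
        return np.vstack([s.absorbance for s in self.spectra])

    @property
    def labels(self) -> list[str]:
        return [s.meta.class_label for s in self.spectra]

    @property
    def patient_ids(self) -> list[str]:
        return [s.meta.patient_id for s in self.spectra]

    def by_patient(self) -> dict[str, list[int]]:
        idx: dict[str, list[int]] = {}
        for i, s in enumerate(self.spectra):
            idx.setdefault(s.meta.patient_id, []).append(i)
        return idx

    def by_sample(self) -> dict[tuple[str, str], list[int]]:
        idx: dict[tuple[str, str], list[int]] = {}
        for i, s in enumerate(self.spectra):
            idx.setdefault((s.meta.patient_id, s.meta.sample_id), []).append(i)
        return idx

    def subset_patients(self, patients) -> "SpectrumSet":
        patients = set(patients)
        return SpectrumSet([s for s in self.spectra if s.meta.patient_id in patients])

    def map(self, fn) -> "SpectrumSet":
        """Apply a Spectrum -> Spectrum function to every member."""
        return SpectrumSet([fn(s) for s in self.spectra])


@dataclass
class SpectralImage:
    """Hyperspectral absorbance cube (row, col, wavenumber) with pixel geometry.

    ``outlier_mask`` is True where a pixel spectrum was rejected; rejected
    pixels are rendered white in contrast images.
    """

    cube: np.ndarray
    grid: WavenumberGrid
    pixel_size_um: float
    outlier_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cube = np.asarray(self.cube, dtype=float)
        if self.cube.ndim != 3 or self.cube.shape[2] != len(self.grid):
            raise GridError("cube spectral axis does not match grid")
        if self.outlier_mask is None:
            self.outlier_mask = np.zeros(self.cube.shape[:2], dtype=bool)
        else:
            self.outlier_mask = np.asarray(self.outlier_mask, dtype=bool)
            if self.outlier_mask.shape != self.cube.shape[:2]:
                raise FormatError("outlier mask shape does not match cube")

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.cube.shape[:2]

    @property
    def physical_size_um(self) -> tuple[float, float]:
        r, c = self.spatial_shape
        return (r * self.pixel_size_um, c * self.pixel_size_um)


# ---------------------------------------------------------------------------
# Spectra tables: wide CSV + metadata sidecar


def _meta_frame(sset: SpectrumSet) -> pd.DataFrame:
    rows = [
        {
            "spectrum_id": s.meta.spectrum_id,
            "patient_id": s.meta.patient_id,
            "sample_id": s.meta.sample_id,
            "slice_id": s.meta.slice_id,
            "class_label": s.meta.class_label,
            "original_label": s.meta.original_label,
            "preprocessing_state": "|".join(s.meta.preprocessing_state),
        }
        for s in sset
    ]
    return pd.DataFrame(rows)


def write_spectra_csv(sset: SpectrumSet, path, meta_path=None) -> None:
    """Write a set as a wide CSV (column per spectrum) plus a metadata CSV.

    Columns are ordered by (patient_id, sample_id, slice_id) so output is
    deterministic regardless of in-memory order.
    """
    if len(sset) == 0:
        raise ValueError("cannot write an empty SpectrumSet")
    order = sorted(
        range(len(sset)),
        key=lambda i: (
            sset[i].meta.patient_id,
            sset[i].meta.sample_id,
            sset[i].meta.slice_id,
        ),
    )
    data = {"wavenumber_cm1": sset.grid.values}
    ids = []
    for i in order:
        sid = sset[i].meta.spectrum_id
        if sid in data:
            raise MetadataError(f"duplicate spectrum id {sid!r}")
        data[sid] = sset[i].absorbance
        ids.append(sid)
    pd.DataFrame(data).to_csv(path, index=False)
    if meta_path is None:
        meta_path = _default_meta_path(path)
    meta = _meta_frame(sset).iloc[order]
    meta.to_csv(meta_path, index=False)


def _default_meta_path(path) -> str:
    p = str(path)
    return (p[:-4] if p.endswith(".csv") else p) + ".meta.csv"


def read_spectra_csv(path, meta_path=None) -> SpectrumSet:
    """Read a wide spectra CSV and its metadata sidecar.

    Accepts descending wavenumber order (the instrument convention) and
    reverses it; the returned grid is always ascending.
    """
    df = pd.read_csv(path)
    if df.columns[0] != "wavenumber_cm1":
        raise FormatError("first column must be 'wavenumber_cm1'")
    if df.isna().any().any():
        raise FormatError("ragged or missing values in spectra table")
    wn = df["wavenumber_cm1"].to_numpy(dtype=float)
    descending = False
    if len(wn) > 1 and wn[0] > wn[-1]:
        descending = True
        df = df.iloc[::-1].reset_index(drop=True)
        wn = wn[::-1]
    if np.any(np.diff(wn) <= 0):
        raise GridError("wavenumber column is not monotone")
    grid = WavenumberGrid(wn)

    if meta_path is None:
        meta_path = _default_meta_path(path)
    meta = pd.read_csv(meta_path, dtype=str).fillna("")
    meta_by_id = {row["spectrum_id"]: row for _, row in meta.iterrows()}

    spectra = []
    for col in df.columns[1:]:
        if col not in meta_by_id:
            raise MetadataError(f"no metadata row for spectrum column {col!r}")
        m = meta_by_id[col]
        state = m.get("preprocessing_state", "raw") or "raw"
        sm = SpectrumMeta(
            patient_id=m["patient_id"],
            sample_id=m["sample_id"],
            slice_id=m["slice_id"],
            class_label=m["class_label"],
            original_label=m.get("original_label", "") or "",
            preprocessing_state=state.split("|"),
        )
        spectra.append(Spectrum(grid, df[col].to_numpy(dtype=float), sm))
    sset = SpectrumSet(spectra)
    sset.was_descending = descending
    return sset


# ---------------------------------------------------------------------------
# Hyperspectral cubes: HDF5 with /cube, /wavenumbers, /outlier_mask


def write_cube(image: SpectralImage, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("cube", data=image.cube)
        f.create_dataset("wavenumbers", data=image.grid.values)
        f.create_dataset("outlier_mask", data=image.outlier_mask)
        f.attrs["pixel_size_um"] = image.pixel_size_um


def read_cube(path) -> SpectralImage:
    with h5py.File(path, "r") as f:
        for name in ("cube", "wavenumbers", "outlier_mask"):
            if name not in f:
                raise FormatError(f"missing dataset /{name}")
        return SpectralImage(
            cube=f["cube"][()],
            grid=WavenumberGrid(f["wavenumbers"][()]),
            pixel_size_um=float(f.attrs["pixel_size_um"]),
            outlier_mask=f["outlier_mask"][()],
        )
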