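"""End-to-end experiments: binary (normal vs tumor) and 3-class (Met/CCC/HCC).

The protocol mirrors the published one at synthetic scale: a patient-level
train/test partition (a sample contributes all its spectra to one side),
region selection by the genetic routine (or a preset window set) on the
training data only, quadratic-discriminant training, re-classification of the
training set, k-fold cross-validation, and classification plus evaluation of
the independent test set.  All randomness is consumed from the single
experiment seed, and reports embed full provenance, so reruns with the same
seed are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .classification import (
    classify_samples,
    kfold_cross_validate,
    normalization_fingerprint,
    qda_fit,
)
from .core import SpectrumSet
from .evaluation import binary_metrics, confusion_matrix
from .preprocessing import PreprocessSpec, minmax_normalize, preprocess_set
from .region_selection import (
    BINARY_PRESET,
    THREE_CLASS_PRESET,
    GaConfig,
    RegionSet,
    extract_features,
    ga_select_regions,
)

__all__ = ["ExperimentConfig", "ExperimentResult", "relabel_to_tumor_union", "run_experiment"]

TUMOR_ENTITIES = ("HCC", "CCC", "metastasis")


def relabel_to_tumor_union(sset: SpectrumSet) -> SpectrumSet:
    """Merge the three malignant entities into one 'tumor' class.

    The original entity label is retained in metadata (``original_label``) so
    it stays recoverable.
    """

    def relabel(s):
        label = s.meta.class_label
        if label == "normal" or label == "tumor":
            return s
        if label not in TUMOR_ENTITIES:
            raise ValueError(f"unknown label {label!r}")
        meta = replace(s.meta, class_label="tumor", original_label=label)
        from .core import Spectrum

        return Spectrum(s.grid, s.absorbance, meta)

    return sset.map(relabel)


@dataclass
class ExperimentConfig:
    task: str = "binary"  # or "three_class"
    n_train_patients: int | dict[str, int] | None = None
    preprocess: PreprocessSpec = field(default_factory=PreprocessSpec)
    regions: RegionSet | None = None  # None with use_preset=False → run the GA
    use_preset: bool = True
    ga: GaConfig | None = None
    k: int = 10
    cv_split_level: str = "spectrum"
    shrinkage: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in ("binary", "three_class"):
            raise ValueError("task must be 'binary' or 'three_class'")

    def train_patients_per_class(self, classes: list[str]) -> dict[str, int]:
        """Balanced defaults: 20 training patients total for the binary task
        (10 per arm), 6 per class for the 3-class task."""
        if isinstance(self.n_train_patients, dict):
            return dict(self.n_train_patients)
        if self.task == "binary":
            total = self.n_train_patients or 20
            per = total // len(classes)
            return {c: per for c in classes}
        per = self.n_train_patients or 6
        return {c: per for c in classes}


@dataclass
class ExperimentResult:
    config_provenance: dict
    train_patients: list[str]
    test_patients: list[str]
    regions: RegionSet
    model: object
    train_table: object  # per-sample classification of the training set
    cv: dict
    test_table: object
    test_confusion: object
    test_metrics: dict
    train_confusion: object = None

    def report(self) -> dict:
        """JSON-serializable summary; deterministic key order and floats."""
        return {
            "provenance": self.config_provenance,
            "train_patients": self.train_patients,
            "test_patients": self.test_patients,
            "regions": self.regions.to_dict(),
            "model": self.model.to_dict(),
            "cv": {
                "fold_accuracies": self.cv["fold_accuracies"],
                "pooled_accuracy": self.cv["pooled_accuracy"],
            },
            "train_samples": json.loads(self.train_table.to_json(orient="records")),
            "test_samples": json.loads(self.test_table.to_json(orient="records")),
            "test_confusion": {
                "classes": self.test_confusion.classes,
                "counts": self.test_confusion.counts.tolist(),
            },
            "test_metrics": self.test_metrics,
        }

    def to_json(self) -> str:
        return json.dumps(self.report(), sort_keys=True, indent=1)


def _minmax_set(sset: SpectrumSet) -> SpectrumSet:
    return sset.map(minmax_normalize)


def run_experiment(config: ExperimentConfig, data: SpectrumSet) -> ExperimentResult:
    """Run one full experiment on a labelled cohort."""
    rng = np.random.default_rng(config.seed)

    if config.task == "binary":
        data = relabel_to_tumor_union(data)
    classes = sorted(set(data.labels))
    if config.task == "binary" and set(classes) != {"normal", "tumor"}:
        raise ValueError("binary task needs normal and tumor spectra")

    # patient-level partition, stratified by class
    by_patient = data.by_patient()
    cls_of = {p: data[idx[0]].meta.class_label for p, idx in by_patient.items()}
    want = config.train_patients_per_class(classes)
    train_patients: list[str] = []
    for cls in classes:
        plist = sorted(p for p, c in cls_of.items() if c == cls)
        n = want.get(cls, 0)
        if n < 1 or n >= len(plist):
            raise ValueError(
                f"class {cls!r}: cannot take {n} training patients out of {len(plist)}"
            )
        train_patients.extend(rng.permutation(plist)[:n].tolist())
    test_patients = sorted(set(by_patient) - set(train_patients))
    train_patients = sorted(train_patients)

    train_raw = data.subset_patients(train_patients)
    test_raw = data.subset_patients(test_patients)

    train_set = _minmax_set(preprocess_set(train_raw, config.preprocess))
    test_set = _minmax_set(preprocess_set(test_raw, config.preprocess))

    # region selection from training data only
    if config.regions is not None:
        regions = config.regions
    elif config.use_preset:
        regions = BINARY_PRESET if config.task == "binary" else THREE_CLASS_PRESET
    else:
        ga = config.ga or GaConfig()
        ga = replace(ga, seed=int(rng.integers(0, 2**31 - 1)))
        regions = ga_select_regions(train_set, ga)

    fingerprint = normalization_fingerprint(train_set, regions)
    model = qda_fit(
        extract_features(train_set, regions),
        train_set.labels,
        shrinkage=config.shrinkage,
        regions=regions,
        normalization_hash=fingerprint,
    )

    from .classification import render_probability_grid

    train_results = classify_samples(model, train_set)
    train_table = render_probability_grid(train_results)
    cv = kfold_cross_validate(
        train_set,
        regions,
        k=config.k,
        split_level=config.cv_split_level,
        seed=int(rng.integers(0, 2**31 - 1)),
        shrinkage=config.shrinkage,
    )
    test_results = classify_samples(model, test_set)
    test_table = render_probability_grid(test_results)

    test_cm = confusion_matrix(test_results, classes=model.classes)
    train_cm = confusion_matrix(train_results, classes=model.classes)
    if config.task == "binary":
        metrics = binary_metrics(test_cm, positive_class="tumor")
        metrics["accuracy"] = test_cm.accuracy
    else:
        metrics = {"accuracy": test_cm.accuracy}

    provenance = {
        "task": config.task,
        "seed": config.seed,
        "k": config.k,
        "cv_split_level": config.cv_split_level,
        "shrinkage": config.shrinkage,
        "regions_source": (
            "explicit" if config.regions is not None
            else "preset" if config.use_preset else "ga"
        ),
        "normalization_hash": fingerprint,
        "n_train_spectra": len(train_set),
        "n_test_spectra": len(test_set),
    }
    return ExperimentResult(
        config_provenance=provenance,
        train_patients=train_patients,
        test_patients=test_patients,
        regions=regions,
        model=model,
        train_table=train_table,
        cv=cv,
        test_table=test_table,
        test_confusion=test_cm,
        test_metrics=metrics,
        train_confusion=train_cm,
    )
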