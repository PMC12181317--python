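"""Quadratic discriminant classification with per-sample posterior averaging.

Each spectrum is scored by a class-conditional Gaussian model (one mean and
covariance per class) and assigned posterior class probabilities.  A tissue
sample is then classified from the arithmetic mean of the posteriors of all
its spectra: in the binary task a sample belongs to the class whose mean
probability exceeds 0.5; in the multi-class task the highest mean probability
P(Met), P(CCC), P(HCC) decides.

Covariances are shrunk towards a scaled identity, Σ + λ·(tr Σ/d)·I, because
the narrow selected windows can make class covariances near-singular;
posterior arithmetic is done in log space with log-sum-exp.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.special import logsumexp

from .core import CLASS_PALETTE, SpectrumSet
from .region_selection import RegionSet, extract_features

__all__ = [
    "QdaModel",
    "SampleClassification",
    "normalization_fingerprint",
    "qda_fit",
    "qda_posterior",
    "kfold_cross_validate",
    "classify_samples",
    "render_probability_grid",
]


def normalization_fingerprint(sset: SpectrumSet, regions: RegionSet | None) -> str:
    """Hash of the preprocessing state and region windows, used to refuse
    classifying spectra that were not normalized like the training data."""
    states = {tuple(s.meta.preprocessing_state) for s in sset}
    if len(states) != 1:
        raise ValueError("spectra in the set have inconsistent preprocessing states")
    payload = repr((sorted(states), regions.windows if regions else None)).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class QdaModel:
    classes: list[str]
    means: np.ndarray  # (k, d)
    covariances: np.ndarray  # (k, d, d), shrinkage included
    priors: np.ndarray  # (k,)
    shrinkage: float
    regions: RegionSet | None = None
    normalization_hash: str = ""
    _chol: np.ndarray = field(init=False, repr=False)
    _logdet: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not np.isclose(self.priors.sum(), 1.0):
            raise ValueError("priors must sum to 1")
        k, d = self.means.shape
        chol = np.empty((k, d, d))
        logdet = np.empty(k)
        for i in range(k):
            try:
                chol[i] = np.linalg.cholesky(self.covariances[i])
            except np.linalg.LinAlgError as e:
                raise np.linalg.LinAlgError(
                    f"covariance of class {self.classes[i]!r} is singular even "
                    "after shrinkage; increase the shrinkage parameter"
                ) from e
            logdet[i] = 2.0 * np.log(np.diag(chol[i])).sum()
        self._chol = chol
        self._logdet = logdet

    @property
    def n_features(self) -> int:
        return self.means.shape[1]

    def to_dict(self) -> dict:
        return {
            "classes": self.classes,
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "priors": self.priors.tolist(),
            "shrinkage": self.shrinkage,
            "regions": self.regions.to_dict() if self.regions else None,
            "normalization_hash": self.normalization_hash,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QdaModel":
        regions = RegionSet(d["regions"]["windows"]) if d.get("regions") else None
        return cls(
            classes=list(d["classes"]),
            means=np.asarray(d["means"], dtype=float),
            covariances=np.asarray(d["covariances"], dtype=float),
            priors=np.asarray(d["priors"], dtype=float),
            shrinkage=float(d["shrinkage"]),
            regions=regions,
            normalization_hash=d.get("normalization_hash", ""),
        )


def qda_fit(
    features: np.ndarray | pd.DataFrame,
    labels,
    priors: np.ndarray | None = None,
    shrinkage: float = 1e-3,
    regions: RegionSet | None = None,
    normalization_hash: str = "",
) -> QdaModel:
    """Fit per-class Gaussians: class means, sample covariances with identity
    shrinkage λ·(tr Σ/d)·I, and empirical priors unless given."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D table")
    classes = sorted(np.unique(y).tolist())
    k, d = len(classes), X.shape[1]
    means = np.empty((k, d))
    covs = np.empty((k, d, d))
    counts = np.empty(k)
    for i, cls in enumerate(classes):
        Xc = X[y == cls]
        if Xc.shape[0] < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 spectra")
        counts[i] = Xc.shape[0]
        means[i] = Xc.mean(axis=0)
        cov = np.cov(Xc, rowvar=False, ddof=1).reshape(d, d)
        scale = np.trace(cov) / d
        if scale <= 0:
            scale = 1.0  # degenerate (e.g. noise-free) class: fall back to identity
        covs[i] = cov + shrinkage * scale * np.eye(d)
    if priors is None:
        priors = counts / counts.sum()
    else:
        priors = np.asarray(priors, dtype=float)
    return QdaModel(
        classes=classes,
        means=means,
        covariances=covs,
        priors=priors,
        shrinkage=shrinkage,
        regions=regions,
        normalization_hash=normalization_hash,
    )


def qda_posterior(model: QdaModel, x: np.ndarray) -> np.ndarray:
    """Posterior class probabilities, computed in log space.

    Accepts one feature vector (d,) → (k,) or a batch (n, d) → (n, k); each
    posterior row sums to 1.
    """
    X = np.asarray(x, dtype=float)
    single = X.ndim == 1
    if single:
        X = X[None, :]
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model ({model.n_features})"
        )
    k = len(model.classes)
    log_post = np.empty((X.shape[0], k))
    for i in range(k):
        diff = (X - model.means[i]).T
        u = solve_triangular(model._chol[i], diff, lower=True)
        maha = np.sum(u * u, axis=0)
        log_post[:, i] = (
            np.log(model.priors[i]) - 0.5 * model._logdet[i] - 0.5 * maha
        )
    log_post -= logsumexp(log_post, axis=1, keepdims=True)
    post = np.exp(log_post)
    return post[0] if single else post


@dataclass
class SampleClassification:
    """Per-sample aggregate of spectrum-level posteriors."""

    patient_id: str
    sample_id: str
    n_spectra: int
    posteriors: np.ndarray  # (n_spectra, k)
    mean_probability: dict[str, float]
    assigned_class: str
    ambiguous: bool
    true_label: str = ""


def _assign(classes: list[str], mean_p: np.ndarray, posteriors: np.ndarray):
    """Decision rules: binary p>0.5 (tie → tumor, flagged); multiclass argmax
    (tie → highest single-spectrum posterior, then class order, flagged)."""
    if len(classes) == 2:
        top = int(np.argmax(mean_p))
        if mean_p[0] == mean_p[1]:
            cls = "tumor" if "tumor" in classes else classes[1]
            return cls, True
        return classes[top], False
    best = np.max(mean_p)
    tied = [i for i, p in enumerate(mean_p) if p == best]
    if len(tied) == 1:
        return classes[tied[0]], False
    peak = [posteriors[:, i].max() for i in tied]
    return classes[tied[int(np.argmax(peak))]], True


def classify_samples(model: QdaModel, sset: SpectrumSet) -> list[SampleClassification]:
    """Classify every (patient, sample) group by its mean posterior."""
    if model.normalization_hash:
        got = normalization_fingerprint(sset, model.regions)
        if got != model.normalization_hash:
            raise ValueError(
                "preprocessing fingerprint mismatch: spectra are not normalized "
                "like the training data"
            )
    feats = extract_features(sset, model.regions).to_numpy() if model.regions else sset.to_matrix()
    post = qda_posterior(model, feats)
    results = []
    for (pid, sid), idx in sorted(sset.by_sample().items()):
        p = post[idx]
        mean_p = p.mean(axis=0)
        cls, ambiguous = _assign(model.classes, mean_p, p)
        truth = {sset[i].meta.class_label for i in idx}
        results.append(
            SampleClassification(
                patient_id=pid,
                sample_id=sid,
                n_spectra=len(idx),
                posteriors=p,
                mean_probability={c: float(v) for c, v in zip(model.classes, mean_p)},
                assigned_class=cls,
                ambiguous=ambiguous,
                true_label=truth.pop() if len(truth) == 1 else "unknown",
            )
        )
    return results


def kfold_cross_validate(
    sset: SpectrumSet,
    regions: RegionSet | None,
    k: int = 10,
    split_level: str = "spectrum",
    seed: int = 0,
    shrinkage: float = 1e-3,
) -> dict:
    """Stratified k-fold cross-validation at spectrum or patient level.

    Every spectrum is predicted exactly once; returns per-fold and pooled
    spectrum-level accuracies.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = np.asarray(sset.labels)
    feats = extract_features(sset, regions).to_numpy() if regions else sset.to_matrix()
    n = len(sset)
    folds: list[np.ndarray] = []
    if split_level == "spectrum":
        if k > n:
            raise ValueError("k exceeds the number of spectra")
        if k == n:  # leave-one-out: stratification is impossible and moot
            folds = [np.array([i]) for i in range(n)]
        else:
            from sklearn.model_selection import StratifiedKFold

            skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
            folds = [test for _, test in skf.split(feats, labels)]
    elif split_level == "patient":
        by_patient = sset.by_patient()
        if k > len(by_patient):
            raise ValueError("k exceeds the number of patients")
        rng = np.random.default_rng(seed)
        assignment: dict[str, int] = {}
        cls_of = {p: sset[idx[0]].meta.class_label for p, idx in by_patient.items()}
        for cls in sorted(set(cls_of.values())):
            plist = rng.permutation(sorted(p for p in by_patient if cls_of[p] == cls))
            for i, p in enumerate(plist):
                assignment[p] = i % k
        folds = [
            np.concatenate(
                [by_patient[p] for p in by_patient if assignment[p] == f] or [[]]
            ).astype(int)
            for f in range(k)
        ]
    else:
        raise ValueError("split_level must be 'spectrum' or 'patient'")

    pred = np.empty(n, dtype=object)
    fold_acc = []
    for f, test_idx in enumerate(folds):
        if len(test_idx) == 0:
            fold_acc.append(np.nan)
            continue
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        model = qda_fit(feats[train_mask], labels[train_mask], shrinkage=shrinkage)
        post = qda_posterior(model, feats[test_idx])
        p = np.asarray(model.classes)[np.argmax(post, axis=1)]
        pred[test_idx] = p
        fold_acc.append(float(np.mean(p == labels[test_idx])))
    pooled = float(np.mean(pred == labels))
    return {"fold_accuracies": fold_acc, "pooled_accuracy": pooled, "predictions": pred}


def render_probability_grid(
    results: list[SampleClassification],
    palette: dict[str, str] | None = None,
    csv_path=None,
    png_path=None,
):
    """Tabulate and optionally draw the per-sample classification grid.

    One row per sample: patient, spectrum count, mean class probabilities
    (the large colored box of the published figures), and one small cell per
    spectrum whose color intensity follows its top posterior.
    """
    if not results:
        raise ValueError("no sample classifications to render")
    palette = palette or CLASS_PALETTE
    classes = list(results[0].mean_probability)
    rows = []
    for r in results:
        row = {
            "patient_id": r.patient_id,
            "sample_id": r.sample_id,
            "n_spectra": r.n_spectra,
        }
        row.update({f"P_{c}": r.mean_probability[c] for c in classes})
        row["assigned_class"] = r.assigned_class
        row["ambiguous"] = r.ambiguous
        rows.append(row)
    table = pd.DataFrame(rows)
    if csv_path is not None:
        table.to_csv(csv_path, index=False)
    fig = None
    if png_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from matplotlib.colors import to_rgb

        fig, ax = plt.subplots(figsize=(8, 0.4 * len(results) + 1))
        for yi, r in enumerate(results):
            color = to_rgb(palette.get(r.assigned_class, "gray"))
            strength = r.mean_probability[r.assigned_class]
            box = tuple(1 - strength * (1 - c) for c in color)
            ax.add_patch(plt.Rectangle((0, yi), 1.8, 0.9, color=box))
            ax.text(-0.1, yi + 0.45, f"{r.patient_id}/{r.sample_id} (n={r.n_spectra})",
                    ha="right", va="center", fontsize=7)
            for xi in range(r.n_spectra):
                p = r.posteriors[xi]
                ci = int(np.argmax(p))
                c = to_rgb(palette.get(classes[ci], "gray"))
                cell = tuple(1 - p[ci] * (1 - v) for v in c)
                ax.add_patch(plt.Rectangle((2.0 + 0.5 * xi, yi), 0.45, 0.9, color=cell))
        ax.set_xlim(-3, 2.0 + 0.5 * max(r.n_spectra for r in results) + 0.5)
        ax.set_ylim(0, len(results))
        ax.invert_yaxis()
        ax.axis("off")
        fig.savefig(png_path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return table
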