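"""Pareto scaling, PCA, and the confidence-ellipse authenticity test.

The classifier is a Hotelling T^2 test in the plane of the first two
principal components: the authentic (olive) reference class defines a
mean and 2x2 score covariance, and a new sample is called authentic
when its squared Mahalanobis distance from the class mean does not
exceed the new-observation Hotelling bound

    T2_crit = 2 (n-1)(n+1) / (n (n-2)) * F_{1-alpha}(2, n-2),

which tends to the chi-square(2) quantile (5.991 at 95%) as the
reference panel grows.

PCA is computed from first principles via the SVD of the Pareto-scaled
matrix; scikit-learn, where available, serves only as an independent
cross-check in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .features import FeatureMatrix
from .spectra import SpectrumValidationError

__all__ = [
    "PCAModel",
    "EllipseModel",
    "ClassificationResult",
    "pareto_scale",
    "fit_pca",
    "fit_chemometric_model",
    "project",
    "fit_ellipse",
    "hotelling_t2",
    "classify",
]


def pareto_scale(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Mean-centre each column, then divide by sqrt(sample sd).

    Pareto scaling sits between plain centring and unit-variance
    scaling: large peaks keep more of their leverage, small ones are
    lifted.  Returns ``(scaled, means, weights, zero_variance_mask)``;
    zero-variance columns are centred and left undivided (weight 1).
    Uses the n-1 standard deviation throughout for consistency with the
    covariance estimates downstream.
    """
    X = np.asarray(values, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise SpectrumValidationError("pareto_scale needs >= 2 samples")
    if not np.all(np.isfinite(X)):
        raise SpectrumValidationError("matrix contains NaN/Inf")
    means = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    zero_var = sd == 0.0
    weights = np.where(zero_var, 1.0, np.sqrt(sd))
    scaled = (X - means) / weights
    return scaled, means, weights, zero_var


@dataclass
class PCAModel:
    """Loadings, scores and scaling parameters of a fitted PCA."""

    column_means: np.ndarray
    pareto_weights: np.ndarray
    loadings: np.ndarray            # bins x components, orthonormal columns
    explained_fraction: np.ndarray  # per component, of total variance
    scores: np.ndarray              # training samples x components
    bin_centers: np.ndarray
    zero_variance: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.zero_variance is None:
            self.zero_variance = np.zeros(self.column_means.size, dtype=bool)

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "column_means": self.column_means.tolist(),
            "pareto_weights": self.pareto_weights.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_fraction": self.explained_fraction.tolist(),
            "scores": self.scores.tolist(),
            "bin_centers": self.bin_centers.tolist(),
            "zero_variance": self.zero_variance.astype(int).tolist(),
        }
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "PCAModel":
        d = json.loads(Path(path).read_text())
        return cls(
            column_means=np.array(d["column_means"]),
            pareto_weights=np.array(d["pareto_weights"]),
            loadings=np.array(d["loadings"]),
            explained_fraction=np.array(d["explained_fraction"]),
            scores=np.array(d["scores"]),
            bin_centers=np.array(d["bin_centers"]),
            zero_variance=np.array(d["zero_variance"], dtype=bool),
        )


def fit_pca(scaled: np.ndarray, n_components: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Top right-singular directions of an already centred/scaled matrix.

    Returns ``(loadings, explained_fraction, scores)``.  The sign of
    each loading column is fixed so its largest-magnitude element is
    positive, making score plots reproducible across SVD
    implementations.
    """
    X = np.asarray(scaled, dtype=float)
    n, p = X.shape
    if n_components > min(n - 1, p):
        raise SpectrumValidationError(
            f"n_components={n_components} exceeds min(samples-1, bins)="
            f"{min(n - 1, p)}"
        )
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    var = s**2
    total = var.sum()
    explained = var[:n_components] / total if total > 0 else np.zeros(n_components)
    loadings = vt[:n_components].T.copy()
    for j in range(loadings.shape[1]):
        k = np.argmax(np.abs(loadings[:, j]))
        if loadings[k, j] < 0:
            loadings[:, j] = -loadings[:, j]
    scores = X @ loadings
    return loadings, explained, scores


def fit_chemometric_model(matrix: FeatureMatrix, n_components: int = 2) -> PCAModel:
    """Pareto-scale a feature matrix and fit the PCA in one step."""
    scaled, means, weights, zero_var = pareto_scale(matrix.values)
    loadings, explained, scores = fit_pca(scaled, n_components)
    return PCAModel(
        column_means=means,
        pareto_weights=weights,
        loadings=loadings,
        explained_fraction=explained,
        scores=scores,
        bin_centers=matrix.bin_centers.copy(),
        zero_variance=zero_var,
    )


def project(model: PCAModel, matrix: FeatureMatrix) -> np.ndarray:
    """Project new samples with the stored centring/scaling/loadings.

    The map is affine, so training samples land exactly on their
    training scores and a 50:50 blend of two samples lands at the
    midpoint of their scores.
    """
    if matrix.bin_centers.size != model.bin_centers.size or \
            not np.allclose(matrix.bin_centers, model.bin_centers):
        raise SpectrumValidationError(
            "bin centres of the new matrix do not match the fitted model"
        )
    scaled = (matrix.values - model.column_means) / model.pareto_weights
    return scaled @ model.loadings


@dataclass
class EllipseModel:
    """Reference-class confidence region in the PC1-PC2 plane."""

    center: np.ndarray        # (2,)
    covariance: np.ndarray    # (2, 2), SPD
    threshold: float          # critical squared Mahalanobis distance
    confidence: float = 0.95
    n_ref: int = 0

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.center.shape != (2,) or self.covariance.shape != (2, 2):
            raise SpectrumValidationError("ellipse is defined in PC1-PC2 only")
        if not np.allclose(self.covariance, self.covariance.T):
            raise SpectrumValidationError("covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(self.covariance) <= 0):
            raise SpectrumValidationError("covariance must be positive definite")
        if not (self.threshold > 0):
            raise SpectrumValidationError("threshold must be positive")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps({
            "center": self.center.tolist(),
            "covariance": self.covariance.tolist(),
            "threshold": self.threshold,
            "confidence": self.confidence,
            "n_ref": self.n_ref,
        }))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "EllipseModel":
        d = json.loads(Path(path).read_text())
        return cls(center=np.array(d["center"]),
                   covariance=np.array(d["covariance"]),
                   threshold=d["threshold"],
                   confidence=d["confidence"],
                   n_ref=d["n_ref"])


def fit_ellipse(reference_scores: np.ndarray,
                confidence: float = 0.95) -> EllipseModel:
    """Fit the reference-class ellipse in PC1-PC2.

    Uses the Hotelling T^2 bound for a single new observation, which
    accounts for the reference mean and covariance being estimated from
    ``n`` samples; for large ``n`` the threshold approaches the
    chi-square(2) quantile.
    """
    S = np.asarray(reference_scores, dtype=float)[:, :2]
    n = S.shape[0]
    if n < 4:
        raise SpectrumValidationError("need >= 4 reference samples for an ellipse")
    center = S.mean(axis=0)
    cov = np.cov(S, rowvar=False, ddof=1)
    if np.linalg.matrix_rank(cov) < 2 or np.any(np.linalg.eigvalsh(cov) <= 0):
        raise SpectrumValidationError("reference score covariance is singular")
    fq = stats.f.ppf(confidence, 2, n - 2)
    threshold = (2.0 * (n - 1) * (n + 1)) / (n * (n - 2)) * fq
    return EllipseModel(center=center, covariance=cov, threshold=float(threshold),
                        confidence=confidence, n_ref=n)


def hotelling_t2(ellipse: EllipseModel, scores: np.ndarray) -> np.ndarray:
    """Squared Mahalanobis distance of PC1-PC2 score points from the class."""
    S = np.atleast_2d(np.asarray(scores, dtype=float))[:, :2]
    d = S - ellipse.center
    inv = np.linalg.inv(ellipse.covariance)
    return np.einsum("ij,jk,ik->i", d, inv, d)


@dataclass(frozen=True)
class ClassificationResult:
    """Authenticity call for one sample."""

    sample_id: str
    pc1: float
    pc2: float
    t2: float
    authentic: bool
    nearest_reference: str | None = None


def classify(model: PCAModel,
             ellipse: EllipseModel,
             samples: FeatureMatrix,
             reference_centroids: Mapping[str, Sequence[float]] | None = None,
             ) -> list[ClassificationResult]:
    """Classify binned samples against the reference ellipse.

    A sample is authentic iff its T^2 in PC1-PC2 is at or below the
    ellipse threshold.  If pure-oil reference centroids are supplied,
    each result also names the Euclidean-closest centroid — the oil the
    sample is trending toward — which suggests the likely adulterant for
    flagged samples.
    """
    scores = project(model, samples)[:, :2]
    t2 = hotelling_t2(ellipse, scores)
    results = []
    cent_items = list(reference_centroids.items()) if reference_centroids else []
    for i, sid in enumerate(samples.sample_ids):
        nearest = None
        if cent_items:
            dists = [float(np.hypot(*(scores[i] - np.asarray(c, dtype=float))))
                     for _, c in cent_items]
            nearest = cent_items[int(np.argmin(dists))][0]
        results.append(ClassificationResult(
            sample_id=sid,
            pc1=float(scores[i, 0]),
            pc2=float(scores[i, 1]),
            t2=float(t2[i]),
            authentic=bool(t2[i] <= ellipse.threshold),
            nearest_reference=nearest,
        ))
    return results
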