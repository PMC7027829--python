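"""Spectral feature extraction: the pixel × feature matrix and type-1 PCA.

The variance-partitioning math operates on a matrix **Y** of *n* pixels ×
*p* spectral features. The features may be the original reflectance bands, a
user-supplied set of spectral indices, or — the usual choice — principal
component scores with *type-1 scaling*. Type-1 (distance-preserving) scaling
means scores are simply the centered data projected onto the orthonormal
eigenvectors of the covariance matrix, so pairwise Euclidean distances among
pixels are preserved at full rank. As a consequence every sum-of-squares
quantity is identical on bands and on the full PC set, and the per-feature
contribution to total variance of PC *j* equals its relative eigenvalue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from sklearn.decomposition import PCA

from .cube import SpectralCube
from .errors import ParameterError, ValidationError


@dataclass
class FeatureMatrix:
    """Pixel × spectral-feature matrix Y with pixel image coordinates.

    Attributes
    ----------
    values
        (n, p) float array; rows are pixels, columns spectral features.
    feature_labels
        One name per column (band wavelengths, "PC1"…, or index names).
    pixel_index
        (n, 2) int array of (row, col) image coordinates, unique per row.
    """

    values: np.ndarray
    feature_labels: List[str] = field(default_factory=list)
    pixel_index: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("FeatureMatrix values must be 2-D (n, p)")
        n, p = self.values.shape
        if n < 2:
            raise ValidationError(f"FeatureMatrix needs n >= 2 pixels; got {n}")
        if p < 1:
            raise ValidationError("FeatureMatrix needs p >= 1 features")
        if not np.isfinite(self.values).all():
            raise ValidationError("FeatureMatrix contains non-finite values")
        if not self.feature_labels:
            self.feature_labels = [f"f{j + 1}" for j in range(p)]
        if len(self.feature_labels) != p:
            raise ValidationError(
                f"{len(self.feature_labels)} feature labels for {p} columns"
            )
        if self.pixel_index is None:
            self.pixel_index = np.column_stack(
                [np.arange(n), np.zeros(n, dtype=int)]
            )
        else:
            self.pixel_index = np.asarray(self.pixel_index, dtype=int)
            if self.pixel_index.shape != (n, 2):
                raise ValidationError("pixel_index must have shape (n, 2)")
            if len(np.unique(self.pixel_index, axis=0)) != n:
                raise ValidationError("pixel_index entries must be unique")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_cube(cls, cube: SpectralCube) -> "FeatureMatrix":
        """Valid pixels of a cube as a feature matrix (features = bands)."""
        labels = [f"{wl:g}nm" for wl in cube.wavelengths]
        return cls(
            values=cube.valid_spectra(),
            feature_labels=labels,
            pixel_index=cube.valid_pixel_coords(),
        )


@dataclass
class PcaModel:
    """Fitted principal-component model (covariance PCA, divisor n−1).

    ``loadings`` columns are orthonormal eigenvectors of the covariance of
    the column-centered training matrix, ordered by decreasing eigenvalue.
    ``relative_eigenvalues`` sum to 1 and equal the share of total variance
    carried by each component. ``degenerate`` flags a rank-0 fit (all
    training rows identical).
    """

    center: np.ndarray
    loadings: np.ndarray  # (p_original, k), orthonormal columns
    eigenvalues: np.ndarray  # (k,), non-increasing, >= 0
    degenerate: bool = False

    @property
    def relative_eigenvalues(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        if total == 0:
            return np.full_like(self.eigenvalues, np.nan)
        return self.eigenvalues / total

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    @property
    def rank(self) -> int:
        """Number of components with nonzero variance."""
        if self.eigenvalues.size == 0 or self.eigenvalues[0] == 0:
            return 0
        tol = self.eigenvalues[0] * 1e-12
        return int(np.sum(self.eigenvalues > tol))

    def n_components_for_variance(self, target: float) -> int:
        """Smallest k whose components jointly explain >= target variance share."""
        if not 0 < target <= 1:
            raise ParameterError(f"variance target must be in (0, 1]; got {target}")
        cum = np.cumsum(self.relative_eigenvalues)
        return int(np.searchsorted(cum, target - 1e-12) + 1)


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: per column, the element of largest
    magnitude is made positive (ties broken by lowest feature index)."""
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0),
                            np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    return loadings * flip


def fit_pca(Y: FeatureMatrix | np.ndarray) -> PcaModel:
    """Fit a covariance PCA (type-1 scaling) to the feature matrix.

    Eigen-decomposition of the covariance of the column-centered matrix with
    divisor n−1; components ordered by decreasing eigenvalue, sign-fixed for
    reproducibility. A rank-0 matrix (all rows identical) yields a valid
    model with all eigenvalues 0 and ``degenerate=True``.
    """
    values = Y.values if isinstance(Y, FeatureMatrix) else np.asarray(Y, float)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValidationError("fit_pca requires a 2-D matrix with n >= 2 rows")
    n, p = values.shape
    k = min(n, p)
    pca = PCA(n_components=k, svd_solver="full")
    with warnings.catch_warnings():
        # rank-0 input triggers a harmless 0/0 in the variance-ratio bookkeeping
        warnings.simplefilter("ignore", RuntimeWarning)
        pca.fit(values)
    eigenvalues = np.clip(pca.explained_variance_, 0.0, None)
    loadings = _fix_signs(pca.components_.T)
    return PcaModel(
        center=pca.mean_,
        loadings=loadings,
        eigenvalues=eigenvalues,
        degenerate=bool(eigenvalues[0] == 0),
    )


def transform_pca(
    model: PcaModel,
    Y: FeatureMatrix | np.ndarray,
    n_components: Optional[int] = None,
) -> FeatureMatrix:
    """Project a feature matrix onto the leading principal components.

    Scores are ``(Y − center) · loadings`` truncated to ``n_components``
    columns. At full rank the pairwise Euclidean distances among rows equal
    those of the centered data (type-1 scaling contract).
    """
    if isinstance(Y, FeatureMatrix):
        values, pixel_index = Y.values, Y.pixel_index
    else:
        values, pixel_index = np.asarray(Y, float), None
    if n_components is None:
        n_components = model.n_components
    if not 1 <= n_components <= model.n_components:
        raise ParameterError(
            f"n_components must be in [1, {model.n_components}]; "
            f"got {n_components}"
        )
    scores = (values - model.center) @ model.loadings[:, :n_components]
    return FeatureMatrix(
        values=scores,
        feature_labels=[f"PC{j + 1}" for j in range(n_components)],
        pixel_index=pixel_index,
    )


def pca_features(
    Y: FeatureMatrix,
    n_components: Optional[int] = None,
    variance_target: Optional[float] = None,
) -> Tuple[FeatureMatrix, PcaModel]:
    """Fit PCA and return scores, selecting the component count.

    Exactly one of ``n_components`` (explicit count) or ``variance_target``
    (smallest k explaining at least that variance share) may be given; with
    neither, all components are kept.
    """
    if n_components is not None and variance_target is not None:
        raise ParameterError(
            "n_components and variance_target are mutually exclusive"
        )
    model = fit_pca(Y)
    if variance_target is not None:
        n_components = model.n_components_for_variance(variance_target)
    return transform_pca(model, Y, n_components), model
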