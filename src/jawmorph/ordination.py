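"""Euclidean distance matrix and principal coordinate analysis (PCoA).

Classical (Torgerson) scaling: double-centre the squared distance matrix,
eigendecompose, and scale eigenvectors by the square root of their (positive)
eigenvalues. For a Euclidean distance matrix this is exactly PCA of the
underlying coordinates, so all eigenvalues are non-negative up to round-off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .biomech import StandardizedMatrix


class OrdinationError(ValueError):
    pass


def euclidean_distances(X: StandardizedMatrix | pd.DataFrame) -> DistanceMatrix:
    """Pairwise Euclidean distances between specimen rows."""
    frame = X.values if isinstance(X, StandardizedMatrix) else X
    if frame.isna().any().any():
        raise OrdinationError(
            "missing values in the character matrix; impute or drop rows first")
    condensed = pdist(frame.to_numpy(dtype=float), metric="euclidean")
    return DistanceMatrix(squareform(condensed), ids=[str(i) for i in frame.index])


@dataclass
class OrdinationResult:
    """PCo scores, eigenvalues and per-axis variance-explained fractions."""

    coordinates: pd.DataFrame          # specimens x retained axes
    eigenvalues: np.ndarray            # descending, retained (positive) axes
    variance_explained: np.ndarray     # fractions of the positive-eigenvalue total

    @property
    def n_axes_retained(self) -> int:
        return self.coordinates.shape[1]


def pcoa(D: DistanceMatrix, n_axes: int | str = "all") -> OrdinationResult:
    """Classical scaling of a distance matrix.

    Eigenvalues within ``eps = 1e-8 * max eigenvalue`` of zero are clamped to
    zero and dropped; negative eigenvalues beyond ``eps`` abort, since the
    pipeline only feeds Euclidean distances, for which the double-centred
    Gram matrix is positive semidefinite up to round-off.

    Sign convention: each axis is oriented so the specimen with the largest
    absolute score on it has a positive score.
    """
    d = np.asarray(D.data, dtype=float)
    n = d.shape[0]
    if n < 2 or not np.any(d > 0):
        raise OrdinationError("degenerate ordination: all distances zero")
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (d ** 2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval, kind="stable")[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eps = 1e-8 * max(eigval.max(), 0.0)
    if eigval.min() < -eps:
        raise OrdinationError(
            f"negative eigenvalue {eigval.min():.3e} beyond tolerance {eps:.3e}; "
            "input distances are not Euclidean-embeddable")
    positive = eigval > eps
    eigval = eigval[positive]
    scores = eigvec[:, positive] * np.sqrt(eigval)
    # deterministic axis orientation
    flip = scores[np.abs(scores).argmax(axis=0), np.arange(scores.shape[1])] < 0
    scores[:, flip] *= -1.0
    if n_axes != "all":
        k = int(n_axes)
        scores, axis_eigval = scores[:, :k], eigval[:k]
    else:
        axis_eigval = eigval
    coords = pd.DataFrame(
        scores, index=list(D.ids),
        columns=[f"PCo{i + 1}" for i in range(scores.shape[1])])
    return OrdinationResult(
        coordinates=coords,
        eigenvalues=axis_eigval,
        variance_explained=axis_eigval / eigval.sum(),
    )
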