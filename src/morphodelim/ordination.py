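"""Principal component analysis of residuals or size-corrected indices.

With raw measurements the first component of a PCA is dominated by absolute
size, which is uninformative for separating cryptic species; the pipeline
therefore ordinates allometrically corrected data (residuals or
reference-size indices).  Covariance PCA is the default for residuals in
common µm units; correlation PCA (``scale=True``) suits mixed-scale indices.

The decomposition is deterministic: the sign of each loading vector is fixed
by making its largest-magnitude element positive, and new items (e.g. type
specimens) can be projected onto a stored ordination.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import MorphometryError
from .clustering import as_frame

__all__ = ["PCAResult", "pca", "project"]


@dataclass
class PCAResult:
    loadings: pd.DataFrame  # columns PC1.. ; rows = input columns
    scores: pd.DataFrame    # rows = items; columns PC1..
    explained_variance_ratio: np.ndarray
    center: np.ndarray
    scale_: np.ndarray | None  # column SDs if scaled, else None
    columns: list[str]

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def pca(matrix, center: bool = True, scale: bool = False) -> PCAResult:
    """Eigendecomposition of the covariance (or correlation) matrix via SVD."""
    frame = as_frame(matrix)
    if frame.shape[0] < 2:
        raise MorphometryError("PCA needs at least 2 rows")
    if frame.isna().any().any():
        raise MorphometryError("missing values in PCA input")
    X = frame.to_numpy(dtype=float)
    mean = X.mean(axis=0) if center else np.zeros(X.shape[1])
    Xc = X - mean
    sd = None
    if scale:
        sd = X.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            raise MorphometryError(
                f"constant column(s) {list(frame.columns[zero])} cannot be scaled"
            )
        Xc = Xc / sd
    _, svals, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-|.| element of each loading positive
    for i in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] = -Vt[i]
    var = svals**2 / (X.shape[0] - 1)
    total = var.sum()
    ratio = var / total if total > 0 else np.zeros_like(var)
    pcs = [f"PC{i + 1}" for i in range(Vt.shape[0])]
    return PCAResult(
        loadings=pd.DataFrame(Vt.T, index=frame.columns, columns=pcs),
        scores=pd.DataFrame(Xc @ Vt.T, index=frame.index, columns=pcs),
        explained_variance_ratio=ratio,
        center=mean,
        scale_=sd,
        columns=list(frame.columns),
    )


def project(result: PCAResult, new_items) -> pd.DataFrame:
    """Project new rows onto a stored ordination (centered/scaled identically)."""
    frame = as_frame(new_items)
    missing = [c for c in result.columns if c not in frame.columns]
    if missing:
        raise MorphometryError(f"projection input lacks column(s) {missing}")
    X = frame[result.columns].to_numpy(dtype=float)
    Xc = X - result.center
    if result.scale_ is not None:
        Xc = Xc / result.scale_
    V = result.loadings.to_numpy()
    return pd.DataFrame(Xc @ V, index=frame.index, columns=result.loadings.columns)
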