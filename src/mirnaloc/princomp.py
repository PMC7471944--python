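"""Principal-component score transformation of the combined feature matrix.

All components are retained: the projection is an orthogonal
re-coordinatization that decorrelates the 33 DiPro+PseDNC features without
discarding information.  Fitting belongs inside each training fold; the
fitted model then projects any matrix with the same named columns.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PrinCompModel:
    """Column means, orthonormal loadings and component variances of a fit.

    `loadings` columns are component directions with a deterministic sign:
    each column is flipped so its largest-magnitude element is positive.
    `variances` uses the n-1 divisor and is sorted non-increasing.
    """

    center: np.ndarray          # (p,)
    loadings: np.ndarray        # (p, p), orthonormal columns
    variances: np.ndarray       # (p,), non-increasing
    feature_names: tuple[str, ...]

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Project rows into principal-component scores (columns PC1..PCp)."""
        if tuple(X.columns) != self.feature_names:
            missing = set(self.feature_names) - set(X.columns)
            extra = set(X.columns) - set(self.feature_names)
            raise ValueError(
                f"feature columns do not match the fit: missing {sorted(missing)}, "
                f"unexpected {sorted(extra)}, or wrong order"
            )
        scores = (X.to_numpy() - self.center) @ self.loadings
        cols = [f"PC{i + 1}" for i in range(self.loadings.shape[1])]
        return pd.DataFrame(scores, index=X.index, columns=cols)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "center": self.center.tolist(),
            "loadings": self.loadings.tolist(),
            "variances": self.variances.tolist(),
            "feature_names": list(self.feature_names),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PrinCompModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            center=np.asarray(payload["center"]),
            loadings=np.asarray(payload["loadings"]),
            variances=np.asarray(payload["variances"]),
            feature_names=tuple(payload["feature_names"]),
        )


def fit_pca(X: pd.DataFrame) -> PrinCompModel:
    """Fit a full-rank PCA (covariance with n-1 divisor, no truncation).

    A constant matrix yields all-zero variances with a logged warning rather
    than an error, so degenerate fixtures still round-trip.
    """
    if X.shape[0] < 2:
        raise ValueError(f"PCA needs at least 2 rows, got {X.shape[0]}")
    if X.isna().any().any():
        raise ValueError("feature matrix contains missing values")
    arr = X.to_numpy(dtype=float)
    pca = PCA(n_components=None, svd_solver="full")
    pca.fit(arr)
    # components_ rows already carry sklearn's sign convention (largest-
    # magnitude entry of each direction positive); store as loading columns.
    loadings = pca.components_.T.copy()
    for k in range(loadings.shape[1]):
        col = loadings[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, k] = -col
    variances = pca.explained_variance_.copy()
    if np.allclose(variances, 0):
        logger.warning("constant feature matrix: all component variances are 0")
    return PrinCompModel(
        center=pca.mean_.copy(),
        loadings=loadings,
        variances=variances,
        feature_names=tuple(X.columns),
    )


def transform(model: PrinCompModel, X: pd.DataFrame) -> pd.DataFrame:
    """Functional alias for :meth:`PrinCompModel.transform`."""
    return model.transform(X)
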