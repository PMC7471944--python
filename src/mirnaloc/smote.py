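"""Synthetic minority over-sampling (SMOTE) for one-vs-rest training sets.

Each synthetic observation is built in three steps from a minority sample x
and one of its K nearest minority neighbours nn: take the difference
(nn - x), multiply it by a uniform random number u in [0, 1), and add the
result to x.  Synthetic points therefore lie on segments between minority
pairs, inside the minority class's convex hull.  Minority rows are cycled in
index order, one synthetic point each, until the requested count is reached,
so the output is deterministic given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SmoteConfig:
    """K nearest neighbours, balancing target and skip rule.

    `target_ratio` is the minority size to reach as a fraction of the
    majority size (1.0 = fully balanced).  When the majority/minority ratio
    is already below `skip_threshold` the data are left untouched, mirroring
    the treatment of nearly balanced classes.
    """

    k_neighbors: int = 5
    target_ratio: float = 1.0
    seed: int = 0
    skip_threshold: float = 1.5

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if not (0 < self.target_ratio <= 1.0):
            raise ValueError("target_ratio must be in (0, 1]")


class SmoteDraw(NamedTuple):
    """Audit record of one synthetic point: base row, neighbour row, u."""

    x_index: int
    nn_index: int
    u: float


def smote_oversample(
    X_min: pd.DataFrame | np.ndarray,
    n_new: int,
    cfg: SmoteConfig,
    rng: np.random.Generator | None = None,
    audit: list[SmoteDraw] | None = None,
) -> np.ndarray:
    """Generate `n_new` synthetic rows from the minority matrix.

    Neighbour search runs among minority rows only (Euclidean distance, ties
    broken by row index).  Pass `audit` to collect (x, nn, u) triples for an
    exact replay of every synthetic point.
    """
    arr = np.asarray(X_min, dtype=float)
    n_min = arr.shape[0]
    if n_min <= cfg.k_neighbors:
        raise ValueError(
            f"minority class has {n_min} rows but k_neighbors={cfg.k_neighbors}; "
            "lower K below the minority size"
        )
    if n_new < 0:
        raise ValueError("n_new must be >= 0")
    if n_new == 0:
        return np.empty((0, arr.shape[1]))
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    # K nearest minority neighbours of each minority row (self excluded);
    # argsort is stable, so equal distances resolve by row index.
    dist = cdist(arr, arr)
    np.fill_diagonal(dist, np.inf)
    neighbours = np.argsort(dist, axis=1, kind="stable")[:, : cfg.k_neighbors]

    out = np.empty((n_new, arr.shape[1]))
    for t in range(n_new):
        i = t % n_min  # cycle minority rows in index order
        nn = int(neighbours[i, rng.integers(cfg.k_neighbors)])
        u = float(rng.random())
        out[t] = arr[i] + u * (arr[nn] - arr[i])
        if audit is not None:
            audit.append(SmoteDraw(x_index=i, nn_index=nn, u=u))
    return out


def balance(
    X: pd.DataFrame,
    y: np.ndarray,
    cfg: SmoteConfig,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Balance a binary training set by SMOTE-augmenting the minority class.

    Original rows are always retained unmodified; synthetic rows are appended
    with ids `smote_0`, `smote_1`, ...  Returns (X, y) unchanged when the
    imbalance ratio is below the skip threshold.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("balance() needs both classes present")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_maj / n_min < cfg.skip_threshold:
        logger.info(
            "imbalance ratio %.2f below threshold %.2f: SMOTE skipped",
            n_maj / n_min, cfg.skip_threshold,
        )
        return X, y
    n_new = int(round(cfg.target_ratio * n_maj)) - n_min
    if n_new <= 0:
        return X, y
    X_min = X[y == minority]
    synth = smote_oversample(X_min, n_new, cfg)
    synth_df = pd.DataFrame(
        synth,
        columns=X.columns,
        index=pd.Index([f"smote_{i}" for i in range(n_new)], name=X.index.name),
    )
    X_out = pd.concat([X, synth_df])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
    return X_out, y_out
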