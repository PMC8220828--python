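"""Linear-regression baseline and the shuffled-track negative control.

The baseline consumes exactly the same per-bin N x 2 inputs as the network
(flattened to 2N columns) so method comparisons are on identical features.
The shuffled control permutes a feature's bin values genome-wide, which
destroys any spatial relationship with methylation while preserving the
value distribution; neighbor means must be recomputed after shuffling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .binning import FeatureTrack

__all__ = ["LinearModel", "fit_linear", "predict_linear", "shuffle_track"]


@dataclass
class LinearModel:
    """OLS fit on flattened inputs: one coefficient per (feature, column)."""

    coefficients: np.ndarray  # (2N,)
    intercept: float


def _flatten(matrix: np.ndarray) -> np.ndarray:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim == 3:
        return matrix.reshape(matrix.shape[0], -1)
    return matrix


def fit_linear(train_matrix: np.ndarray, train_targets: np.ndarray) -> LinearModel:
    """Ordinary least squares on the flattened N x 2 inputs.

    Rank-deficient designs fall back to the least-norm solution with a
    warning (``numpy.linalg.lstsq``). Deterministic.
    """
    X = _flatten(train_matrix)
    y = np.asarray(train_targets, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("matrix/target length mismatch")
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    design = np.column_stack([X, np.ones(X.shape[0])])
    solution, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        warnings.warn(
            f"rank-deficient design (rank {rank} < {design.shape[1]}); "
            "using least-norm solution",
            stacklevel=2,
        )
    return LinearModel(coefficients=solution[:-1], intercept=float(solution[-1]))


def predict_linear(model: LinearModel, matrix: np.ndarray) -> np.ndarray:
    X = _flatten(matrix)
    if X.shape[0] == 0:
        return np.empty(0)
    return X @ model.coefficients + model.intercept


def shuffle_track(track: FeatureTrack, seed: int) -> FeatureTrack:
    """Permute bin values genome-wide with a seeded uniform permutation."""
    rng = np.random.default_rng(seed)
    return FeatureTrack(track.feature_name, rng.permutation(track.values))
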