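"""Class rebalancing: SMOTE oversampling of cases plus random
undersampling of controls to a balanced design (default 300/300).

SMOTE synthesises new minority points on line segments between an
original minority point and one of its k nearest minority neighbours:
``x_new = x + u * (x_nn - x)`` with ``u ~ Uniform(0, 1)``. Every
synthetic point is therefore a convex combination of two original
minority points and never leaves the minority per-feature bounds.
Neighbours are found in standardised feature space (zero mean / unit
variance over the minority) so large-scale features such as the baseline
(~140 bpm) do not dominate the Euclidean metric over small-scale ones
such as sample entropy (~1); interpolation itself happens in the
original scale.

Caveat: rebalancing the full dataset *before* cross-validation (the
classical study design this package reproduces) leaks synthetic
neighbours of test points into training folds and optimistically biases
fold metrics. For unbiased estimates resample within training folds only
(see ``cross_validate(..., resampler=...)``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .dataset import LabelledDataset
from .records import ValidationError

__all__ = ["SmoteConfig", "smote_resample"]


@dataclass(frozen=True)
class SmoteConfig:
    k_neighbours: int = 5
    target_minority: int = 300
    target_majority: int = 300
    seed: int = 0

    def validate(self, n_minority: int) -> None:
        if self.k_neighbours < 1:
            raise ValidationError("k_neighbours must be >= 1")
        if self.k_neighbours >= n_minority:
            raise ValidationError(
                f"k_neighbours={self.k_neighbours} must be < minority size {n_minority}"
            )
        if self.target_minority < 1 or self.target_majority < 1:
            raise ValidationError("resampling targets must be >= 1")


def smote_resample(data: LabelledDataset, cfg: SmoteConfig | None = None) -> LabelledDataset:
    """Grow the minority (case) class to ``target_minority`` with SMOTE and
    randomly undersample the majority to ``target_majority``.

    Original minority points are always retained. The minority target is
    met exactly even when the required multiplication is non-integral:
    whole synthesis rounds cover the integer part and the remainder is
    filled from uniformly chosen minority seed points. Deterministic
    given ``cfg.seed``.
    """
    cfg = cfg or SmoteConfig()
    minority_idx = np.flatnonzero(data.labels == 1)
    majority_idx = np.flatnonzero(data.labels == 0)
    n_min = minority_idx.size
    if n_min < 2:
        raise ValidationError("need >= 2 minority records for SMOTE")
    cfg.validate(n_min)
    if cfg.target_minority < n_min:
        raise ValidationError(
            f"target_minority={cfg.target_minority} below minority size {n_min}"
        )
    if cfg.target_majority > majority_idx.size:
        raise ValidationError(
            f"target_majority={cfg.target_majority} exceeds majority size {majority_idx.size}"
        )
    rng = np.random.default_rng(cfg.seed)

    x_min = data.features[minority_idx]
    mu = x_min.mean(axis=0)
    sd = x_min.std(axis=0)
    sd[sd == 0.0] = 1.0
    z = (x_min - mu) / sd
    nn = NearestNeighbors(n_neighbors=cfg.k_neighbours + 1).fit(z)
    # column 0 is the point itself
    neighbour_idx = nn.kneighbors(z, return_distance=False)[:, 1:]

    n_new = cfg.target_minority - n_min
    rounds, remainder = divmod(n_new, n_min)
    seeds = np.concatenate(
        [np.tile(np.arange(n_min), rounds),
         rng.choice(n_min, size=remainder, replace=False)]
    ).astype(int)
    synthetic = np.empty((n_new, data.features.shape[1]))
    for out_row, i in enumerate(seeds):
        j = neighbour_idx[i, rng.integers(cfg.k_neighbours)]
        u = rng.uniform()
        synthetic[out_row] = x_min[i] + u * (x_min[j] - x_min[i])

    keep_majority = rng.choice(majority_idx, size=cfg.target_majority, replace=False)
    features = np.vstack([data.features[keep_majority], x_min, synthetic])
    labels = np.concatenate(
        [np.zeros(cfg.target_majority, int), np.ones(cfg.target_minority, int)]
    )
    ids = (
        [data.record_ids[i] for i in keep_majority]
        + [data.record_ids[i] for i in minority_idx]
        + [f"smote{i:04d}" for i in range(n_new)]
    )
    return LabelledDataset(features, labels, data.feature_names, tuple(ids))
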