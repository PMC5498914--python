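"""Recursive feature elimination (RFE) with cross-validated subset-size
profiling.

A random forest is fitted once on all features and features are ranked by
mean impurity-decrease importance; each candidate subset size keeps the
top-ranked features (single-pass, caret-style recursive drop, which
guarantees that the size-k set is contained in the size-(k+1) set), the
model is refitted and its cross-validated sensitivity/specificity/AUC
recorded. The chosen size maximises CV AUC, ties going to the smaller
subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import LabelledDataset
from .evaluation import CvConfig, cross_validate
from .models import rf_fit
from .records import ValidationError

__all__ = ["RfeResult", "rfe_select"]


@dataclass
class RfeResult:
    ranking: tuple                 # all feature names, most important first
    profile: list                  # per candidate size: dict(size, sensitivity, specificity, auc)
    best_size: int
    selected: tuple                # top best_size of ranking

    def profile_row(self, size: int) -> dict:
        for row in self.profile:
            if row["size"] == size:
                return row
        raise KeyError(size)


def rfe_select(
    data: LabelledDataset,
    sizes=None,
    estimator: str = "rf",
    folds: int = 5,
    seed: int = 0,
    n_trees: int = 500,
) -> RfeResult:
    """Rank features with RF importance and profile candidate subset sizes.

    ``sizes`` defaults to 1..n_features. Deterministic given ``seed``.
    """
    if estimator != "rf":
        raise ValidationError(f"unsupported ranking estimator {estimator!r}")
    if len(np.unique(data.labels)) < 2:
        raise ValidationError("both classes required for RFE")
    n_feat = data.features.shape[1]
    sizes = sorted(set(sizes)) if sizes is not None else list(range(1, n_feat + 1))
    if any(s < 1 or s > n_feat for s in sizes):
        raise ValidationError(f"candidate sizes must lie in [1, {n_feat}]")

    base = rf_fit(data, n_trees=n_trees, seed=seed)
    order = np.argsort(-base.feature_importances, kind="stable")
    ranking = tuple(data.feature_names[i] for i in order)

    profile = []
    for size in sizes:
        subset = data.subset_features(ranking[:size])
        report = cross_validate(
            subset, ("rf", {"n_trees": n_trees}), CvConfig(k_folds=folds, seed=seed)
        )
        profile.append(
            dict(
                size=size,
                sensitivity=report.sensitivity,
                specificity=report.specificity,
                auc=report.auc,
            )
        )
    # max AUC; ties -> smaller size (profile is sorted by size ascending)
    best = max(profile, key=lambda row: (row["auc"], -row["size"]))
    return RfeResult(
        ranking=ranking,
        profile=profile,
        best_size=int(best["size"]),
        selected=ranking[: int(best["size"])],
    )
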