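"""Feature-matrix container shared by resampling, selection, models and
evaluation. Labels are binary with case = positive (1), control = 0."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES
from .records import ValidationError

__all__ = ["LabelledDataset"]


@dataclass
class LabelledDataset:
    features: np.ndarray              # (n_records, n_features)
    labels: np.ndarray                # (n_records,), 0 = control, 1 = case
    feature_names: tuple = FEATURE_NAMES
    record_ids: tuple | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.ndim != 2:
            raise ValidationError("features must be a 2-D matrix")
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValidationError("features and labels disagree on record count")
        if self.features.shape[1] != len(self.feature_names):
            raise ValidationError("feature_names must match the feature columns")
        if not np.isfinite(self.features).all():
            raise ValidationError("features contain missing values")
        if not np.isin(self.labels, [0, 1]).all():
            raise ValidationError("labels must be binary 0/1")
        self.feature_names = tuple(self.feature_names)
        if self.record_ids is None:
            self.record_ids = tuple(f"r{i}" for i in range(self.labels.size))
        else:
            self.record_ids = tuple(self.record_ids)
            if len(self.record_ids) != self.labels.size:
                raise ValidationError("record_ids must match the record count")

    @property
    def n_cases(self) -> int:
        return int(np.sum(self.labels == 1))

    @property
    def n_controls(self) -> int:
        return int(np.sum(self.labels == 0))

    def subset_features(self, names) -> "LabelledDataset":
        """Restrict to the named feature columns (order preserved as given)."""
        idx = [self.feature_names.index(n) for n in names]
        return LabelledDataset(
            features=self.features[:, idx],
            labels=self.labels.copy(),
            feature_names=tuple(names),
            record_ids=self.record_ids,
        )

    def take(self, indices) -> "LabelledDataset":
        indices = np.asarray(indices, dtype=int)
        return LabelledDataset(
            features=self.features[indices],
            labels=self.labels[indices],
            feature_names=self.feature_names,
            record_ids=tuple(self.record_ids[i] for i in indices),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=list(self.feature_names))
        df.insert(0, "label", np.where(self.labels == 1, "case", "control"))
        df.insert(0, "record_id", list(self.record_ids))
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LabelledDataset":
        if "label" not in df.columns:
            raise ValidationError("feature table needs a 'label' column")
        names = [c for c in df.columns if c not in ("record_id", "label")]
        labels = (df["label"].astype(str) == "case").astype(int).to_numpy()
        ids = df["record_id"].astype(str).tolist() if "record_id" in df.columns else None
        return cls(df[names].to_numpy(dtype=float), labels, tuple(names), ids)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LabelledDataset":
        return cls.from_frame(pd.read_csv(path))
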