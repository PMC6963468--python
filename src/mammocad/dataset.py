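"""Tabular container for classification: feature matrix + binary labels.

Label convention: abnormal (lesion present) is the positive class 1,
normal is 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, SchemaError


@dataclass
class LabeledDataset:
    X: np.ndarray
    y: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or self.X.shape[1] < 1:
            raise SchemaError("X must be an n x d matrix with d >= 1")
        if self.y.shape != (self.X.shape[0],):
            raise SchemaError("y length must match the number of rows of X")
        if np.isnan(self.X).any():
            raise SchemaError("missing values are not allowed")
        if not np.isin(self.y, (0, 1)).all():
            raise SchemaError("labels must be binary {0, 1}")
        if not self.feature_names:
            self.feature_names = [f"f{i}" for i in range(self.X.shape[1])]
        if len(self.feature_names) != self.X.shape[1]:
            raise SchemaError("feature_names length must equal d")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    def restrict(self, subset) -> "LabeledDataset":
        """Column-restricted copy keeping the canonical feature order."""
        names = [n for n in self.feature_names if n in set(subset)]
        if not names:
            raise ParameterError("subset must name at least one feature")
        idx = [self.feature_names.index(n) for n in names]
        return LabeledDataset(X=self.X[:, idx], y=self.y.copy(), feature_names=names)

    @classmethod
    def from_dataframe(cls, df, label_col: str = "label") -> "LabeledDataset":
        names = [c for c in df.columns if c != label_col]
        labels = df[label_col]
        if labels.dtype == object:
            labels = (labels.astype(str) == "abnormal").astype(int)
        return cls(X=df[names].to_numpy(float), y=labels.to_numpy(int), feature_names=names)
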