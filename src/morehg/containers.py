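"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class OmicsMatrix:
    """One omics modality as a samples x features numeric table.

    Rows are samples, columns are features. ``values`` is always a float64
    array; missing entries are NaN. ``sample_ids`` and ``feature_ids`` are
    ordered and unique.
    """

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    modality: str = "omics"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x features array")
        if self.values.shape[0] != len(self.sample_ids):
            raise ValueError(
                f"{self.values.shape[0]} rows but {len(self.sample_ids)} sample ids"
            )
        if self.values.shape[1] != len(self.feature_ids):
            raise ValueError(
                f"{self.values.shape[1]} columns but {len(self.feature_ids)} feature ids"
            )
        for name, ids in (("sample", self.sample_ids), ("feature", self.feature_ids)):
            if len(set(ids)) != len(ids):
                seen: set[str] = set()
                dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
                raise ValueError(f"duplicate {name} id: {dup!r}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select_features(self, column_indices: np.ndarray) -> "OmicsMatrix":
        """New matrix keeping the given feature columns (order preserved)."""
        idx = np.asarray(column_indices, dtype=int)
        return replace(
            self,
            values=self.values[:, idx],
            feature_ids=[self.feature_ids[i] for i in idx],
        )

    def select_samples(self, row_indices: np.ndarray) -> "OmicsMatrix":
        idx = np.asarray(row_indices, dtype=int)
        return replace(
            self,
            values=self.values[idx, :],
            sample_ids=[self.sample_ids[i] for i in idx],
        )


@dataclass
class GroundTruth:
    """Planted structure of a synthetic dataset.

    ``labels`` holds one class index per sample; ``signal_feature_ids`` maps
    each modality name to the feature ids that carry the class signal;
    ``missing_feature_ids`` maps each modality to the all-NaN columns.
    """

    labels: np.ndarray
    signal_feature_ids: dict[str, list[str]]
    missing_feature_ids: dict[str, list[str]] = field(default_factory=dict)
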