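"""Core containers for multi-omics sample x feature data.

All matrices are oriented samples x features. Missing cells are stored as
NaN inside :class:`OmicsMatrix`; the aligned :class:`MaskMatrix` carries the
observedness indicator (1 = observed, 0 = missing) used by the adversarial
imputer. Layer kinds distinguish the three heterogeneous data types handled
here: non-negative continuous (mRNA-like abundance), unit-interval
continuous (methylation beta values), and ternary copy-number calls
{-1, 0, +1}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Valid layer-kind tags.
CONTINUOUS_NONNEG = "continuous_nonneg"
CONTINUOUS_UNIT = "continuous_unit"
TERNARY = "ternary"
LAYER_KINDS = (CONTINUOUS_NONNEG, CONTINUOUS_UNIT, TERNARY)

_TERNARY_VALUES = (-1.0, 0.0, 1.0)


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} ID: {i!r}")
        seen.add(i)
    return ids


@dataclass
class OmicsMatrix:
    """One omics layer: samples in rows, features in columns, NaN = missing."""

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    layer_kind: str
    name: str = ""

    def __post_init__(self) -> None:
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.feature_ids = _check_unique(self.feature_ids, "feature")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if self.layer_kind not in LAYER_KINDS:
            raise ValueError(f"unknown layer_kind {self.layer_kind!r}")
        if self.layer_kind == TERNARY:
            observed = self.values[~np.isnan(self.values)]
            bad = observed[~np.isin(observed, _TERNARY_VALUES)]
            if bad.size:
                raise ValueError(
                    f"ternary layer {self.name!r} contains non-ternary value {bad[0]!r}"
                )

    # -- basic views -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def mask(self) -> "MaskMatrix":
        """Observedness indicator aligned to this matrix (1 = observed)."""
        return MaskMatrix((~np.isnan(self.values)).astype(float))

    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.feature_ids
        )

    def select_samples(self, idx: Sequence[int]) -> "OmicsMatrix":
        idx = list(idx)
        return OmicsMatrix(
            [self.sample_ids[i] for i in idx],
            list(self.feature_ids),
            self.values[idx, :].copy(),
            self.layer_kind,
            self.name,
        )

    def select_features(self, feature_ids: Sequence[str]) -> "OmicsMatrix":
        pos = {f: j for j, f in enumerate(self.feature_ids)}
        cols = [pos[f] for f in feature_ids]
        return OmicsMatrix(
            list(self.sample_ids),
            [self.feature_ids[j] for j in cols],
            self.values[:, cols].copy(),
            self.layer_kind,
            self.name,
        )

    def copy(self) -> "OmicsMatrix":
        return OmicsMatrix(
            list(self.sample_ids),
            list(self.feature_ids),
            self.values.copy(),
            self.layer_kind,
            self.name,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OmicsMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.feature_ids == other.feature_ids
            and self.layer_kind == other.layer_kind
            and np.array_equal(self.values, other.values, equal_nan=True)
        )


@dataclass
class MaskMatrix:
    """Binary observedness matrix: 1 = observed, 0 = missing."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("mask cells must be 0 or 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def check_aligned(self, m: OmicsMatrix) -> None:
        if self.values.shape != m.values.shape:
            raise ValueError(
                f"mask shape {self.values.shape} != matrix shape {m.values.shape}"
            )
        # the mask may hide extra (held-out) cells, but every NaN must be masked
        missing = np.isnan(m.values)
        if np.any(missing & (self.values == 1)):
            raise ValueError("mask marks a missing (NaN) cell as observed")


@dataclass
class OmicsBundle:
    """Ordered collection of layers sharing one sample ordering."""

    layers: list[OmicsMatrix]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("bundle needs at least one layer")
        ref = self.layers[0].sample_ids
        for m in self.layers[1:]:
            if m.sample_ids != ref:
                raise ValueError(
                    f"layer {m.name!r} sample ordering differs from {self.layers[0].name!r}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return self.layers[0].sample_ids

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.layers]

    def __iter__(self):
        return iter(self.layers)

    def __len__(self) -> int:
        return len(self.layers)

    def __getitem__(self, key) -> OmicsMatrix:
        if isinstance(key, str):
            for m in self.layers:
                if m.name == key:
                    return m
            raise KeyError(key)
        return self.layers[key]

    def arrays(self) -> list[np.ndarray]:
        return [m.values for m in self.layers]

    def concatenated(self) -> np.ndarray:
        return np.concatenate([m.values for m in self.layers], axis=1)

    def select_samples(self, idx: Sequence[int]) -> "OmicsBundle":
        return OmicsBundle([m.select_samples(idx) for m in self.layers])


@dataclass
class LabelVector:
    """Binary per-sample class labels aligned to a bundle's sample order."""

    sample_ids: list[str]
    labels: np.ndarray
    label_names: dict[int, str] = field(default_factory=lambda: {0: "0", 1: "1"})

    def __post_init__(self) -> None:
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.sample_ids),):
            raise ValueError("labels length must match sample_ids")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def select(self, idx: Sequence[int]) -> "LabelVector":
        idx = list(idx)
        return LabelVector(
            [self.sample_ids[i] for i in idx],
            self.labels[idx].copy(),
            dict(self.label_names),
        )


@dataclass
class RunConfig:
    """Flat run configuration covering the full pipeline.

    Numeric invariants are validated on construction; the grid lists must be
    non-empty. Defaults mirror the pipeline defaults documented in
    docs/methods.md.
    """

    matrix_paths: dict[str, str] = field(default_factory=dict)
    layer_kinds: dict[str, str] = field(default_factory=dict)
    labels_path: str = ""
    max_missing_rate: float = 1.0 - 1e-9
    rfs_B: int = 10
    rfs_k: int = 2000
    rfs_m: int = 1000
    gain_iterations: int = 2000
    gain_batch_size: int = 128
    gain_hint_rate: float = 0.9
    gain_alpha: float = 10.0
    cv_folds: int = 5
    epochs: int = 50
    seed: int = 0
    grid: dict[str, list] = field(
        default_factory=lambda: {
            "learn_rate": [0.001, 0.01],
            "batch_size": [32, 64, 128],
            "num_heads": [2, 4, 8],
            "num_blocks": [1, 2, 3],
            "dropout_rate": [0.01, 0.1],
            "dense_dim": [32, 64, 128],
        }
    )

    def __post_init__(self) -> None:
        for name in (
            "max_missing_rate", "rfs_B", "rfs_k", "rfs_m", "gain_iterations",
            "gain_batch_size", "gain_hint_rate", "gain_alpha", "cv_folds",
            "epochs",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for key, vals in self.grid.items():
            if not vals:
                raise ValueError(f"grid entry {key!r} is empty")
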