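"""Preprocessing chain for heterogeneous omics layers.

Order used by the pipeline: drop (near-)all-missing features, min-max scale
the continuous layers, ternary-code the copy-number layer, then feature
selection and imputation downstream. Survival times are dichotomized at the
nearest integer to the median; samples strictly above the threshold are the
long-term survivors (LTS, label 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import TERNARY, LabelVector, MaskMatrix, OmicsBundle, OmicsMatrix

#: default keeps only features missing in (essentially) every sample
DEFAULT_MAX_MISSING_RATE = 1.0 - 1e-9


@dataclass
class ScalerParams:
    """Per-feature min/max learned on a training partition."""

    feature_ids: list[str]
    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self) -> None:
        self.mins = np.asarray(self.mins, dtype=float)
        self.maxs = np.asarray(self.maxs, dtype=float)
        if np.any(self.maxs < self.mins):
            raise ValueError("per-feature max must be >= min")


def filter_missing_features(
    m: OmicsMatrix,
    mask: MaskMatrix | None = None,
    max_missing_rate: float = DEFAULT_MAX_MISSING_RATE,
) -> OmicsMatrix:
    """Drop features whose missing fraction exceeds ``max_missing_rate``.

    The default threshold removes only fully missing features. Feature order
    is preserved. Raises if nothing survives.
    """
    if mask is None:
        mask = m.mask()
    mask.check_aligned(m)
    miss_frac = 1.0 - mask.values.mean(axis=0)
    keep = miss_frac <= max_missing_rate
    if not keep.any():
        raise ValueError("all features exceed the missing-rate threshold")
    kept_ids = [f for f, k in zip(m.feature_ids, keep) if k]
    return m.select_features(kept_ids)


def fit_minmax(m: OmicsMatrix, rows: np.ndarray | list[int] | None = None) -> ScalerParams:
    """Learn per-feature min/max from observed cells of the given rows."""
    rows = np.arange(m.n_samples) if rows is None else np.asarray(rows, dtype=int)
    if rows.size == 0:
        raise ValueError("empty training set")
    sub = m.values[rows, :]
    with np.errstate(all="ignore"):
        mins = np.nanmin(sub, axis=0)
        maxs = np.nanmax(sub, axis=0)
    # features unobserved in the training rows: neutral [0, 0] params
    allnan = np.isnan(mins)
    mins[allnan] = 0.0
    maxs[allnan] = 0.0
    return ScalerParams(list(m.feature_ids), mins, maxs)


def apply_minmax(m: OmicsMatrix, p: ScalerParams) -> OmicsMatrix:
    """Map observed cells into [0, 1]; constant features map to 0.

    Cells outside the training range (held-out data) are clipped to [0, 1].
    Missing cells stay missing. The output layer kind becomes unit-interval
    continuous.
    """
    if p.feature_ids != m.feature_ids:
        raise ValueError("scaler was fit on different features")
    span = p.maxs - p.mins
    safe = np.where(span > 0, span, 1.0)
    vals = (m.values - p.mins) / safe
    vals = np.where(span > 0, vals, 0.0)
    missing = np.isnan(m.values)
    vals = np.clip(vals, 0.0, 1.0)
    vals[missing] = np.nan
    from .datamodel import CONTINUOUS_UNIT

    return OmicsMatrix(list(m.sample_ids), list(m.feature_ids), vals, CONTINUOUS_UNIT, m.name)


def encode_cnv(m: OmicsMatrix) -> OmicsMatrix:
    """Ternary-code a copy-number layer by sign: loss -1, neutral 0, gain +1."""
    if m.has_missing():
        raise ValueError("copy-number layer must be complete before encoding")
    vals = np.sign(m.values)
    return OmicsMatrix(list(m.sample_ids), list(m.feature_ids), vals, TERNARY, m.name)


def dichotomize_survival(
    times: np.ndarray | list[float],
    sample_ids: list[str] | None = None,
) -> tuple[LabelVector, int]:
    """Split survival times at the nearest integer to the median.

    Threshold = round-half-to-even of the median; label 1 ("LTS", long-term
    survivor) iff time strictly exceeds the threshold, else 0.
    """
    times = np.asarray(times, dtype=float)
    if times.size < 2:
        raise ValueError("need at least two survival times")
    if np.any(times <= 0) or np.any(~np.isfinite(times)):
        raise ValueError("survival times must be positive and finite")
    threshold = int(np.round(np.median(times)))
    labels = (times > threshold).astype(int)
    if sample_ids is None:
        sample_ids = [f"S{i:04d}" for i in range(times.size)]
    return LabelVector(sample_ids, labels, {0: "non-LTS", 1: "LTS"}), threshold


def heterogeneity_summary(b: OmicsBundle, n_bins: int = 20) -> pd.DataFrame:
    """Per-feature mean, coefficient of variation and Shannon entropy.

    Entropy (bits) is computed on an ``n_bins``-bin histogram of each
    feature's values over its own range; a constant feature has entropy 0
    and CV 0. Requires complete (imputed) layers.
    """
    rows = []
    for m in b:
        if m.has_missing():
            raise ValueError(f"layer {m.name!r} has missing cells; impute first")
        means = m.values.mean(axis=0)
        sds = m.values.std(axis=0, ddof=1) if m.n_samples > 1 else np.zeros(m.n_features)
        for j, fid in enumerate(m.feature_ids):
            col = m.values[:, j]
            mean, sd = means[j], sds[j]
            cv = 0.0 if sd == 0 else (sd / abs(mean) if mean != 0 else np.inf)
            if col.max() == col.min():
                entropy = 0.0
            else:
                counts, _ = np.histogram(col, bins=n_bins)
                pk = counts[counts > 0] / counts.sum()
                entropy = float(-(pk * np.log2(pk)).sum())
            rows.append(
                {"layer": m.name, "feature": fid, "mean": mean, "cv": cv, "entropy": entropy}
            )
    return pd.DataFrame(rows)
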