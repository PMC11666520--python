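"""Bootstrap-stability ("robust") feature selection.

A plain variance filter is sensitive to outlying samples: one aberrant
measurement can push a noisy feature into the selected set. Here the
variance top-k filter is instead applied to B bootstrap resamples of the
samples and the final set of m features is chosen by how often each feature
made the per-resample top-k, so only features whose high variance is stable
under resampling survive. Selection runs per omics layer independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import OmicsMatrix


@dataclass
class RFSConfig:
    """B resamples, k features kept per resample, m finally selected."""

    B: int = 10
    k: int = 2000
    m: int = 1000
    seed: int = 0

    def resolve(self, n_features: int) -> "RFSConfig":
        """Clamp k and m to the actual feature count."""
        k = min(self.k, n_features)
        return RFSConfig(self.B, k, min(self.m, k), self.seed)

    def validate(self, n_features: int) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not (1 <= self.m <= self.k <= n_features):
            raise ValueError(f"need 1 <= m <= k <= n_features, got m={self.m}, k={self.k}, p={n_features}")


@dataclass
class RFSResult:
    """Selection counts, mean variance ranks, and the final feature list.

    ``selected`` is ordered by (count desc, mean variance rank asc, feature
    ID asc) — the full deterministic tie-breaking chain.
    """

    counts: pd.Series
    mean_rank: pd.Series
    selected: list[str]

    def table(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "feature": self.counts.index.astype(str),
                "count": self.counts.to_numpy(),
                "mean_variance_rank": self.mean_rank.to_numpy(),
            }
        )
        return df.sort_values(
            by=["count", "mean_variance_rank", "feature"],
            ascending=[False, True, True],
            kind="mergesort",
        ).reset_index(drop=True)


def bootstrap_indices(n: int, B: int, seed: int) -> np.ndarray:
    """B bootstrap index vectors of length n (sampling with replacement)."""
    if n < 1 or B < 1:
        raise ValueError("n and B must be positive")
    rng = np.random.default_rng(seed)
    return rng.integers(0, n, size=(B, n))


def _observed_variances(values: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Unbiased per-feature variance over observed cells of the given rows.

    Features with fewer than two observed values get variance 0.
    """
    import warnings

    sub = values[rows, :]
    n_obs = (~np.isnan(sub)).sum(axis=0)
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        var = np.nanvar(sub, axis=0, ddof=1)
    var = np.where(n_obs >= 2, var, 0.0)
    return np.nan_to_num(var, nan=0.0)


def variance_topk(m: OmicsMatrix, rows: np.ndarray, k: int) -> list[str]:
    """IDs of the k features with largest variance on the resampled rows.

    Ties break by feature ID (ascending); missing cells are excluded from
    each feature's variance rather than treated as zeros.
    """
    if k > m.n_features:
        raise ValueError("k exceeds the number of features")
    var = _observed_variances(m.values, np.asarray(rows, dtype=int))
    order = _variance_order(var, m.feature_ids)
    return [m.feature_ids[j] for j in order[:k]]


def _variance_order(var: np.ndarray, feature_ids: list[str]) -> np.ndarray:
    """Column order by variance descending, ties by feature ID ascending."""
    ids = np.asarray(feature_ids, dtype=object)
    # np.lexsort: last key is primary
    return np.lexsort((ids, -var))


def select_robust_features(m: OmicsMatrix, cfg: RFSConfig) -> RFSResult:
    """Run the full bootstrap-stability selection on one layer."""
    cfg = cfg.resolve(m.n_features)
    cfg.validate(m.n_features)
    idx = bootstrap_indices(m.n_samples, cfg.B, cfg.seed)
    counts = np.zeros(m.n_features, dtype=int)
    rank_sum = np.zeros(m.n_features, dtype=float)
    pos = {f: j for j, f in enumerate(m.feature_ids)}
    for b in range(cfg.B):
        var = _observed_variances(m.values, idx[b])
        order = _variance_order(var, m.feature_ids)
        ranks = np.empty(m.n_features)
        ranks[order] = np.arange(1, m.n_features + 1)
        rank_sum += ranks
        for f in (m.feature_ids[j] for j in order[: cfg.k]):
            counts[pos[f]] += 1
    mean_rank = rank_sum / cfg.B
    order = sorted(
        range(m.n_features),
        key=lambda j: (-counts[j], mean_rank[j], str(m.feature_ids[j])),
    )
    selected = [m.feature_ids[j] for j in order[: cfg.m]]
    counts_s = pd.Series(counts, index=m.feature_ids, name="count")
    rank_s = pd.Series(mean_rank, index=m.feature_ids, name="mean_variance_rank")
    return RFSResult(counts_s, rank_s, selected)
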