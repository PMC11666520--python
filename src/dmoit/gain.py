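"""Generative-adversarial imputation of continuous omics layers.

The generator receives the observed matrix with missing cells filled by
small uniform noise, together with the observedness mask, and proposes a
completed matrix. The discriminator receives the composited matrix plus a
hint matrix (a ``hint_rate`` fraction of the true mask revealed, 0.5
elsewhere) and predicts per-cell observedness. The generator is trained
with an adversarial term on missing cells plus ``alpha`` times the
reconstruction error on observed cells. Only the missing cells of the
original data are ever replaced; observed cells pass through bit-identical.

Also provides the zero / mean / median / KNN baseline imputers used for
benchmarking, and an RMSE scorer over held-out cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._autograd import Tensor
from .datamodel import TERNARY, MaskMatrix, OmicsMatrix
from .nn import Adam, Linear, Module

BASELINE_METHODS = ("zero", "mean", "median", "knn")


@dataclass
class GainConfig:
    """Training hyperparameters; hidden widths default to the feature count."""

    hidden: tuple[int, int] | None = None
    hint_rate: float = 0.9
    alpha: float = 100.0
    batch_size: int = 128
    n_iterations: int = 2000
    learn_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.hint_rate <= 1:
            raise ValueError("hint_rate must lie in (0, 1]")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.batch_size < 1 or self.n_iterations < 1:
            raise ValueError("batch_size and n_iterations must be positive")


class _CellNet(Module):
    """Two-hidden-layer fully connected net mapping (n, 2p) -> (n, p)."""

    def __init__(self, p: int, hidden: tuple[int, int], rng: np.random.Generator):
        self.fc1 = Linear(2 * p, hidden[0], rng)
        self.fc2 = Linear(hidden[0], hidden[1], rng)
        self.fc3 = Linear(hidden[1], p, rng)

    def logits(self, x: Tensor) -> Tensor:
        return self.fc3(self.fc2(self.fc1(x).relu()).relu())

    def __call__(self, x: Tensor) -> Tensor:
        return self.logits(x).sigmoid()


@dataclass
class GainModel:
    """Trained generator/discriminator pair plus the training-loss trace."""

    generator: _CellNet
    discriminator: _CellNet
    cfg: GainConfig
    feature_ids: list[str]
    loss_trace: dict[str, list[float]] = field(default_factory=dict)


def _check_continuous_unit(m: OmicsMatrix) -> None:
    if m.layer_kind == TERNARY:
        raise ValueError("ternary (copy-number) layers are never imputed")
    observed = m.values[~np.isnan(m.values)]
    if observed.size and (observed.min() < -1e-9 or observed.max() > 1 + 1e-9):
        raise ValueError("layer must be min-max scaled to [0, 1] before GAIN")


def train_gain(m: OmicsMatrix, mask: MaskMatrix, cfg: GainConfig) -> GainModel:
    """Adversarial training on one scaled continuous layer.

    Deterministic given ``cfg.seed``. Raises if the mask is all-zero or a
    loss becomes non-finite (reporting the iteration index).
    """
    _check_continuous_unit(m)
    mask.check_aligned(m)
    mk = mask.values
    if mk.sum() == 0:
        raise ValueError("mask is all-zero: no observed cells to learn from")
    n, p = m.shape
    hidden = cfg.hidden or (p, p)
    rng = np.random.default_rng(cfg.seed)
    G = _CellNet(p, hidden, rng)
    D = _CellNet(p, hidden, rng)
    opt_g = Adam(G.parameters(), lr=cfg.learn_rate)
    opt_d = Adam(D.parameters(), lr=cfg.learn_rate)

    x_full = np.nan_to_num(m.values, nan=0.0)
    trace: dict[str, list[float]] = {"d_loss": [], "g_adv": [], "g_rec": []}
    eps = 1e-8
    batch = min(cfg.batch_size, n)

    for it in range(cfg.n_iterations):
        idx = rng.choice(n, size=batch, replace=False)
        xb = x_full[idx]
        mb = mk[idx]
        z = rng.uniform(0, 0.01, size=xb.shape)
        x_tilde = mb * xb + (1 - mb) * z
        reveal = (rng.random(xb.shape) < cfg.hint_rate).astype(float)
        hint = reveal * mb + 0.5 * (1 - reveal)

        mb_t = Tensor(mb)
        xb_t = Tensor(xb)
        g_in = Tensor(np.concatenate([x_tilde, mb], axis=1))
        sample = G(g_in)
        x_hat = mb_t * xb_t + (1 - mb_t) * sample

        # --- discriminator step (generator output detached) ---
        from ._autograd import concat as _concat

        d_in = _concat([x_hat.detach(), Tensor(hint)], axis=1)
        d_logits = D.logits(d_in)
        d_loss = (mb_t * (-d_logits).softplus() + (1 - mb_t) * d_logits.softplus()).mean()
        opt_d.zero_grad()
        d_loss.backward()
        opt_d.step()

        # --- generator step ---
        d_in_g = _concat([x_hat, Tensor(hint)], axis=1)
        d_logits_g = D.logits(d_in_g)
        n_missing = float((1 - mb).sum())
        n_observed = float(mb.sum())
        g_adv = ((1 - mb_t) * (-d_logits_g).softplus()).sum() / (n_missing + eps)
        diff = xb_t - sample
        g_rec = (mb_t * diff * diff).sum() / (n_observed + eps)
        g_loss = g_adv + cfg.alpha * g_rec
        opt_g.zero_grad()
        opt_d.zero_grad()  # discard D grads accumulated through the G pass
        g_loss.backward()
        opt_g.step()

        vals = (float(d_loss.data), float(g_adv.data), float(g_rec.data))
        if not all(np.isfinite(v) for v in vals):
            raise RuntimeError(f"non-finite loss at iteration {it}")
        trace["d_loss"].append(vals[0])
        trace["g_adv"].append(vals[1])
        trace["g_rec"].append(vals[2])

    return GainModel(G, D, cfg, list(m.feature_ids), trace)


def impute_gain(model: GainModel, m: OmicsMatrix, mask: MaskMatrix) -> OmicsMatrix:
    """Composite the generator's proposal into the missing cells only.

    ``output = mask * original + (1 - mask) * generated``; observed cells
    are bit-identical to the input and the output is complete.
    """
    if list(m.feature_ids) != model.feature_ids:
        raise ValueError("matrix features do not match the trained model")
    mask.check_aligned(m)
    mk = mask.values
    x_full = np.nan_to_num(m.values, nan=0.0)
    rng = np.random.default_rng(model.cfg.seed + 1)
    z = rng.uniform(0, 0.01, size=x_full.shape)
    x_tilde = mk * x_full + (1 - mk) * z
    model.generator.eval()
    sample = model.generator(Tensor(np.concatenate([x_tilde, mk], axis=1))).data
    out_vals = np.where(mk == 1, m.values, sample)
    return OmicsMatrix(
        list(m.sample_ids), list(m.feature_ids), out_vals, m.layer_kind, m.name
    )


def impute_baseline(
    m: OmicsMatrix,
    mask: MaskMatrix | None = None,
    method: str = "mean",
    knn_k: int = 5,
) -> OmicsMatrix:
    """Zero / column-mean / column-median / KNN imputation.

    KNN averages the ``knn_k`` nearest samples by Euclidean distance over
    mutually observed features. A fully missing column is filled with 0
    (with a warning) since its mean/median is undefined.
    """
    if m.layer_kind == TERNARY:
        raise ValueError("ternary (copy-number) layers are never imputed")
    if method not in BASELINE_METHODS:
        raise ValueError(f"unknown imputation method {method!r}")
    if mask is None:
        mask = m.mask()
    mask.check_aligned(m)
    vals = m.values.copy()
    vals[mask.values == 0] = np.nan
    missing = np.isnan(vals)
    all_missing_cols = missing.all(axis=0)
    if all_missing_cols.any():
        warnings.warn(
            f"{int(all_missing_cols.sum())} fully missing column(s) filled with 0",
            stacklevel=2,
        )
    if method == "zero":
        filled = np.where(missing, 0.0, vals)
    elif method in ("mean", "median"):
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            stat = np.nanmean(vals, axis=0) if method == "mean" else np.nanmedian(vals, axis=0)
        stat = np.nan_to_num(stat, nan=0.0)
        filled = np.where(missing, stat, vals)
    else:  # knn
        from sklearn.impute import KNNImputer

        imputer = KNNImputer(n_neighbors=knn_k, keep_empty_features=True)
        filled = imputer.fit_transform(vals)
        if filled.shape != vals.shape:  # pragma: no cover - guarded by keep_empty
            raise RuntimeError("KNN imputer dropped columns")
    out = np.where(mask.values == 1, m.values, filled)
    return OmicsMatrix(list(m.sample_ids), list(m.feature_ids), out, m.layer_kind, m.name)


def score_imputation(
    imputed: OmicsMatrix, truth: OmicsMatrix, mask: MaskMatrix
) -> float:
    """RMSE over held-out (mask = 0) cells only."""
    if imputed.shape != truth.shape or mask.shape != truth.shape:
        raise ValueError("shapes of imputed, truth and mask must match")
    held_out = mask.values == 0
    if not held_out.any():
        raise ValueError("mask is all-ones: nothing to score")
    diff = imputed.values[held_out] - truth.values[held_out]
    return float(np.sqrt(np.mean(diff**2)))
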