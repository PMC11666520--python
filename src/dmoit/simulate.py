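"""Synthetic three-layer multi-omics bundles with planted class signal.

The generator emulates the heterogeneity of a transcriptomic / methylation /
copy-number triplet measured on the same samples:

* an abundance-like layer: non-negative continuous, log-normal marginals;
* a methylation-like layer: [0,1] continuous, Beta marginals via a Gaussian
  copula;
* a copy-number-like layer: ternary {-1, 0, +1}, obtained by thresholding a
  latent Gaussian.

Class structure is planted on the *latent* standardized features by
Gaussian class-conditional generation, which induces an exactly logistic
posterior P(y | z): each informative column is shifted by ``beta_intra``
(in within-class SD units) between the two classes — equivalently, a
logistic model with coefficient ``beta_intra`` per informative feature —
and a fixed set of cross-layer pairs of informative features receives a
common component whose sign flips with the class, so the pair's
correlation is +rho in one class and -rho in the other. That makes the
cross-layer *product* predictive (a product term in the implied logit)
while leaving each member's marginal distribution unchanged: signal a
per-layer encoder cannot see but a shared encoder can. Labels are drawn
first, Bernoulli(``class_balance``). Observed values are monotone
transforms of a noisy copy of the latents, so the planted signal survives
the marginal transforms but is attenuated by observation noise.

Missingness is MCAR and confined to the two continuous layers; the ternary
layer is always generated complete, matching how copy-number calls arrive
without gaps in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datamodel import (
    CONTINUOUS_NONNEG,
    CONTINUOUS_UNIT,
    TERNARY,
    LabelVector,
    MaskMatrix,
    OmicsBundle,
    OmicsMatrix,
)

LAYER_NAMES = ("mRNA", "MET", "CNV")
_LAYER_KINDS = (CONTINUOUS_NONNEG, CONTINUOUS_UNIT, TERNARY)


@dataclass
class SimConfig:
    """Scenario parameters for the synthetic bundle generator.

    ``beta_intra`` is the per-informative-feature logistic coefficient on the
    standardized latent scale (so it doubles as the class-conditional mean
    shift in SD units, per coefficient); ``beta_inter`` multiplies each
    cross-layer product term in the logit.
    """

    n_samples: int = 400
    n_features: tuple[int, int, int] = (500, 400, 200)
    n_informative: tuple[int, int, int] = (20, 15, 10)
    beta_intra: float = 0.8
    beta_inter: float = 1.0
    class_balance: float = 0.5
    missing_rate: float = 0.15
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.class_balance < 1:
            raise ValueError("class_balance must lie in (0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        if len(self.n_features) != 3 or len(self.n_informative) != 3:
            raise ValueError("n_features and n_informative must have 3 entries")
        for p, k in zip(self.n_features, self.n_informative):
            if k > p:
                raise ValueError("n_informative cannot exceed n_features")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class SimTruth:
    """Ground truth of one generated scenario, for scoring and diagnostics."""

    informative: dict[str, list[str]]
    coefficients: dict[str, float]
    pairs: list[tuple[str, str]]
    masks: dict[str, np.ndarray]
    complete: dict[str, np.ndarray] = field(default_factory=dict)


def _feature_ids(layer: str, p: int) -> list[str]:
    return [f"{layer}_f{j:04d}" for j in range(p)]


def _latents(cfg: SimConfig):
    """Labels, latent standardized signals, informative sets and pairs.

    Labels come first (Bernoulli class balance); informative latent columns
    are shifted by ``beta_intra`` within-class SDs between classes; paired
    cross-layer informative features share a component whose sign flips
    with the class (strength set by ``beta_inter``).
    """
    rng = np.random.default_rng(cfg.seed)
    labels = rng.binomial(1, cfg.class_balance, size=cfg.n_samples)
    Z = [rng.standard_normal((cfg.n_samples, p)) for p in cfg.n_features]
    informative = [
        np.sort(rng.choice(p, size=k, replace=False))
        for p, k in zip(cfg.n_features, cfg.n_informative)
    ]
    # fixed cross-layer pairs: informative j of one layer with informative j
    # of another, for each unordered layer pair
    pairs: list[tuple[int, int, int, int]] = []
    for a, b in ((0, 1), (1, 2), (0, 2)):
        for ja, jb in zip(informative[a], informative[b]):
            pairs.append((a, int(ja), b, int(jb)))
    # intra-omics main effects: class-conditional mean shift
    centered = labels - cfg.class_balance
    for lz, inf in zip(Z, informative):
        lz[:, inf] += cfg.beta_intra * centered[:, None]
    # inter-omics interactions: class-sign-flipped shared component, so the
    # cross-layer product (not either marginal) carries the class signal
    delta = np.sqrt(cfg.beta_inter / 2.0) if cfg.beta_inter > 0 else 0.0
    if delta > 0:
        sign = 2.0 * labels - 1.0
        for a, ja, b, jb in pairs:
            w = rng.standard_normal(cfg.n_samples)
            Z[a][:, ja] += delta * w
            Z[b][:, jb] += delta * sign * w
    return rng, labels, Z, informative, pairs


def _risk_score(cfg: SimConfig, Z, informative, pairs) -> np.ndarray:
    """Discriminant-style risk score: main effects plus cross-layer products."""
    s = np.zeros(cfg.n_samples)
    for lz, inf in zip(Z, informative):
        s += cfg.beta_intra * lz[:, inf].sum(axis=1)
    for a, ja, b, jb in pairs:
        s += cfg.beta_inter * Z[a][:, ja] * Z[b][:, jb]
    return s


def generate_bundle(
    cfg: SimConfig,
) -> tuple[OmicsBundle, list[MaskMatrix], LabelVector, SimTruth]:
    """Generate a three-layer bundle, MCAR masks, labels and ground truth.

    Fully reproducible from ``cfg.seed``; the ternary layer is complete.
    """
    rng, labels, Z, informative, pairs = _latents(cfg)

    # observed latents: noisy copy, re-standardized
    denom = np.sqrt(1.0 + cfg.noise_sd**2)
    Zobs = [
        (lz + cfg.noise_sd * rng.standard_normal(lz.shape)) / denom for lz in Z
    ]

    sample_ids = [f"S{i:04d}" for i in range(cfg.n_samples)]
    layers: list[OmicsMatrix] = []
    masks: list[MaskMatrix] = []
    truth_masks: dict[str, np.ndarray] = {}
    complete: dict[str, np.ndarray] = {}
    informative_ids: dict[str, list[str]] = {}

    for li, (name, kind, p) in enumerate(zip(LAYER_NAMES, _LAYER_KINDS, cfg.n_features)):
        z = Zobs[li]
        if kind == CONTINUOUS_NONNEG:
            mu = rng.uniform(1.0, 3.0, size=p)
            sigma = rng.uniform(0.3, 0.8, size=p)
            vals = np.exp(mu + sigma * z)
        elif kind == CONTINUOUS_UNIT:
            a = rng.uniform(0.5, 3.0, size=p)
            b = rng.uniform(0.5, 3.0, size=p)
            vals = stats.beta.ppf(stats.norm.cdf(z), a, b)
        else:  # ternary: threshold the latent at per-feature +/- t
            t = rng.uniform(0.5, 1.5, size=p)
            vals = np.zeros_like(z)
            vals[z > t] = 1.0
            vals[z < -t] = -1.0
        complete[name] = vals.copy()

        mask = np.ones_like(vals)
        if kind != TERNARY and cfg.missing_rate > 0:
            mask = (rng.random(vals.shape) >= cfg.missing_rate).astype(float)
            vals = vals.copy()
            vals[mask == 0] = np.nan
        truth_masks[name] = mask.copy()
        fids = _feature_ids(name, p)
        informative_ids[name] = [fids[j] for j in informative[li]]
        layers.append(OmicsMatrix(sample_ids, fids, vals, kind, name))
        masks.append(MaskMatrix(mask))

    pair_ids = [
        (
            _feature_ids(LAYER_NAMES[a], cfg.n_features[a])[ja],
            _feature_ids(LAYER_NAMES[b], cfg.n_features[b])[jb],
        )
        for a, ja, b, jb in pairs
    ]
    truth = SimTruth(
        informative=informative_ids,
        coefficients={
            "beta_intra": cfg.beta_intra,
            "beta_inter": cfg.beta_inter,
        },
        pairs=pair_ids,
        masks=truth_masks,
        complete=complete,
    )
    bundle = OmicsBundle(layers)
    label_vec = LabelVector(sample_ids, labels, {0: "class0", 1: "class1"})
    return bundle, masks, label_vec, truth


def generate_survival_times(cfg: SimConfig, t_scale: float = 36.0) -> np.ndarray:
    """Log-normal survival-like times with risk tied to the planted signal.

    Times are strictly positive. With all effect sizes zero the times are
    independent of the features. The same ``cfg.seed`` reproduces the latent
    draw used by :func:`generate_bundle`, so times align sample-by-sample
    with a bundle generated from the same config.
    """
    rng, _, Z, informative, pairs = _latents(cfg)
    score = _risk_score(cfg, Z, informative, pairs)
    sd = score.std()
    risk = score / sd if sd > 0 else np.zeros_like(score)
    eps = rng.standard_normal(cfg.n_samples)
    return t_scale * np.exp(-0.8 * risk + 0.5 * eps)


def corrupt_with_missing(
    m: OmicsMatrix, rate: float, seed: int
) -> tuple[OmicsMatrix, MaskMatrix]:
    """Hide exactly ``round(rate * n_cells)`` cells uniformly at random.

    Intended for imputer benchmarking on complete continuous layers; the
    caller keeps the original matrix as ground truth for RMSE scoring.
    """
    if m.layer_kind == TERNARY:
        raise ValueError("corrupt_with_missing applies to continuous layers only")
    if not 0 <= rate < 1:
        raise ValueError("rate must lie in [0, 1)")
    n_cells = m.values.size
    n_hide = int(round(rate * n_cells))
    rng = np.random.default_rng(seed)
    flat = rng.choice(n_cells, size=n_hide, replace=False)
    mask = np.ones(n_cells)
    mask[flat] = 0.0
    mask = mask.reshape(m.values.shape)
    vals = m.values.copy()
    vals[mask == 0] = np.nan
    out = OmicsMatrix(list(m.sample_ids), list(m.feature_ids), vals, m.layer_kind, m.name)
    return out, MaskMatrix(mask)
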