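"""Shared fixtures: small matrices and the packaged toy classification task."""

from __future__ import annotations

import numpy as np
import pytest

from dmoit import (
    CONTINUOUS_UNIT,
    TERNARY,
    GridSpec,
    LabelVector,
    OmicsBundle,
    OmicsMatrix,
    run_cv,
)


def make_matrix(values, kind=CONTINUOUS_UNIT, name="layer", prefix="f"):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return OmicsMatrix(
        [f"S{i:03d}" for i in range(n)],
        [f"{prefix}{j:03d}" for j in range(p)],
        values,
        kind,
        name,
    )


@pytest.fixture
def small_matrix():
    vals = np.array([[0.1, 0.5, np.nan], [0.2, np.nan, 0.9], [0.3, 0.7, 0.8]])
    return make_matrix(vals, name="toy")


@pytest.fixture(scope="session")
def margin_toy():
    """Three-layer toy where the label is determined by one mRNA feature.

    The signal feature is margin-separated between classes (class 0 in
    [0, 0.3], class 1 in [0.7, 1]), so the task is cleanly learnable; all
    other features are uninformative noise.
    """
    rng = np.random.default_rng(0)
    n = 200
    ids = [f"S{i:03d}" for i in range(n)]
    y = (rng.random(n) < 0.5).astype(int)
    f0 = np.where(y == 1, rng.uniform(0.7, 1, n), rng.uniform(0, 0.3, n))
    mrna = rng.uniform(0, 1, (n, 10))
    mrna[:, 0] = f0
    met = rng.uniform(0, 1, (n, 8))
    cnv = rng.choice([-1.0, 0.0, 1.0], (n, 5))
    bundle = OmicsBundle(
        [
            OmicsMatrix(ids, [f"mRNA_f{j}" for j in range(10)], mrna, CONTINUOUS_UNIT, "mRNA"),
            OmicsMatrix(ids, [f"MET_f{j}" for j in range(8)], met, CONTINUOUS_UNIT, "MET"),
            OmicsMatrix(ids, [f"CNV_f{j}" for j in range(5)], cnv, TERNARY, "CNV"),
        ]
    )
    return bundle, LabelVector(ids, y)


@pytest.fixture(scope="session")
def margin_toy_cv(margin_toy):
    """CV results on the margin toy, one entry per architecture.

    Computed once per session; the dmoit entry keeps its fold models for
    the permutation-importance tests.
    """
    bundle, labels = margin_toy
    results = {}
    for arch in ("m1", "m2", "m3", "dmoit"):
        results[arch] = run_cv(
            arch, bundle, labels, grid=GridSpec.small(), k=5, seed=1,
            epochs=50, return_models=(arch == "dmoit"),
        )
    return results
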