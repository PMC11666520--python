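"""Post-hoc interpretation: permutation importance and joint-effects analysis.

Permutation importance keeps the fold-trained models fixed ("the optimal
parameters from the full feature set") and shuffles one feature column at a
time across each held-out fold, recording the drop in weighted F1 relative
to the unpermuted baseline, averaged over folds and repeats.

The joint-effects analysis asks whether a biomarker's marginal association
with the outcome survives adjustment for one biomarker from each of the
other two omics layers: for every triple (X1, X2, X3) it fits ordinary
least squares Y ~ X1 and Y ~ X1 + X2 + X3 (linear probability models on the
0/1 label) and counts sign changes of X1's coefficient — the classic
omitted-variable-bias signature of cross-omics joint effects.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datamodel import LabelVector, OmicsBundle
from .train_eval import evaluate

_SIGN_TOL = 1e-12


@dataclass
class ImportanceResult:
    """Per-feature mean weighted-F1 drop, its SD, layer, and rank (1 = largest)."""

    table: pd.DataFrame  # columns: feature, layer, mean_drop, sd_drop, rank

    def top(self, n: int) -> pd.DataFrame:
        return self.table.nsmallest(n, "rank")


@dataclass
class JointEffectsResult:
    per_layer: dict[str, dict[str, int]]  # layer -> {triples, flips, collinear}
    table: pd.DataFrame


def permutation_importance(
    models: list,
    bundle: OmicsBundle,
    labels: LabelVector,
    folds: np.ndarray,
    n_repeats: int = 10,
    seed: int = 0,
) -> ImportanceResult:
    """Evaluation-time permutation importance over held-out folds.

    ``models[f]`` must be the model trained with fold ``f`` held out.
    Permutations are independently seeded per (feature, fold, repeat).
    """
    xs = bundle.arrays()
    y = labels.labels
    k = len(models)
    baselines = []
    test_rows_per_fold = []
    for f in range(k):
        test_rows = np.where(folds == f)[0]
        test_rows_per_fold.append(test_rows)
        preds = models[f].predict([x[test_rows] for x in xs])
        baselines.append(evaluate(preds, y[test_rows])[1])

    records = []
    feat_idx = 0
    for li, layer in enumerate(bundle):
        for j, fid in enumerate(layer.feature_ids):
            drops = []
            for f in range(k):
                test_rows = test_rows_per_fold[f]
                blocks = [x[test_rows] for x in xs]
                col = blocks[li][:, j].copy()
                for r in range(n_repeats):
                    rng = np.random.default_rng([seed, feat_idx, f, r])
                    blocks[li][:, j] = col[rng.permutation(col.size)]
                    preds = models[f].predict(blocks)
                    f1 = evaluate(preds, y[test_rows])[1]
                    drops.append(baselines[f] - f1)
                blocks[li][:, j] = col
            drops = np.asarray(drops)
            records.append(
                {
                    "feature": fid,
                    "layer": layer.name,
                    "mean_drop": float(drops.mean()),
                    "sd_drop": float(drops.std(ddof=1)) if drops.size > 1 else 0.0,
                }
            )
            feat_idx += 1
    table = pd.DataFrame(records)
    order = table.sort_values(
        by=["mean_drop", "feature"], ascending=[False, True], kind="mergesort"
    ).index
    table["rank"] = 0
    table.loc[order, "rank"] = np.arange(1, len(table) + 1)
    return ImportanceResult(table)


def select_top_biomarkers(
    imp: ImportanceResult, per_layer_counts: dict[str, int]
) -> dict[str, list[str]]:
    """Per layer, the top-count features by mean F1 drop (ties by feature ID)."""
    out: dict[str, list[str]] = {}
    for layer, count in per_layer_counts.items():
        sub = imp.table[imp.table["layer"] == layer]
        if count > len(sub):
            raise ValueError(f"requested {count} biomarkers from layer {layer!r} of size {len(sub)}")
        ordered = sub.sort_values(
            by=["mean_drop", "feature"], ascending=[False, True], kind="mergesort"
        )
        out[layer] = list(ordered["feature"].head(count))
    return out


def _ols_coef(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """OLS coefficients with intercept; first entry is the intercept."""
    design = sm.add_constant(X, has_constant="add")
    return sm.OLS(y, design).fit().params


def _sign(x: float) -> int:
    if abs(x) <= _SIGN_TOL:
        return 0
    return 1 if x > 0 else -1


def joint_effects_sign_flip(
    biomarkers: dict[str, pd.DataFrame],
    labels: LabelVector | np.ndarray,
) -> JointEffectsResult:
    """Sign-flip analysis of single vs three-omics linear probability models.

    ``biomarkers`` maps each of three layer names to a samples x features
    DataFrame of its selected biomarker columns (identical row order across
    layers). For each choice of X1's layer and each (X1, X2, X3) triple
    across the other two layers, a flip is recorded when the sign of X1's
    coefficient differs between Y ~ X1 and Y ~ X1 + X2 + X3. A coefficient
    within 1e-12 of zero counts as sign 0, which never flips. Perfectly
    collinear triples are excluded from the flip count and reported
    separately.
    """
    if len(biomarkers) != 3:
        raise ValueError("need biomarker sets from exactly three layers")
    y = labels.labels if isinstance(labels, LabelVector) else np.asarray(labels)
    y = np.asarray(y, dtype=float)
    names = list(biomarkers.keys())
    mats = {n: np.asarray(df, dtype=float) for n, df in biomarkers.items()}
    cols = {n: list(df.columns) for n, df in biomarkers.items()}
    for n, m in mats.items():
        if m.shape[0] != y.size:
            raise ValueError(f"layer {n!r} row count does not match labels")
        if np.isnan(m).any():
            raise ValueError(f"layer {n!r} has missing values")

    rows = []
    per_layer: dict[str, dict[str, int]] = {}
    for x1_layer in names:
        others = [n for n in names if n != x1_layer]
        n_flips = 0
        n_collinear = 0
        n_triples = 0
        # marginal coefficient of each X1 candidate, computed once
        single_sign = {}
        for j1, f1 in enumerate(cols[x1_layer]):
            coef = _ols_coef(y, mats[x1_layer][:, [j1]])
            single_sign[f1] = _sign(coef[1])
        for j1, j2, j3 in itertools.product(
            range(len(cols[x1_layer])), range(len(cols[others[0]])), range(len(cols[others[1]]))
        ):
            f1 = cols[x1_layer][j1]
            f2 = cols[others[0]][j2]
            f3 = cols[others[1]][j3]
            X = np.column_stack(
                [mats[x1_layer][:, j1], mats[others[0]][:, j2], mats[others[1]][:, j3]]
            )
            design = sm.add_constant(X, has_constant="add")
            collinear = np.linalg.matrix_rank(design) < design.shape[1]
            n_triples += 1
            if collinear:
                n_collinear += 1
                flipped = False
                joint_sign = None
            else:
                coef = sm.OLS(y, design).fit().params
                joint_sign = _sign(coef[1])
                s1 = single_sign[f1]
                flipped = s1 != 0 and joint_sign != 0 and joint_sign != s1
                if flipped:
                    n_flips += 1
            rows.append(
                {
                    "x1_layer": x1_layer,
                    "x1": f1,
                    "x2": f2,
                    "x3": f3,
                    "sign_single": single_sign[f1],
                    "sign_joint": joint_sign,
                    "flipped": flipped,
                    "collinear": collinear,
                }
            )
        per_layer[x1_layer] = {
            "triples": n_triples,
            "flips": n_flips,
            "collinear": n_collinear,
        }
    return JointEffectsResult(per_layer, pd.DataFrame(rows))
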