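"""Permutation importance and joint-effects sign-flip analysis."""

import numpy as np
import pandas as pd
import pytest

from dmoit import (
    LabelVector,
    joint_effects_sign_flip,
    permutation_importance,
    select_top_biomarkers,
)


class TestPermutationImportance:
    def test_signal_feature_has_largest_drop(self, margin_toy, margin_toy_cv):
        bundle, labels = margin_toy
        res = margin_toy_cv["dmoit"]
        imp = permutation_importance(
            res.models, bundle, labels, res.folds, n_repeats=5, seed=0
        )
        top = imp.table.sort_values("rank").iloc[0]
        assert top["feature"] == "mRNA_f0"

    def test_constant_feature_has_exactly_zero_drop(self, margin_toy, margin_toy_cv):
        bundle, labels = margin_toy
        res = margin_toy_cv["dmoit"]
        # make a constant copy of one noise column
        bundle2 = bundle.select_samples(range(bundle.n_samples))
        bundle2[1].values[:, 3] = 0.5
        imp = permutation_importance(
            res.models, bundle2, labels, res.folds, n_repeats=3, seed=1
        )
        row = imp.table[imp.table["feature"] == "MET_f3"].iloc[0]
        assert row["mean_drop"] == 0.0

    def test_repeatable_with_same_seed(self, margin_toy, margin_toy_cv):
        bundle, labels = margin_toy
        res = margin_toy_cv["dmoit"]
        i1 = permutation_importance(res.models, bundle, labels, res.folds, 1, seed=2)
        i2 = permutation_importance(res.models, bundle, labels, res.folds, 1, seed=2)
        pd.testing.assert_frame_equal(i1.table, i2.table)

    def test_ranks_are_a_permutation(self, margin_toy, margin_toy_cv):
        bundle, labels = margin_toy
        res = margin_toy_cv["dmoit"]
        imp = permutation_importance(res.models, bundle, labels, res.folds, 2, seed=3)
        assert sorted(imp.table["rank"]) == list(range(1, len(imp.table) + 1))


class TestSelectTopBiomarkers:
    def _importance(self):
        rng = np.random.default_rng(0)
        rows = []
        for layer, p in (("mRNA", 30), ("MET", 20), ("CNV", 10)):
            for j in range(p):
                rows.append(
                    {"feature": f"{layer}_f{j}", "layer": layer,
                     "mean_drop": rng.uniform(-0.01, 0.2), "sd_drop": 0.0}
                )
        table = pd.DataFrame(rows)
        table["rank"] = (-table["mean_drop"]).rank().astype(int)
        from dmoit.interpret import ImportanceResult

        return ImportanceResult(table)

    def test_requested_counts_returned(self):
        imp = self._importance()
        sets = select_top_biomarkers(imp, {"mRNA": 10, "MET": 15, "CNV": 4})
        assert [len(sets[k]) for k in ("mRNA", "MET", "CNV")] == [10, 15, 4]

    def test_whole_layer_and_empty(self):
        imp = self._importance()
        sets = select_top_biomarkers(imp, {"CNV": 10, "MET": 0})
        assert len(sets["CNV"]) == 10 and sets["MET"] == []

    def test_count_exceeding_layer_rejected(self):
        with pytest.raises(ValueError):
            select_top_biomarkers(self._importance(), {"CNV": 11})

    def test_selected_are_largest_drops(self):
        imp = self._importance()
        sets = select_top_biomarkers(imp, {"mRNA": 3})
        sub = imp.table[imp.table["layer"] == "mRNA"].sort_values("mean_drop", ascending=False)
        assert sets["mRNA"] == list(sub["feature"].head(3))


def _frames(n, sizes, seed):
    rng = np.random.default_rng(seed)
    out = {}
    for name, p in sizes.items():
        out[name] = pd.DataFrame(
            rng.standard_normal((n, p)), columns=[f"{name}_f{j}" for j in range(p)]
        )
    return out


class TestJointEffects:
    def test_triple_counts_are_set_size_products(self):
        frames = _frames(50, {"A": 3, "B": 2, "C": 2}, seed=0)
        y = np.random.default_rng(1).integers(0, 2, 50)
        res = joint_effects_sign_flip(frames, LabelVector([f"S{i}" for i in range(50)], y))
        assert res.per_layer["A"]["triples"] == 3 * 2 * 2
        assert res.per_layer["B"]["triples"] == 2 * 3 * 2
        assert res.per_layer["C"]["triples"] == 2 * 3 * 2
        assert len(res.table) == 3 * 12

    def test_orthogonal_adjusters_never_flip(self):
        """X2, X3 exactly orthogonal to X1 and y leave a1 unchanged."""
        n = 64
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.tile([1.0, 1.0, -1.0, -1.0], n // 4)
        x3 = np.tile([1.0, -1.0, -1.0, 1.0], n // 4)
        y = (x1 > 0).astype(int)
        frames = {
            "A": pd.DataFrame({"a0": x1}),
            "B": pd.DataFrame({"b0": x2}),
            "C": pd.DataFrame({"c0": x3}),
        }
        res = joint_effects_sign_flip(frames, LabelVector([f"S{i}" for i in range(n)], y))
        assert res.per_layer["A"]["flips"] == 0

    def test_constructed_confounder_flips_sign(self):
        """Omitted-variable bias: marginally positive, conditionally negative."""
        rng = np.random.default_rng(7)
        n = 200
        c = rng.standard_normal(n)
        x1 = c + 0.5 * rng.standard_normal(n)
        y_star = c - 0.4 * x1 + 0.05 * rng.standard_normal(n)
        y = (y_star > np.median(y_star)).astype(int)
        frames = {
            "A": pd.DataFrame({"x1": x1}),
            "B": pd.DataFrame({"conf": c}),
            "C": pd.DataFrame({"noise": rng.standard_normal(n)}),
        }
        labels = LabelVector([f"S{i}" for i in range(n)], y)
        res = joint_effects_sign_flip(frames, labels)
        assert res.per_layer["A"]["flips"] == 1
        # brute-force normal-equations oracle agrees on both coefficients
        X1 = np.column_stack([np.ones(n), x1])
        a_single = np.linalg.solve(X1.T @ X1, X1.T @ y)[1]
        X123 = np.column_stack([np.ones(n), x1, c, frames["C"]["noise"]])
        a_joint = np.linalg.solve(X123.T @ X123, X123.T @ y)[1]
        assert a_single > 0 > a_joint
        row = res.table[(res.table["x1_layer"] == "A")].iloc[0]
        assert row["sign_single"] == 1 and row["sign_joint"] == -1

    def test_collinear_triples_excluded_and_reported(self):
        rng = np.random.default_rng(3)
        n = 40
        x = rng.standard_normal(n)
        frames = {
            "A": pd.DataFrame({"x1": x}),
            "B": pd.DataFrame({"dup": 2 * x}),  # perfectly collinear with x1
            "C": pd.DataFrame({"z": rng.standard_normal(n)}),
        }
        y = rng.integers(0, 2, n)
        res = joint_effects_sign_flip(frames, LabelVector([f"S{i}" for i in range(n)], y))
        assert res.per_layer["A"]["collinear"] == 1
        assert res.per_layer["A"]["flips"] == 0

    def test_ols_matches_brute_force_on_random_instances(self):
        """statsmodels-backed fits equal the normal-equations solution."""
        rng = np.random.default_rng(4)
        from dmoit.interpret import _ols_coef

        for _ in range(20):
            n = rng.integers(10, 40)
            X = rng.standard_normal((n, 3))
            y = rng.standard_normal(n)
            coef = _ols_coef(y, X)
            design = np.column_stack([np.ones(n), X])
            ref = np.linalg.solve(design.T @ design, design.T @ y)
            assert np.abs(np.asarray(coef) - ref).max() < 1e-8
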