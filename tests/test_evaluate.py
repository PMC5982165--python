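"""Classification evaluation: folds, voting, settings, three-way ANOVA."""

import itertools

import numpy as np
import pandas as pd
import pytest

from emgfault import anova3, enumerate_kfolds, majority_vote, train_classifier
from emgfault.evaluate import run_setting
from emgfault.features import feature_columns


class TestFolds:
    @pytest.mark.parametrize("n,k,expect", [(6, 3, 20), (2, 1, 2), (4, 2, 6)])
    def test_partition_counts(self, n, k, expect):
        assert len(enumerate_kfolds(n, k)) == expect

    def test_partitions_disjoint_and_exhaustive(self):
        for train, test in enumerate_kfolds(6, 3):
            assert set(train) & set(test) == set()
            assert sorted(train + test) == [1, 2, 3, 4, 5, 6]

    def test_each_repetition_in_ten_training_triples(self):
        folds = enumerate_kfolds(6, 3)
        for rep in range(1, 7):
            assert sum(rep in train for train, _ in folds) == 10

    def test_invalid_split_rejected(self):
        with pytest.raises(ValueError):
            enumerate_kfolds(3, 3)


class TestVoting:
    def test_isolated_flip_suppressed(self):
        raw = np.array(["A", "A", "B", "A"])
        assert list(majority_vote(raw)) == ["A", "A", "A", "A"]

    def test_constant_sequence_unchanged(self):
        raw = np.array([3, 3, 3, 3])
        assert list(majority_vote(raw)) == [3, 3, 3, 3]

    def test_three_way_tie_keeps_current(self):
        raw = np.array(["A", "B", "C"])
        assert majority_vote(raw)[2] == "C"

    def test_runs_of_two_or_more_preserved(self):
        rng = np.random.default_rng(0)
        raw = np.repeat(rng.integers(0, 5, size=20), 2)
        voted = majority_vote(raw)
        # every position inside a run of >= 2 identical raw labels keeps it
        for i in range(1, len(raw)):
            if raw[i] == raw[i - 1]:
                assert voted[i] == raw[i]


def _toy_feature_table(seed=0, n_channels=2, n_classes=3, reps=(1, 2), rows_per=30):
    """Linearly separable per-class feature clusters over repetitions."""
    rng = np.random.default_rng(seed)
    rows = []
    cols = feature_columns(n_channels)
    for rep in reps:
        for cls in range(n_classes):
            center = 3.0 * cls
            X = rng.normal(center, 0.1, size=(rows_per, len(cols)))
            for x in X:
                row = dict(zip(cols, x))
                row.update(
                    {"label": cls, "repetition": rep, "fold_repetition": rep,
                     "provenance": "clean"}
                )
                rows.append(row)
    return pd.DataFrame(rows)


class TestClassifier:
    def test_separable_training_perfect(self):
        tab = _toy_feature_table()
        model = train_classifier(tab, C=10.0, gamma=0.1)
        pred = model.predict_raw(tab)
        assert np.mean(pred == tab["label"].to_numpy()) == 1.0

    def test_single_class_rejected(self):
        tab = _toy_feature_table(n_classes=1)
        with pytest.raises(ValueError):
            train_classifier(tab, C=1.0, gamma=0.1)

    def test_grid_search_deterministic(self):
        tab = _toy_feature_table()
        grid = {"C": [1.0, 10.0], "gamma": [0.01, 0.1]}
        m1 = train_classifier(tab, seed=5, grid=grid)
        m2 = train_classifier(tab, seed=5, grid=grid)
        assert m1.meta["params"] == m2.meta["params"]

    def test_run_setting_clean_reference(self):
        tab = _toy_feature_table(reps=(1, 2, 3, 4))
        folds = [((1, 2), (3, 4)), ((3, 4), (1, 2))]
        res = run_setting(1, {"clean": tab}, folds, C=10.0, gamma=0.1)
        assert res.mean_accuracy >= 95.0
        total = res.confusions[0][1].sum()
        assert total == (tab["fold_repetition"].isin((3, 4))).sum()

    def test_run_setting_null_contamination_matches_clean(self):
        tab = _toy_feature_table(reps=(1, 2, 3, 4))
        folds = [((1, 2), (3, 4))]
        r1 = run_setting(1, {"clean": tab}, folds, C=10.0, gamma=0.1)
        r2 = run_setting(
            2, {"clean": tab, "contaminated": tab.copy()}, folds, C=10.0, gamma=0.1
        )
        assert r1.mean_accuracy == r2.mean_accuracy

    def test_missing_bundle_rejected(self):
        tab = _toy_feature_table()
        with pytest.raises(ValueError):
            run_setting(4, {"clean": tab}, [((1,), (2,))])


def _balanced_table(effects_a=(0.0, 0.0), effects_b=(0.0, 0.0), effects_c=(0.0, 0.0),
                    reps=4, noise=1.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i, a in enumerate(effects_a):
        for j, b in enumerate(effects_b):
            for k, c in enumerate(effects_c):
                for _ in range(reps):
                    rows.append(
                        {
                            "setting": f"a{i}",
                            "contaminant": f"b{j}",
                            "case": f"c{k}",
                            "accuracy": 50 + a + b + c + noise * rng.standard_normal(),
                        }
                    )
    return pd.DataFrame(rows)


def _two_pass_ss(df):
    """Textbook two-pass sums of squares for a balanced 3-factor design."""
    y = df["accuracy"]
    grand = y.mean()
    ss_total = ((y - grand) ** 2).sum()

    def ss_main(f):
        g = df.groupby(f)["accuracy"]
        return (g.count() * (g.mean() - grand) ** 2).sum()

    def ss_two(f1, f2):
        g = df.groupby([f1, f2])["accuracy"]
        cell = (g.count() * (g.mean() - grand) ** 2).sum()
        return cell - ss_main(f1) - ss_main(f2)

    A, B, C = "setting", "contaminant", "case"
    g3 = df.groupby([A, B, C])["accuracy"]
    ss_cells = (g3.count() * (g3.mean() - grand) ** 2).sum()
    ss = {
        A: ss_main(A),
        B: ss_main(B),
        C: ss_main(C),
        f"{A}:{B}": ss_two(A, B),
        f"{A}:{C}": ss_two(A, C),
        f"{B}:{C}": ss_two(B, C),
    }
    ss[f"{A}:{B}:{C}"] = ss_cells - sum(ss.values())
    ss["Residual"] = ss_total - ss_cells
    return ss, ss_total


class TestAnova:
    def test_matches_two_pass_oracle_2x2x2(self):
        df = _balanced_table((0, 4), (0, 2), (0, 1), reps=3, seed=1)
        model = anova3(df)
        oracle, ss_total = _two_pass_ss(df)
        for effect, ss in oracle.items():
            assert model.table.loc[effect, "sum_sq"] == pytest.approx(ss, rel=1e-8)
        assert model.table["sum_sq"].sum() == pytest.approx(ss_total, rel=1e-8)

    def test_partition_exact_on_larger_design(self):
        df = _balanced_table((0, 3, 6), (0, 2), (0, 1, 2, 3), reps=2, seed=2)
        model = anova3(df)
        grand = df["accuracy"].mean()
        ss_total = ((df["accuracy"] - grand) ** 2).sum()
        assert model.table["sum_sq"].sum() == pytest.approx(ss_total, rel=1e-8)

    def test_effects_sum_to_zero(self):
        df = _balanced_table((0, 4), (0, 2), (0, 1), reps=3, seed=3)
        model = anova3(df)
        for f in model.factors:
            assert model.effects[f].sum() == pytest.approx(0.0, abs=1e-9)

    def test_pure_main_effect_detected_interactions_null(self):
        """Only factor A truly differs: F_A large, interaction p-values > 0.05."""
        df = _balanced_table((0, 5), (0, 0), (0, 0), reps=50, noise=1.0, seed=0)
        model = anova3(df)
        t = model.table
        assert t.loc["setting", "F"] > 100
        for effect in ("setting:contaminant", "setting:case", "contaminant:case",
                       "setting:contaminant:case"):
            assert t.loc[effect, "PR(>F)"] > 0.05

    def test_constant_cells_zero_f(self):
        df = _balanced_table(reps=3, noise=0.0, seed=5)
        df["accuracy"] = 42.0
        model = anova3(df)
        assert np.allclose(model.table["sum_sq"].to_numpy(), 0.0, atol=1e-16)

    def test_missing_cells_rejected(self):
        df = _balanced_table((0, 4), (0, 2), (0, 1), reps=3, seed=6)
        df = df[~((df["setting"] == "a0") & (df["contaminant"] == "b0"))]
        with pytest.raises(ValueError):
            anova3(df)

    def test_group_interval_separation(self):
        df = _balanced_table((0, 10), (0, 0), (0, 0), reps=20, noise=1.0, seed=7)
        model = anova3(df)
        assert model.significantly_different("setting", "a0", "a1")
        assert not model.significantly_different("contaminant", "b0", "b1")
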