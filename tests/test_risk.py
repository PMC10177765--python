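"""Feature assembly, stratified splitting, classifiers, ROC/AUC, importance."""

import itertools

import numpy as np
import pandas as pd
import pytest

import fieldspot as fs

from conftest import panel_from_windows


def _clinical(n_high, n_low, rng=None, age_shift=0.0):
    rng = rng or np.random.default_rng(0)
    rows = []
    for i in range(n_high + n_low):
        label = "high" if i < n_high else "low"
        rows.append(
            {
                "sample_id": f"s{i:04d}",
                "risk_label": label,
                "age": 60 + (age_shift if label == "high" else 0) + rng.normal(0, 5),
                "sex": "male" if rng.random() < 0.5 else "female",
                "smoking": str(rng.choice(["never", "former", "current"])),
            }
        )
    return fs.ClinicalTable(pd.DataFrame(rows))


class TestAssembleFeatures:
    def test_burden_counts_records_inside_panel(self):
        panel = panel_from_windows([fs.Window("1", 100, 199)])
        recs = [
            fs.MutationRecord("s0000", "1", 150, "A", "G"),
            fs.MutationRecord("s0000", "1", 160, "C", "T"),
            fs.MutationRecord("s0000", "1", 500, "A", "G"),
            fs.MutationRecord("s0000", "2", 150, "A", "G"),
        ]
        cat = fs.MutationCatalog(recs, cohort_name="c")
        clin = _clinical(1, 1)
        table = fs.assemble_features({"c": cat}, {"mibc": panel}, clin, "mibc+risk")
        assert table.loc["s0000", "hotspot_burden_mibc"] == 2
        # zero-mutation sample present in clinical keeps burden 0
        assert table.loc["s0001", "hotspot_burden_mibc"] == 0

    def test_matches_brute_force_on_toy(self):
        rng = np.random.default_rng(5)
        windows = [fs.Window("1", 1, 100), fs.Window("1", 301, 400)]
        panel = panel_from_windows(windows)
        recs = []
        for i in range(5):
            for _ in range(4):
                recs.append(
                    fs.MutationRecord(f"s{i:04d}", "1", int(rng.integers(1, 500)), "A", "G")
                )
        cat = fs.MutationCatalog(recs, cohort_name="c")
        table = fs.assemble_features({"c": cat}, {"mibc": panel}, _clinical(3, 2), "mibc+risk")
        for sid in table.index:
            expected = sum(
                1 for r in recs
                if r.sample_id == sid
                and any(w.start <= r.pos <= w.end for w in windows if w.chrom == r.chrom)
            )
            assert table.loc[sid, "hotspot_burden_mibc"] == expected

    def test_risk_only_omits_burden(self):
        table = fs.assemble_features({}, {}, _clinical(2, 2), "risk_only")
        assert not any(c.startswith("hotspot_burden") for c in table.columns)
        assert {"age", "sex_male", "smoking_current", "smoking_former", "label"} <= set(
            table.columns
        )

    def test_unknown_feature_set_errors(self):
        with pytest.raises(ValueError, match="feature_set"):
            fs.assemble_features({}, {}, _clinical(1, 1), "everything")

    def test_missing_age_rows_dropped_missing_smoking_flagged(self):
        df = _clinical(2, 2).data.reset_index()
        df.loc[0, "age"] = np.nan
        df.loc[1, "smoking"] = "unknown"
        table = fs.assemble_features({}, {}, fs.ClinicalTable(df), "risk_only")
        assert len(table) == 3
        flagged = table.loc[df.loc[1, "sample_id"]]
        assert flagged["smoking_missing"] == 1
        assert flagged["smoking_current"] == 0 and flagged["smoking_former"] == 0


class TestSplit:
    def _table(self, n_high=100, n_low=100):
        clin = _clinical(n_high, n_low)
        return fs.assemble_features({}, {}, clin, "risk_only")

    def test_stratified_sizes(self):
        table = self._table(100, 100)
        train, test = fs.split_train_test(table, 0.7, seed=0)
        assert (len(train), len(test)) == (140, 60)
        assert (train["label"] == "high").sum() == 70
        assert set(train.index).isdisjoint(test.index)
        assert set(train.index) | set(test.index) == set(table.index)

    def test_deterministic_given_seed(self):
        table = self._table(40, 60)
        t1, _ = fs.split_train_test(table, seed=3)
        t2, _ = fs.split_train_test(table, seed=3)
        t3, _ = fs.split_train_test(table, seed=4)
        assert t1.index.tolist() == t2.index.tolist()
        assert t1.index.tolist() != t3.index.tolist()

    def test_label_proportions_preserved(self):
        table = self._table(75, 25)
        train, test = fs.split_train_test(table, 0.7, seed=1)
        # floor(0.7 * n_label) per label, never off by more than one sample
        assert abs((train["label"] == "high").mean() - 0.75) < 0.02

    def test_full_train_fraction_rejected(self):
        with pytest.raises(ValueError):
            fs.split_train_test(self._table(10, 10), train_frac=1.0)

    def test_tiny_label_rejected(self):
        table = self._table(10, 10).iloc[: 10 + 1]
        with pytest.raises(ValueError, match="fewer than 2"):
            fs.split_train_test(table)


def brute_force_auc(scores, labels):
    """Pairwise concordance with ties counted 1/2 — the oracle."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = fs.roc_auc([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0])
        assert auc == 1.0

    def test_three_of_four_pairs_concordant(self):
        _, auc = fs.roc_auc([0.9, 0.4, 0.6, 0.2], [1, 1, 0, 0])
        assert auc == 0.75

    def test_all_ties_half(self):
        _, auc = fs.roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0])
        assert auc == 0.5

    def test_matches_brute_force_exactly(self):
        rng = np.random.default_rng(13)
        for _ in range(200):
            n = int(rng.integers(2, 21))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            # coarse grid forces plenty of ties
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
            _, auc = fs.roc_auc(scores, labels)
            assert auc == brute_force_auc(scores, labels)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(14)
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        _, a1 = fs.roc_auc(scores, labels)
        _, a2 = fs.roc_auc(np.exp(scores) * 3 + 1, labels)
        assert a1 == pytest.approx(a2)

    def test_roc_shape(self):
        rng = np.random.default_rng(15)
        scores = rng.random(25)
        labels = rng.integers(0, 2, 25)
        labels[:2] = [0, 1]
        points, _ = fs.roc_auc(scores, labels)
        assert points[0] == (0.0, 0.0) and points[-1] == (1.0, 1.0)
        fprs, tprs = zip(*points)
        assert all(a <= b for a, b in zip(fprs, fprs[1:]))
        assert all(a <= b for a, b in zip(tprs, tprs[1:]))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fs.roc_auc([0.1, 0.2], [1, 1])


class TestFitAndScore:
    def _separable_table(self, n=60):
        rng = np.random.default_rng(20)
        clin = _clinical(n // 2, n // 2, rng=rng)
        table = fs.assemble_features({}, {}, clin, "risk_only")
        # plant a perfectly separating feature
        table["age"] = np.where(table["label"] == "high", 80.0, 40.0) + rng.normal(
            0, 1, len(table)
        )
        return table

    @pytest.mark.parametrize("model", ["logistic", "neural_net", "random_forest"])
    def test_separable_data_gives_auc_one(self, model):
        table = self._separable_table()
        train, test = fs.split_train_test(table, seed=0)
        rep = fs.fit_and_score(train, test, model, seed=0)
        assert rep.auc == 1.0

    def test_label_permutation_gives_chance_auc(self):
        rng = np.random.default_rng(30)
        clin = _clinical(200, 200, rng=rng, age_shift=10)
        table = fs.assemble_features({}, {}, clin, "risk_only")
        table["label"] = rng.permutation(table["label"].to_numpy())
        train, test = fs.split_train_test(table, seed=0)
        for model in ("logistic", "random_forest"):
            rep = fs.fit_and_score(train, test, model, seed=0)
            assert 0.4 < rep.auc < 0.6

    def test_unknown_model_rejected(self):
        table = self._separable_table(20)
        train, test = fs.split_train_test(table, seed=0)
        with pytest.raises(ValueError):
            fs.fit_and_score(train, test, "svm")


class TestVariableImportance:
    def test_label_copy_feature_dominates_noise(self):
        rng = np.random.default_rng(40)
        clin = _clinical(100, 100, rng=rng)
        table = fs.assemble_features({}, {}, clin, "risk_only")
        table["age"] = (table["label"] == "high").astype(float) + rng.normal(
            0, 0.05, len(table)
        )  # effectively the label
        table["sex_male"] = rng.integers(0, 2, len(table))  # pure noise
        train, test = fs.split_train_test(table, seed=0)
        rep = fs.fit_and_score(train, test, "random_forest", seed=0)
        imp = fs.variable_importance(rep, test, seed=0)
        assert imp.index[0] == "age"
        assert abs(imp["sex_male"]) < 0.05
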