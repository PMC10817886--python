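"""Stratified folds, the six-metric suite, ROC/AUC and the ablation harness."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rvflkit as rk
from rvflkit.errors import ValidationError
from rvflkit.evaluation import DEFAULT_GRIDS, METRIC_COLUMNS, ablate, report_to_json


class TestStratifiedKfold:
    def test_mass_patch_class_totals(self):
        # 1908 benign + 1810 malignant, k=5: the published partition shape
        labels = ["benign"] * 1908 + ["malignant"] * 1810
        plan = rk.stratified_kfold(labels, 5, seed=3)
        lab = np.asarray(labels, dtype=object)
        benign_sizes, malig_sizes, totals = [], [], []
        for f in range(5):
            idx = plan.test_indices(f)
            benign_sizes.append(int(np.sum(lab[idx] == "benign")))
            malig_sizes.append(int(np.sum(lab[idx] == "malignant")))
            totals.append(len(idx))
        assert sum(totals) == 3718
        assert sorted(benign_sizes) == [381, 381, 382, 382, 382]
        assert malig_sizes == [362] * 5
        assert max(totals) == 744

    def test_single_class_even_split(self):
        plan = rk.stratified_kfold(["benign"] * 10, 5, seed=0)
        sizes = [len(plan.test_indices(f)) for f in range(5)]
        assert sizes == [2] * 5

    @given(
        n_b=st.integers(min_value=5, max_value=40),
        n_m=st.integers(min_value=5, max_value=40),
        seed=st.integers(min_value=0, max_value=100),
    )
    @settings(deadline=None, max_examples=30)
    def test_partition_property(self, n_b, n_m, seed):
        labels = ["benign"] * n_b + ["malignant"] * n_m
        plan = rk.stratified_kfold(labels, 5, seed=seed)
        all_idx = np.concatenate([plan.test_indices(f) for f in range(5)])
        assert sorted(all_idx.tolist()) == list(range(n_b + n_m))
        # per-class fold sizes differ by at most 1
        lab = np.asarray(labels, dtype=object)
        for cls in ("benign", "malignant"):
            sizes = [int(np.sum(lab[plan.test_indices(f)] == cls)) for f in range(5)]
            assert max(sizes) - min(sizes) <= 1

    def test_reproducible_same_seed(self):
        labels = ["benign"] * 20 + ["malignant"] * 20
        p1 = rk.stratified_kfold(labels, 4, seed=9)
        p2 = rk.stratified_kfold(labels, 4, seed=9)
        assert np.array_equal(p1.assignment, p2.assignment)

    def test_class_smaller_than_k_rejected(self):
        with pytest.raises(ValidationError):
            rk.stratified_kfold(["benign"] * 3 + ["malignant"] * 10, 5, seed=0)


class TestMetrics:
    def test_perfect_classifier(self):
        m = rk.compute_metrics(rk.ConfusionCounts(tp=1, fp=0, tn=1, fn=0))
        assert all(m[k] == 1.0 for k in ("sensitivity", "specificity", "precision", "f1", "accuracy"))

    def test_hand_arithmetic_oracle(self):
        m = rk.compute_metrics(rk.ConfusionCounts(tp=30, fp=10, tn=40, fn=20))
        assert m["sensitivity"] == pytest.approx(0.6)
        assert m["specificity"] == pytest.approx(0.8)
        assert m["precision"] == pytest.approx(0.75)
        assert m["f1"] == pytest.approx(2 * 0.75 * 0.6 / 1.35)
        assert m["accuracy"] == pytest.approx(0.7)

    def test_degenerate_denominator_flagged_not_zero(self):
        with pytest.warns(UserWarning, match="precision"):
            m = rk.compute_metrics(rk.ConfusionCounts(tp=0, fp=0, tn=5, fn=5))
        assert np.isnan(m["precision"])
        assert m["specificity"] == 1.0
        assert m["accuracy"] == 0.5

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            rk.ConfusionCounts(tp=-1, fp=0, tn=0, fn=0)

    def test_sklearn_cross_check(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(4)
        true = rng.choice(["benign", "malignant"], size=200)
        pred = rng.choice(["benign", "malignant"], size=200)
        c = rk.confusion_from_labels(true, pred)
        m = rk.compute_metrics(c)
        assert m["accuracy"] == pytest.approx(
            sk.accuracy_score(true, pred))
        assert m["sensitivity"] == pytest.approx(
            sk.recall_score(true, pred, pos_label="malignant"))
        assert m["f1"] == pytest.approx(
            sk.f1_score(true, pred, pos_label="malignant"))


def _pair_auc(scores, labels):
    """O(n^2) Mann-Whitney oracle: fraction of (pos, neg) pairs won, ties half."""
    pos = [s for s, l in zip(scores, labels) if l == "malignant"]
    neg = [s for s, l in zip(scores, labels) if l == "benign"]
    wins = sum(1.0 if p > n else (0.5 if p == n else 0.0) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        scores = [0.1, 0.2, 0.8, 0.9]
        labels = ["benign", "benign", "malignant", "malignant"]
        auc, pts = rk.roc_auc(scores, labels)
        assert auc == 1.0
        assert tuple(pts[0]) == (0.0, 0.0) and tuple(pts[-1]) == (1.0, 1.0)

    def test_all_ties_give_half(self):
        auc, _ = rk.roc_auc([1.0] * 10, ["benign"] * 5 + ["malignant"] * 5)
        assert auc == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(10))
    def test_trapezoid_equals_pair_statistic(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        scores = np.round(rng.standard_normal(n), 1)  # rounding forces ties
        labels = ["malignant" if b else "benign" for b in rng.random(n) < 0.5]
        if len(set(labels)) < 2:
            labels[0] = "benign" if labels[0] == "malignant" else "malignant"
        auc, _ = rk.roc_auc(scores, labels)
        assert abs(auc - _pair_auc(scores, labels)) < 1e-12

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(8)
        scores = rng.standard_normal(50)
        labels = ["malignant" if b else "benign" for b in rng.random(50) < 0.4]
        a1, _ = rk.roc_auc(scores, labels)
        a2, _ = rk.roc_auc(np.exp(3 * scores), labels)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_roc_points_monotone(self):
        rng = np.random.default_rng(9)
        scores = rng.standard_normal(60)
        labels = ["malignant" if b else "benign" for b in rng.random(60) < 0.5]
        _, pts = rk.roc_auc(scores, labels)
        assert (np.diff(pts[:, 0]) >= 0).all() and (np.diff(pts[:, 1]) >= 0).all()

    def test_sklearn_cross_check(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(13)
        scores = rng.standard_normal(100)
        y = rng.random(100) < 0.5
        labels = ["malignant" if b else "benign" for b in y]
        auc, _ = rk.roc_auc(scores, labels)
        assert auc == pytest.approx(sk.roc_auc_score(y, scores), abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValidationError):
            rk.roc_auc([1.0, 2.0], ["benign", "benign"])


class _ConstantBenignSpec:
    """Stub spec whose fitted model always scores zero (ties -> benign)."""

    kind, h, widths, activation, eta, mode = "rvfln", 0, None, "sigmoid", 0.0, "auto"

    def fit(self, train, seed):
        model = rk.fit_rvfln(train, h=0, seed=seed)
        model.alpha[:] = 0.0
        return model


class TestCrossValidate:
    def test_constant_classifier_closed_form(self, gauss24):
        report = rk.cross_validate(gauss24, _ConstantBenignSpec(), k=5, seed=1)
        prevalence = 0.5  # balanced generator
        assert report["summary"]["accuracy"]["mean"] == pytest.approx(prevalence)
        assert report["summary"]["sensitivity"]["mean"] == 0.0

    def test_identical_folds_zero_std(self):
        rep = {"summary": None}
        per_fold = [dict(sensitivity=0.8, specificity=0.9, precision=0.7,
                         f1=0.75, accuracy=0.85, auc=0.9) for _ in range(5)]
        from rvflkit.evaluation import _summarize
        s = _summarize(per_fold)
        assert all(s[m]["std"] == 0.0 for m in METRIC_COLUMNS)

    def test_separable_drvfl_benchmark(self, gauss24):
        spec = rk.ClassifierSpec(kind="drvfl", widths=(6, 6, 6))
        report = rk.cross_validate(gauss24, spec, k=5, seed=2)
        assert report["summary"]["accuracy"]["mean"] >= 0.99
        assert report["summary"]["accuracy"]["std"] <= 0.01

    def test_report_deterministic(self, small_features):
        spec = rk.ClassifierSpec(kind="elm", h=10)
        r1 = report_to_json(rk.cross_validate(small_features, spec, k=4, seed=7))
        r2 = report_to_json(rk.cross_validate(small_features, spec, k=4, seed=7))
        assert r1 == r2

    def test_summary_uses_sample_std(self, small_features):
        spec = rk.ClassifierSpec(kind="elm", h=10)
        report = rk.cross_validate(small_features, spec, k=4, seed=7)
        accs = [f["accuracy"] for f in report["per_fold"]]
        assert report["summary"]["accuracy"]["std"] == pytest.approx(
            np.std(accs, ddof=1))


class TestAblate:
    def test_default_grids_match_published(self):
        assert DEFAULT_GRIDS["elm"] == (40, 80, 100, 200, 400, 800, 1000)
        assert DEFAULT_GRIDS["rvfln"] == (40, 80, 100, 200, 400, 800, 1000)
        assert DEFAULT_GRIDS["drvfl"] == (6, 12, 18, 24)

    def test_single_point_grid_matches_cross_validate(self, small_features):
        table = ablate(small_features, "elm", grid=[10], k=4, seed=7)
        assert len(table) == 1
        report = rk.cross_validate(
            small_features, rk.ClassifierSpec(kind="elm", h=10), k=4, seed=7)
        assert table.loc[0, "accuracy_mean"] == pytest.approx(
            report["summary"]["accuracy"]["mean"])

    def test_separable_benchmark_all_rows(self, gauss24):
        table = ablate(gauss24, "drvfl", grid=[6, 12], k=5, seed=3)
        assert (table["accuracy_mean"] >= 0.99).all()
        assert {f"{m}_mean" for m in METRIC_COLUMNS} <= set(table.columns)

    def test_empty_grid_rejected(self, small_features):
        with pytest.raises(ValidationError):
            ablate(small_features, "elm", grid=[], k=4, seed=0)
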