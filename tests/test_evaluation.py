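"""Metrics, fold plans, leakage auditing, and nested-CV behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pcgscreen.errors import InvalidConfigError, InvalidInputError, LeakageError
from pcgscreen.evaluation import (
    ConfusionCounts,
    Fold,
    FoldPlan,
    PROTOCOL_IMBALANCED,
    PROTOCOL_STRATIFIED,
    confusion,
    hc_count_for_prevalence,
    imbalanced_fold_plan,
    metrics,
    run_experiment,
    run_nested_cv,
    stratified_fold_plan,
    validate_no_leakage,
)


def subjects(n_rhd, n_hc):
    return [(f"rhd-{i}", "RHD") for i in range(n_rhd)] + [
        (f"hc-{i}", "HC") for i in range(n_hc)
    ]


def separable_features(n_rhd, n_hc, seed=0, d=8, gap=6.0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(gap / 2, 1.0, (n_rhd, d)), rng.normal(-gap / 2, 1.0, (n_hc, d))])
    df = pd.DataFrame(X, columns=[f"f{i}" for i in range(d)])
    df.insert(0, "subject_id", [s for s, _ in subjects(n_rhd, n_hc)])
    df.insert(1, "label", ["RHD"] * n_rhd + ["HC"] * n_hc)
    return df


class TestConfusionAndMetrics:
    def test_perfect_prediction(self):
        c = confusion(["RHD", "HC", "RHD"], ["RHD", "HC", "RHD"])
        assert (c.fp, c.fn) == (0, 0) and (c.tp, c.tn) == (2, 1)

    def test_all_hc_prediction(self):
        c = confusion(["RHD"] * 3 + ["HC"] * 4, ["HC"] * 7)
        assert c.tp == 0 and c.fn == 3 and c.tn == 4

    def test_hand_counted_example(self):
        y_true = ["RHD", "RHD", "HC", "HC", "RHD", "HC", "HC", "RHD", "HC", "HC"]
        y_pred = ["RHD", "HC", "RHD", "HC", "RHD", "HC", "RHD", "RHD", "HC", "HC"]
        c = confusion(y_true, y_pred)
        assert (c.tp, c.fp, c.fn, c.tn) == (3, 2, 1, 4)

    def test_length_mismatch(self):
        with pytest.raises(InvalidInputError):
            confusion(["RHD"], ["RHD", "HC"])

    def test_closed_form_metrics(self):
        m = metrics(ConfusionCounts(tp=1, fp=1, fn=0, tn=19))
        assert m.precision == 0.5 and m.recall == 1.0
        assert m.f1 == pytest.approx(2 / 3) and m.specificity == pytest.approx(0.95)

    def test_undefined_precision_flagged(self):
        with pytest.warns(UserWarning):
            m = metrics(ConfusionCounts(tp=0, fp=0, fn=3, tn=5))
        assert m.precision == 0.0 and "precision" in m.undefined

    @given(
        st.integers(0, 200), st.integers(0, 200), st.integers(0, 200), st.integers(0, 200)
    )
    def test_random_counts_match_independent_formulas(self, tp, fp, fn, tn):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = metrics(ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn))
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        s = tn / (tn + fp) if tn + fp else 0.0
        assert m.precision == pytest.approx(p, abs=1e-12)
        assert m.recall == pytest.approx(r, abs=1e-12)
        assert m.specificity == pytest.approx(s, abs=1e-12)
        # harmonic-mean form equals the counting identity 2Tp/(2Tp+Fp+Fn)
        if tp:
            assert m.f1 == pytest.approx(2 * tp / (2 * tp + fp + fn), abs=1e-12)


class TestPrevalence:
    @pytest.mark.parametrize("p,expected", [(0.05, 20), (0.025, 40), (0.10, 10), (0.20, 5)])
    def test_hc_counts(self, p, expected):
        assert hc_count_for_prevalence(p) == expected

    @pytest.mark.parametrize("p", [0.0, -0.1, 0.6, 1.5])
    def test_out_of_range(self, p):
        with pytest.raises(InvalidConfigError):
            hc_count_for_prevalence(p)


class TestImbalancedPlan:
    def test_structure(self):
        plan = imbalanced_fold_plan(subjects(10, 60), 0.05, seed=1)
        assert len(plan.outer_folds) == 10
        for fold in plan.outer_folds:
            assert len(fold.inner) == 9
            assert len(fold.test) == 21  # 1 RHD + 20 HC
            for inner in fold.inner:
                assert len(inner.test) == 21

    def test_determinism_and_seed_sensitivity(self):
        subs = subjects(8, 60)
        a = imbalanced_fold_plan(subs, 0.05, seed=7)
        b = imbalanced_fold_plan(subs, 0.05, seed=7)
        c = imbalanced_fold_plan(subs, 0.05, seed=8)
        assert a.outer_folds == b.outer_folds
        assert a.outer_folds != c.outer_folds

    def test_insufficient_hc_pool(self):
        with pytest.raises(InvalidConfigError):
            imbalanced_fold_plan(subjects(10, 30), 0.025, seed=0)

    def test_no_hc_repeats_within_a_fold(self):
        plan = imbalanced_fold_plan(subjects(6, 50), 0.05, seed=2)
        for fold in plan.outer_folds:
            assert len(set(fold.test)) == len(fold.test)

    def test_audit_passes(self):
        validate_no_leakage(imbalanced_fold_plan(subjects(6, 50), 0.1, seed=3))


class TestStratifiedPlan:
    def test_fold_sizes_fullscale(self):
        plan = stratified_fold_plan(subjects(124, 127), k=10, seed=0)
        assert len(plan.outer_folds) == 10
        for fold in plan.outer_folds:
            rhd_test = sum(1 for s in fold.test if s.startswith("rhd"))
            hc_test = sum(1 for s in fold.test if s.startswith("hc"))
            assert rhd_test in (12, 13) and hc_test in (12, 13)
            assert len(fold.inner) == 10

    def test_partition_property(self):
        plan = stratified_fold_plan(subjects(20, 22), k=5, seed=1)
        seen = [s for fold in plan.outer_folds for s in fold.test]
        assert sorted(seen) == sorted(s for s, _ in subjects(20, 22))

    def test_class_smaller_than_k_rejected(self):
        with pytest.raises(InvalidConfigError):
            stratified_fold_plan(subjects(5, 40), k=10, seed=0)

    def test_leave_one_out_like_boundary(self):
        plan = stratified_fold_plan(subjects(5, 7), k=5, seed=2)
        assert len(plan.outer_folds) == 5


class TestLeakageAudit:
    def test_overlapping_fold_rejected(self):
        bad = FoldPlan(
            protocol=PROTOCOL_STRATIFIED,
            outer_folds=(Fold(train=("a", "b"), test=("b", "c")),),
            repeat_seed=0,
        )
        with pytest.raises(LeakageError):
            validate_no_leakage(bad)

    def test_inner_fold_touching_outer_test_rejected(self):
        bad = FoldPlan(
            protocol=PROTOCOL_STRATIFIED,
            outer_folds=(
                Fold(
                    train=("a", "b"),
                    test=("c",),
                    inner=(Fold(train=("a",), test=("c",)),),
                ),
            ),
            repeat_seed=0,
        )
        with pytest.raises(LeakageError):
            validate_no_leakage(bad)


class TestNestedCV:
    def test_separable_data_perfect_metrics(self):
        df = separable_features(12, 14)
        report = run_experiment(
            df, PROTOCOL_STRATIFIED, repeats=2, seed=0, k=3,
            c_grid=(1.0, 10.0), gamma_grid=(0.1, 0.01),
        )
        for rep in report.repeats:
            assert rep.metrics.recall == 1.0 and rep.metrics.precision == 1.0

    def test_each_rhd_subject_evaluated_once_per_repeat(self):
        df = separable_features(6, 50)
        plan = imbalanced_fold_plan(list(zip(df.subject_id, df.label)), 0.1, seed=4)
        result = run_nested_cv(plan, df, c_grid=(1.0,), gamma_grid=(0.1,))
        assert result.counts.tp + result.counts.fn == 6
        assert result.counts.fp + result.counts.tn == 6 * hc_count_for_prevalence(0.1)

    def test_noise_features_score_at_chance(self):
        # Oracle band established by repeated-seed simulation of the
        # no-signal condition: pooled f1 hovers around 0.3-0.55.
        f1s = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            df = separable_features(24, 24, seed=seed)
            df.iloc[:, 2:] = rng.standard_normal(df.iloc[:, 2:].shape)
            rep = run_experiment(
                df, PROTOCOL_STRATIFIED, repeats=1, seed=seed, k=3,
                c_grid=(0.1, 1.0, 10.0), gamma_grid=(0.1, 0.01),
            )
            f1s.append(rep.repeats[0].metrics.f1)
        assert 0.2 <= float(np.mean(f1s)) <= 0.7

    def test_precision_nondecreasing_in_prevalence_with_stubbed_classifier(self):
        # Fixed per-class error rates (fn 10%, fp 5%) applied directly to the
        # plans' test sets: expected precision rises with prevalence.
        rng = np.random.default_rng(0)
        subs = subjects(12, 90)
        mean_precision = []
        for p in (0.025, 0.05, 0.10, 0.20):
            precisions = []
            for seed in range(10):
                plan = imbalanced_fold_plan(subs, p, seed=seed)
                tp = fp = fn = tn = 0
                for fold in plan.outer_folds:
                    for sid in fold.test:
                        is_rhd = sid.startswith("rhd")
                        if is_rhd:
                            if rng.random() < 0.10:
                                fn += 1
                            else:
                                tp += 1
                        else:
                            if rng.random() < 0.05:
                                fp += 1
                            else:
                                tn += 1
                precisions.append(tp / (tp + fp))
            mean_precision.append(np.mean(precisions))
        assert all(b > a for a, b in zip(mean_precision, mean_precision[1:]))

    def test_report_serialization(self, tmp_path):
        df = separable_features(10, 12)
        report = run_experiment(
            df, PROTOCOL_STRATIFIED, repeats=2, seed=1, k=3,
            c_grid=(1.0,), gamma_grid=(0.1,),
        )
        path = report.save(tmp_path)
        import json

        data = json.loads(path.read_text())
        assert data["n_repeats"] == 2
        assert set(data["mean_std_percent"]) == {"f1", "recall", "precision", "specificity"}
        assert (tmp_path / "cv_report.txt").exists()

    def test_protocol_configuration_errors(self):
        df = separable_features(10, 12)
        with pytest.raises(InvalidConfigError):
            run_experiment(df, PROTOCOL_IMBALANCED, repeats=1, seed=0)
        with pytest.raises(InvalidConfigError):
            run_experiment(df, PROTOCOL_STRATIFIED, prevalence=0.05, repeats=1, seed=0)
        with pytest.raises(InvalidConfigError):
            run_experiment(df, "bootstrap", repeats=1, seed=0)
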