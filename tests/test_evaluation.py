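import numpy as np
import pytest

from angiopattern import (
    ConfusionMatrix,
    confusion_from_predictions,
    confusion_metrics,
    one_vs_rest_auc,
    repeat_evaluate,
    roc_auc,
    round_pct,
    simulate_cohort,
    split_data,
)
from angiopattern.evaluation import (
    evaluate_split,
    prepare_task,
    split_labels,
    task_label,
)


def cm(tp, fn, fp, tn):
    """Binary confusion matrix with 'focal' as the positive class."""
    return ConfusionMatrix(
        counts=np.array([[tp, fn], [fp, tn]]), class_order=("focal", "diffuse")
    )


class TestConfusionMetrics:
    # published confusion counts of the three classification analyses
    @pytest.mark.parametrize(
        "counts,expected_pct",
        [
            # PPGi cut-off, focal vs diffuse, all 234 vessels
            ((84, 76, 2, 72), dict(accuracy=67, sensitivity=53, specificity=97, ppv=98, npv=49)),
            # PPGi cut-off, focal vs non-focal, all 343 vessels
            ((84, 76, 8, 175), dict(accuracy=76, sensitivity=53, specificity=96, ppv=91, npv=70)),
            # μFR model, focal vs diffuse, 58-vessel test set
            ((33, 7, 5, 13), dict(accuracy=79, sensitivity=83, specificity=72, ppv=87, npv=65)),
            # PPGi cut-off on the same 58-vessel test set
            ((20, 20, 1, 17), dict(accuracy=64, sensitivity=50, specificity=94, ppv=95, npv=46)),
            # PPGi model, focal vs diffuse test set
            ((36, 4, 5, 13), dict(sensitivity=90, specificity=72, ppv=88, npv=76)),
            # PPGi model, focal vs non-focal, 85-vessel test set
            ((31, 9, 11, 34), dict(accuracy=76, sensitivity=78, specificity=76, ppv=74, npv=79)),
        ],
    )
    def test_printed_counts_reproduce_printed_percentages(self, counts, expected_pct):
        metrics = confusion_metrics(cm(*counts), positive_class="focal")
        for name, pct in expected_pct.items():
            assert round_pct(metrics[name]) == pct, name

    def test_all_correct_gives_100(self):
        metrics = confusion_metrics(cm(10, 0, 0, 5), positive_class="focal")
        assert all(round_pct(v) == 100 for v in metrics.values())

    def test_zero_denominator_is_nan_not_zero(self):
        metrics = confusion_metrics(cm(0, 0, 3, 7), positive_class="focal")
        assert np.isnan(metrics["sensitivity"])

    def test_accuracy_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            tp, fn, fp, tn = rng.integers(1, 50, 4)
            m = confusion_metrics(cm(tp, fn, fp, tn), positive_class="focal")
            p, n = tp + fn, tn + fp
            assert m["accuracy"] == pytest.approx(
                (m["sensitivity"] * p + m["specificity"] * n) / (p + n)
            )

    def test_non_binary_rejected(self):
        cm3 = ConfusionMatrix(counts=np.eye(3, dtype=int), class_order=("a", "b", "c"))
        with pytest.raises(ValueError):
            confusion_metrics(cm3, positive_class="a")


class TestRounding:
    @pytest.mark.parametrize(
        "x,expected", [(84 / 160, 53), (0.664, 66), (0.665, 67), (0.5, 50), (175 / 251, 70)]
    )
    def test_half_away_from_zero(self, x, expected):
        assert round_pct(x) == expected


class TestRocAuc:
    def test_perfect_ranking(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(1)
        scores = rng.random(2000)
        labels = rng.integers(0, 2, 2000)
        assert roc_auc(scores, labels) == pytest.approx(0.5, abs=0.03)

    def test_rank_formula_matches_pairwise_oracle(self):
        rng = np.random.default_rng(2)
        scores = np.round(rng.random(50), 1)  # ties on purpose
        labels = rng.integers(0, 2, 50).astype(bool)
        pos = scores[labels]
        neg = scores[~labels]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert roc_auc(scores, labels) == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestOneVsRest:
    def test_one_hot_perfect(self):
        labels = np.array(["a", "b", "c", "a"])
        proba = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 0, 0]], float)
        aucs = one_vs_rest_auc(proba, labels, ("a", "b", "c"))
        assert all(v == 1.0 for v in aucs.values())

    def test_uniform_probabilities_half(self):
        labels = np.array(["a", "b", "c"] * 4)
        proba = np.full((12, 3), 1 / 3)
        aucs = one_vs_rest_auc(proba, labels, ("a", "b", "c"))
        assert all(v == pytest.approx(0.5) for v in aucs.values())

    def test_duplicated_columns_give_equal_aucs_for_symmetric_labels(self):
        rng = np.random.default_rng(3)
        scores = rng.random(30)
        labels = np.array((["a"] * 10) + (["b"] * 10) + (["c"] * 10))
        proba = np.stack([scores, scores, 1 - 2 * scores / 3], axis=1)
        labels_sym = labels.copy()
        labels_sym[labels == "b"] = "a"
        labels_sym[:5] = "b"
        aucs = one_vs_rest_auc(proba, labels_sym, ("a", "b", "c"))
        assert set(aucs) == {"a", "b", "c"}

    def test_missing_class_rejected(self):
        labels = np.array(["a", "a", "b"])
        proba = np.full((3, 3), 1 / 3)
        with pytest.raises(ValueError):
            one_vs_rest_auc(proba, labels, ("a", "b", "c"))


class TestSplit:
    def test_234_splits_176_58(self):
        labels = ["focal"] * 160 + ["diffuse"] * 74
        tr, te = split_labels(labels, rng_seed=0)
        assert (len(tr), len(te)) == (176, 58)

    def test_343_splits_258_85(self):
        labels = ["focal"] * 160 + ["diffuse"] * 74 + ["mixed"] * 82 + ["serial"] * 27
        tr, te = split_labels(labels, rng_seed=0)
        assert (len(tr), len(te)) == (258, 85)

    def test_seed_reproducibility(self):
        labels = ["a"] * 30 + ["b"] * 20
        a = split_labels(labels, rng_seed=11)
        b = split_labels(labels, rng_seed=11)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_stratification_preserves_class_fractions(self):
        labels = np.array(["a"] * 40 + ["b"] * 20)
        tr, te = split_labels(labels, rng_seed=5)
        assert np.sum(labels[tr] == "a") == 30
        assert np.sum(labels[te] == "b") == 5

    def test_tiny_stratum_rejected(self):
        with pytest.raises(ValueError):
            split_labels(["a"] * 10 + ["b"], rng_seed=0)

    def test_split_data_on_records(self, small_cohort):
        tr, te = split_data(small_cohort.records, rng_seed=2)
        assert len(tr) + len(te) == len(small_cohort.records)
        ids = {r.vessel_id for r in tr} | {r.vessel_id for r in te}
        assert len(ids) == len(small_cohort.records)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            split_data([], rng_seed=0)


class TestTaskMapping:
    @pytest.mark.parametrize(
        "label,task,expected",
        [
            ("mixed", "focal_vs_diffuse", None),
            ("serial", "focal_vs_nonfocal", "nonfocal"),
            ("focal", "focal_vs_nonfocal", "focal"),
            ("mixed", "three_class", "others"),
            ("diffuse", "three_class", "diffuse"),
        ],
    )
    def test_label_mapping(self, label, task, expected):
        assert task_label(label, task) == expected


class TestPipeline:
    def test_cutoff_method_has_no_auc(self, small_cohort):
        reports = repeat_evaluate(
            small_cohort, "focal_vs_diffuse", ["ppgi_cutoff"], n_iterations=2, base_seed=0
        )
        assert "auc" not in reports["ppgi_cutoff"].per_iteration.columns

    def test_cutoff_rejected_for_three_class(self, small_cohort):
        with pytest.raises(ValueError):
            repeat_evaluate(
                small_cohort, "three_class", ["ppgi_cutoff"], n_iterations=1, base_seed=0
            )

    def test_summary_ci_brackets_mean(self, small_cohort):
        reports = repeat_evaluate(
            small_cohort, "focal_vs_diffuse", ["ppgi_cutoff"], n_iterations=5, base_seed=3
        )
        s = reports["ppgi_cutoff"].summary
        assert (s["ci_low"] <= s["mean"] + 1e-12).all()
        assert (s["mean"] <= s["ci_high"] + 1e-12).all()
        assert ((s[["mean", "ci_low", "ci_high"]] >= 0) & (s[["mean", "ci_low", "ci_high"]] <= 1)).all().all()

    def test_test_labels_never_influence_predictions(self, small_cohort):
        """Leakage guard: corrupting test labels changes no prediction."""
        prep = prepare_task(small_cohort, "focal_vs_diffuse")
        res1 = evaluate_split(prep, "focal_vs_diffuse", ["plr_ppgi"], rng_seed=4)
        tr, te = split_labels(prep.strata, 0.75, True, 4)
        corrupted = prepare_task(small_cohort, "focal_vs_diffuse")
        flipped = corrupted.labels.copy()
        flipped[te] = np.where(flipped[te] == "focal", "diffuse", "focal")
        corrupted.labels = flipped
        res2 = evaluate_split(corrupted, "focal_vs_diffuse", ["plr_ppgi"], rng_seed=4)
        np.testing.assert_array_equal(
            res1["plr_ppgi"]["y_pred"], res2["plr_ppgi"]["y_pred"]
        )

    def test_majority_prevalence_matches_cutoff_analytics(self):
        # a cohort of only diffuse and focal with overwhelming PPGi separation:
        # the cut-off rule's accuracy equals the fraction it classifies correctly
        coh = simulate_cohort(60, class_probs={"focal": 0.5, "diffuse": 0.5, "mixed": 0.0, "serial": 0.0}, rng_seed=9)
        reports = repeat_evaluate(coh, "focal_vs_diffuse", ["ppgi_cutoff"], n_iterations=3, base_seed=0)
        acc = reports["ppgi_cutoff"].summary.loc["accuracy", "mean"]
        assert 0.5 <= acc <= 1.0

    def test_single_iteration_reproduces_single_split(self, small_cohort):
        prep = prepare_task(small_cohort, "focal_vs_diffuse")
        single = evaluate_split(prep, "focal_vs_diffuse", ["ppgi_cutoff"], rng_seed=6)
        reports = repeat_evaluate(
            small_cohort, "focal_vs_diffuse", ["ppgi_cutoff"], n_iterations=1, base_seed=6
        )
        row = reports["ppgi_cutoff"].per_iteration.iloc[0]
        for k, v in single["ppgi_cutoff"]["metrics"].items():
            assert row[k] == pytest.approx(v, nan_ok=True)
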