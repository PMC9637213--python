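import numpy as np
import pytest

from eegcsp.errors import ConfigurationError, SchemaError
from eegcsp.evaluate import (
    ClassifierResult,
    GridConfig,
    SplitSpec,
    evaluate_classifier,
    metrics_from_counts,
    run_grid,
    stratified_split,
    train,
)
from eegcsp.montage import default_grid
from eegcsp.synthetic import (
    SyntheticConfig,
    default_config,
    generate_cohort,
    null_config,
)


def manifest_of(n_control, n_pd):
    return [(f"control_{i:02d}", "control") for i in range(n_control)] + [
        (f"pd_{i:02d}", "pd") for i in range(n_pd)
    ]


class TestStratifiedSplit:
    def test_25_25_at_60_percent(self):
        split = stratified_split(manifest_of(25, 25), 0.6, seed=0)
        learn_pd = [i for i in split.learning_ids if i.startswith("pd")]
        learn_ctl = [i for i in split.learning_ids if i.startswith("control")]
        assert len(learn_pd) == 15 and len(learn_ctl) == 15
        valid_pd = [i for i in split.validation_ids if i.startswith("pd")]
        valid_ctl = [i for i in split.validation_ids if i.startswith("control")]
        assert len(valid_pd) == 10 and len(valid_ctl) == 10

    def test_2_2_at_half(self):
        split = stratified_split(manifest_of(2, 2), 0.5, seed=1)
        assert len(split.learning_ids) == 2
        assert len(split.validation_ids) == 2

    def test_deterministic(self):
        a = stratified_split(manifest_of(10, 10), 0.6, seed=7)
        b = stratified_split(manifest_of(10, 10), 0.6, seed=7)
        assert a == b

    def test_seed_changes_split(self):
        a = stratified_split(manifest_of(10, 10), 0.6, seed=1)
        b = stratified_split(manifest_of(10, 10), 0.6, seed=2)
        assert a != b

    def test_disjoint_and_covering(self):
        split = stratified_split(manifest_of(9, 7), 0.6, seed=3)
        all_ids = set(split.learning_ids) | set(split.validation_ids)
        assert all_ids == {rid for rid, _ in manifest_of(9, 7)}
        assert not set(split.learning_ids) & set(split.validation_ids)

    def test_bad_fraction(self):
        with pytest.raises(ConfigurationError):
            stratified_split(manifest_of(4, 4), 1.2, seed=0)

    def test_tiny_group_rejected(self):
        with pytest.raises(ConfigurationError):
            stratified_split([("a", "control"), ("b", "pd")], 0.6, seed=0)

    def test_save_load_and_hash_guard(self, tmp_path):
        split = stratified_split(manifest_of(5, 5), 0.6, seed=0)
        path = tmp_path / "split.json"
        split.save(path)
        assert SplitSpec.load(path) == split
        # tampering is detected
        tampered = path.read_text().replace("pd_00", "pd_99")
        path.write_text(tampered)
        with pytest.raises(ConfigurationError, match="hash"):
            SplitSpec.load(path)

    def test_overlapping_split_rejected(self):
        with pytest.raises(ConfigurationError):
            SplitSpec(("a", "b"), ("b", "c"))


class TestMetrics:
    def test_paper_85_70_100(self):
        # the unique confusion realization on a 10+10 validation set
        assert metrics_from_counts(7, 3, 10, 0) == (85.0, 70.0, 100.0)

    def test_paper_90_80_100(self):
        assert metrics_from_counts(8, 2, 10, 0) == (90.0, 80.0, 100.0)

    def test_all_correct(self):
        assert metrics_from_counts(10, 0, 10, 0) == (100.0, 100.0, 100.0)

    def test_consistency_with_stored_predictions(self):
        result = ClassifierResult(
            classifier="x", feature_desc="y",
            record_ids=("a", "b", "c", "d"),
            y_true=("pd", "pd", "control", "control"),
            y_pred=("pd", "control", "control", "pd"),
        )
        tp, fn, tn, fp = result.counts
        assert (tp, fn, tn, fp) == (1, 1, 1, 1)
        assert result.accuracy == 100.0 * (tp + tn) / 4
        assert result.sensitivity == 100.0 * tp / (tp + fn)
        assert result.specificity == 100.0 * tn / (tn + fp)

    def test_label_swap_swaps_se_sp(self):
        y_true = ("pd", "pd", "pd", "control", "control")
        y_pred = ("pd", "control", "pd", "control", "pd")
        base = ClassifierResult("c", "f", tuple("abcde"), y_true, y_pred)
        flip = {"pd": "control", "control": "pd"}
        swapped = ClassifierResult(
            "c", "f", tuple("abcde"),
            tuple(flip[v] for v in y_true),
            tuple(flip[v] for v in y_pred),
        )
        assert base.accuracy == swapped.accuracy
        assert base.sensitivity == swapped.specificity
        assert base.specificity == swapped.sensitivity


class TestTrain:
    def test_separable_lda(self):
        X = np.array([[0.0], [0.1], [0.2], [5.0], [5.1], [5.2]])
        y = ["control"] * 3 + ["pd"] * 3
        model = train("lda", X, y)
        result = evaluate_classifier(model, X, y)
        assert result.accuracy == 100.0

    def test_constant_feature_predicts_majority(self):
        X = np.zeros((5, 1))
        y = ["pd", "pd", "pd", "control", "control"]
        model = train("tree", X, y)  # no split possible -> majority class
        assert list(model.predict(np.zeros((2, 1)))) == ["pd", "pd"]

    def test_xor_rbf_vs_lda(self):
        X = np.array(
            [[0, 0], [1, 1], [0, 1], [1, 0]] * 10, dtype=float
        ) + 0.01 * np.random.default_rng(0).standard_normal((40, 2))
        y = (["control", "control", "pd", "pd"] * 10)
        rbf = train("svm_rbf", X, y)
        lda = train("lda", X, y)
        rbf_acc = evaluate_classifier(rbf, X, y).accuracy
        lda_acc = evaluate_classifier(lda, X, y).accuracy
        assert rbf_acc == 100.0
        assert 30.0 <= lda_acc <= 70.0

    def test_single_class_rejected(self):
        with pytest.raises(SchemaError):
            train("lda", np.zeros((3, 2)), ["pd", "pd", "pd"])

    def test_length_mismatch_rejected(self):
        with pytest.raises(SchemaError):
            train("lda", np.zeros((3, 2)), ["pd", "control"])

    def test_unknown_kind(self):
        with pytest.raises(ConfigurationError):
            train("forest", np.zeros((4, 2)), ["pd", "pd", "control", "control"])

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((20, 3))
        y = ["pd"] * 10 + ["control"] * 10
        for kind in ("svm_poly", "svm_rbf", "bayes", "lda", "qda", "tree"):
            a = train(kind, X, y, seed=3).predict(X)
            b = train(kind, X, y, seed=3).predict(X)
            assert list(a) == list(b)

    def test_unknown_labels_rejected_at_evaluation(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        model = train("lda", X, ["pd", "pd", "control", "control"])
        with pytest.raises(SchemaError):
            evaluate_classifier(model, X, ["pd", "patient", "control", "control"])


def tiny_cohort(seed=0, n_per_group=4, planted=6.0):
    config = default_config(
        n_subjects_per_group=n_per_group,
        seed=seed,
        planted_gain_uv=planted,
        channel_labels=("Fz", "F3", "F4", "Cz", "C3", "C4", "Pz", "Oz"),
        record_duration_s=20.0,
        events_per_task={"Standard": 3},
        noise_sigma=1.0,
    )
    return config, *generate_cohort(config)


class TestRunGrid:
    def _split(self, records):
        return stratified_split(
            [(r.subject_id, r.group) for r in records], 0.6, seed=0
        )

    def test_restricted_grid_row_count(self):
        _, records, _ = tiny_cohort()
        config = GridConfig(
            high_hz=(20.0,),
            interval_lengths_ms=(500.0,),
            feature_kinds=("csp",),
            csp_component_sets=(("MxPMnC1",), ("MxPMnC1", "MnPMxC1")),
            classifiers=("lda",),
            numtaps=501,
        )
        table = run_grid(records, self._split(records), config)
        assert len(table) == 2  # one row per feature subset

    def test_metric_identities_on_every_row(self):
        _, records, _ = tiny_cohort()
        config = GridConfig(
            high_hz=(20.0,), interval_lengths_ms=(500.0,),
            feature_kinds=("csp",),
            csp_component_sets=(("MxPMnC1", "MxPMnC2"),),
            classifiers=("lda", "bayes"), numtaps=501,
        )
        table = run_grid(records, self._split(records), config)
        for _, row in table.iterrows():
            n = row.tp + row.fn + row.tn + row.fp
            assert row.accuracy == pytest.approx(100 * (row.tp + row.tn) / n)
            assert row.sensitivity == pytest.approx(
                100 * row.tp / (row.tp + row.fn)
            )
            assert row.specificity == pytest.approx(
                100 * row.tn / (row.tn + row.fp)
            )

    def test_infeasible_masks_skipped(self):
        config60 = default_config(
            n_subjects_per_group=3,
            record_duration_s=20.0,
            events_per_task={"Standard": 3},
            seed=1,
        )
        records, _ = generate_cohort(config60)
        from eegcsp.laplacian import LaplacianMaskSpec

        grid_config = GridConfig(
            high_hz=(20.0,), interval_lengths_ms=(500.0,),
            feature_kinds=("laplacian",),
            laplacian_mask_sets=(
                (LaplacianMaskSpec("Fz", 1),),
                (LaplacianMaskSpec("Fp1", 2),),  # no cell two rows above Fp1
            ),
            classifiers=("lda",), numtaps=501,
        )
        table = run_grid(records, self._split(records), grid_config)
        assert len(table) == 1
        assert table.iloc[0]["feature_desc"] == "Fz"

    def test_no_validation_leakage(self):
        # the CSP model inside run_grid must equal one fitted on the
        # learning set alone; perturbing a validation record must not
        # change any learning-set feature, hence not the fitted model's
        # behavior on the learning set
        _, records, _ = tiny_cohort(seed=3)
        split = self._split(records)
        config = GridConfig(
            high_hz=(20.0,), interval_lengths_ms=(500.0,),
            feature_kinds=("csp",), csp_component_sets=(("MxPMnC1",),),
            classifiers=("lda",), numtaps=501,
        )
        base = run_grid(records, split, config)

        perturbed = []
        valid_set = set(split.validation_ids)
        for r in records:
            if r.subject_id in valid_set and r.group == "pd":
                perturbed.append(r.copy_with(r.data * 3.0 + 1.0))
            else:
                perturbed.append(r)
        shifted = run_grid(perturbed, split, config)
        # learning-only quantities unchanged: same feature description and
        # same model => control-record predictions driven by same boundary.
        assert base.iloc[0]["feature_desc"] == shifted.iloc[0]["feature_desc"]
        # specificity (control validation records untouched) is identical
        assert base.iloc[0]["specificity"] == shifted.iloc[0]["specificity"]

    def test_strong_planted_difference_classified(self):
        _, records, _ = tiny_cohort(seed=11, n_per_group=6, planted=10.0)
        split = self._split(records)
        config = GridConfig(
            high_hz=(20.0,), interval_lengths_ms=(500.0,),
            feature_kinds=("csp",),
            csp_component_sets=(("MxPMnC1",), ("MxPMnC1", "MxPMnC2")),
            classifiers=("lda", "bayes"), numtaps=501,
        )
        table = run_grid(records, split, config)
        assert table["accuracy"].max() >= 75.0

    def test_null_calibration_mean_near_chance(self):
        # scaled-down Monte-Carlo: 20 null cohorts; mean validation
        # accuracy within a 3-sigma binomial band of 50%
        accs = []
        for rep in range(20):
            base_config, _, _ = tiny_cohort(seed=100 + rep, n_per_group=5)
            config = null_config(base_config, seed=200 + rep)
            records, _ = generate_cohort(config)
            split = self._split(records)
            grid_config = GridConfig(
                high_hz=(20.0,), interval_lengths_ms=(500.0,),
                feature_kinds=("csp",), csp_component_sets=(("MxPMnC1",),),
                classifiers=("lda",), numtaps=501,
            )
            table = run_grid(records, split, grid_config)
            accs.append(table.iloc[0]["accuracy"])
        n_bernoulli = 20 * 4  # 4 validation records per repetition
        band = 3 * 50.0 / np.sqrt(n_bernoulli)
        assert abs(np.mean(accs) - 50.0) <= band

    def test_unknown_record_in_split(self):
        _, records, _ = tiny_cohort()
        split = SplitSpec(("ghost",), tuple(r.subject_id for r in records))
        with pytest.raises(SchemaError, match="ghost"):
            run_grid(records, split, GridConfig(numtaps=501))
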