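"""Repeated-run classification protocol: split, SMOTE, runs, error analysis."""

import numpy as np
import pytest

from ptsdlang.features import reduce_features
from ptsdlang.ml import (
    ModelSpec,
    error_analysis,
    repeated_runs,
    smote_oversample,
    stratified_split,
    train_eval_run,
)
from ptsdlang.registry import FeatureTable, default_registry
from ptsdlang.synthetic import binary_labels, strata_map


def _toy_table(n=60, p=8, seed=0, effect=0.0):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, p))
    X[:, 0] += effect * y
    X[:, 1] += effect * y
    names = default_registry().retained_names[:p]
    table = FeatureTable([f"d{i:03d}" for i in range(n)], X,
                         default_registry(), names=names)
    labels = {d: int(v) for d, v in zip(table.doc_ids, y)}
    strata = {d: labels[d] for d in table.doc_ids}
    return table, labels, strata


class TestStratifiedSplit:
    def test_cohort_arithmetic(self):
        ids = [f"d{i}" for i in range(148)]
        strata = {d: ("A1" if i < 110 else "A2", i % 3)
                  for i, d in enumerate(ids)}
        train, test = stratified_split(ids, strata, seed=1)
        assert len(test) == 30 and len(train) == 118
        assert set(train) | set(test) == set(ids)
        assert not set(train) & set(test)

    def test_per_stratum_share_within_one(self):
        ids = [f"d{i}" for i in range(148)]
        strata = {d: ("A1" if i < 110 else "A2") for i, d in enumerate(ids)}
        _, test = stratified_split(ids, strata, seed=3)
        n_a2 = sum(strata[d] == "A2" for d in test)
        assert abs(n_a2 - 0.2 * 38) <= 1 + 1  # rounding + global repair

    def test_deterministic(self):
        ids = [f"d{i}" for i in range(40)]
        strata = {d: i % 4 for i, d in enumerate(ids)}
        assert stratified_split(ids, strata, seed=9) == stratified_split(
            ids, strata, seed=9)

    def test_singleton_stratum_rejected(self):
        strata = {"a": 0, "b": 0, "c": 1}
        with pytest.raises(ValueError, match="merge"):
            stratified_split(["a", "b", "c"], strata)


class TestSmote:
    def test_balanced_input_unchanged(self):
        X = np.arange(20.0).reshape(10, 2)
        y = np.repeat([0, 1], 5)
        X2, y2 = smote_oversample(X, y, k_neighbors=3)
        np.testing.assert_array_equal(X2, X)
        np.testing.assert_array_equal(y2, y)

    def test_synthetic_points_lie_on_minority_segments(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0, 1, (30, 3)), rng.normal(4, 1, (9, 3))])
        y = np.r_[np.zeros(30, int), np.ones(9, int)]
        X2, y2 = smote_oversample(X, y, k_neighbors=5, seed=1)
        assert (y2 == 1).sum() == (y2 == 0).sum()
        minority = X[y == 1]
        for row in X2[len(X):]:
            found = False
            for i in range(len(minority)):
                for j in range(len(minority)):
                    if i == j:
                        continue
                    seg = minority[j] - minority[i]
                    denom = seg @ seg
                    if denom == 0:
                        continue
                    lam = (row - minority[i]) @ seg / denom
                    if -1e-9 <= lam <= 1 + 1e-9 and np.allclose(
                            minority[i] + lam * seg, row, atol=1e-8):
                        found = True
                        break
                if found:
                    break
            assert found, "synthetic point off all minority segments"

    def test_tiny_minority_rejected(self):
        X = np.random.default_rng(0).normal(size=(13, 2))
        y = np.r_[np.zeros(10, int), np.ones(3, int)]
        with pytest.raises(ValueError, match="k_neighbors"):
            smote_oversample(X, y, k_neighbors=5)


class TestTrainEval:
    def test_separable_data_perfect_auc(self):
        table, labels, strata = _toy_table(effect=8.0)
        split = stratified_split(table.doc_ids, strata, seed=0)
        run = train_eval_run(ModelSpec("logistic_elasticnet"), split, table,
                             labels, seed=0)
        assert run.roc_auc == 1.0

    def test_shuffled_labels_chance_level(self):
        table, labels, strata = _toy_table(effect=0.0, n=100)
        aucs = []
        for seed in range(8):
            split = stratified_split(table.doc_ids, strata, seed=seed)
            run = train_eval_run(ModelSpec("logistic_elasticnet"), split,
                                 table, labels, seed=seed)
            aucs.append(run.roc_auc)
        assert 0.35 <= np.mean(aucs) <= 0.65

    def test_constant_feature_gets_zero_coefficient(self):
        table, labels, strata = _toy_table(effect=3.0)
        table.values[:, -1] = 7.0  # constant column
        split = stratified_split(table.doc_ids, strata, seed=2)
        run = train_eval_run(ModelSpec("logistic_elasticnet"), split, table,
                             labels, seed=2)
        assert run.importances[-1] == pytest.approx(0.0, abs=1e-6)

    def test_no_information_flow_from_test_fold(self):
        table, labels, strata = _toy_table(effect=2.0)
        split = stratified_split(table.doc_ids, strata, seed=5)
        run1 = train_eval_run(ModelSpec("logistic_elasticnet"), split, table,
                              labels, seed=5)
        # perturb the test rows only: fitted model must be unchanged
        mutated = FeatureTable(table.doc_ids, table.values.copy(),
                               table.registry, names=table.names)
        idx = {d: i for i, d in enumerate(table.doc_ids)}
        for d in split[1]:
            mutated.values[idx[d]] += 100.0
        run2 = train_eval_run(ModelSpec("logistic_elasticnet"), split,
                              mutated, labels, seed=5)
        np.testing.assert_allclose(run1.importances, run2.importances)


class TestRepeatedRuns:
    def test_summary_deterministic(self):
        table, labels, strata = _toy_table(effect=1.0)
        s1 = repeated_runs(ModelSpec("logistic_elasticnet"), table, labels,
                           strata, n_runs=10, base_seed=3)
        s2 = repeated_runs(ModelSpec("logistic_elasticnet"), table, labels,
                           strata, n_runs=10, base_seed=3)
        assert s1.mean_auc == s2.mean_auc
        np.testing.assert_array_equal(s1.mean_importances,
                                      s2.mean_importances)

    def test_anti_labels_mirror_auc_of_fixed_model(self):
        # a trained model scored against flipped test labels mirrors its AUC
        from sklearn.metrics import roc_auc_score

        table, labels, strata = _toy_table(effect=1.5)
        split = stratified_split(table.doc_ids, strata, seed=1)
        run = train_eval_run(ModelSpec("logistic_elasticnet"), split, table,
                             labels, seed=1)
        y = [labels[d] for d in run.test_ids]
        scores = [run.test_scores[d] for d in run.test_ids]
        anti_auc = roc_auc_score([1 - v for v in y], scores)
        assert run.roc_auc == pytest.approx(1 - anti_auc)

    def test_planted_features_dominate_importances(self, small_bundle,
                                                   lexicons):
        # end-to-end on synthetic text with planted lexical effects
        from ptsdlang.corpus_io import tokenize
        from ptsdlang.features import extract_all
        from ptsdlang.synthetic import PlantedEffect, generate_corpus

        from .conftest import small_config

        cfg = small_config(
            n_docs=148, exposure_split=(110, 38), diagnosis_split=(70, 42, 36),
            planted_effects=[PlantedEffect("model_death", d=1.5),
                             PlantedEffect("model_body", d=1.5)],
            seed=13)
        corpus, meta, _ = generate_corpus(cfg)
        table = reduce_features(
            extract_all([tokenize(t) for t in corpus], lexicons))
        summary = repeated_runs(
            ModelSpec("logistic_elasticnet"), table, binary_labels(meta),
            strata_map(meta), n_runs=30, base_seed=0)
        assert summary.mean_auc >= 0.8
        top = [n for n, _ in summary.ranked_importances()[:4]]
        assert {"model_death", "model_body"} <= set(top)


class TestErrorAnalysis:
    def _summary(self, freqs, appearances=None):
        from ptsdlang.ml import RunSummary

        ids = sorted(freqs)
        return RunSummary(
            family="logistic_elasticnet", mean_auc=0.7, std_auc=0.05,
            n_runs=10, feature_names=["f"], mean_importances=np.zeros(1),
            misclassification_frequency=freqs,
            test_appearances=appearances or {d: 5 for d in ids})

    def _metadata(self, ids, exposure_fn):
        from ptsdlang.corpus_io import MetadataRecord

        return [MetadataRecord(
            doc_id=d, exposure=exposure_fn(d), diagnosis="no_ptsd",
            criteria=dict.fromkeys("BCDEG", False), sex="F", age=30.0,
            single=False, living_alone=False) for d in ids]

    def test_no_errors_reported(self):
        ids = [f"d{i:02d}" for i in range(30)]
        summary = self._summary({d: 0.0 for d in ids})
        report = error_analysis(summary, self._metadata(ids, lambda d: "A1"),
                                power_reps=0)
        assert report.get("no_errors") is True
        assert report["tests"] == {}

    def test_tie_break_is_deterministic_by_doc_id(self):
        ids = [f"d{i:02d}" for i in range(30)]
        summary = self._summary({d: 0.5 for d in ids})
        r1 = error_analysis(summary, self._metadata(ids, lambda d: "A1"),
                            power_reps=0)
        r2 = error_analysis(summary, self._metadata(ids, lambda d: "A1"),
                            power_reps=0)
        assert r1["worst_documents"] == sorted(ids)[:20]
        assert r1["worst_documents"] == r2["worst_documents"]

    def test_planted_stratum_concentration_detected(self):
        # errors concentrated in the A2 exposure stratum are flagged
        ids = [f"d{i:02d}" for i in range(60)]
        exposure = {d: ("A2" if i < 22 else "A1")
                    for i, d in enumerate(ids)}
        freqs = {d: (0.9 if exposure[d] == "A2" else 0.05) for d in ids}
        summary = self._summary(freqs)
        report = error_analysis(summary, self._metadata(
            ids, lambda d: exposure[d]), power_reps=0)
        assert report["tests"]["exposure"].significant
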