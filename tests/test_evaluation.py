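import numpy as np
import pytest

import methgen as mg
from methgen.evaluation import EvaluationError, train_classifiers

from .oracles import auc_pair_counting


@pytest.fixture(scope="module")
def four_cond_data():
    spec = mg.SyntheticSpec(
        n_conditions=4, n_cpgs=60, n_samples_per_condition=30,
        mean_separation=0.3, frac_informative=0.8,
        concentration_range=(20.0, 40.0), seed=31,
    )
    m, lab, _ = mg.generate_ground_truth(spec)
    return m, lab


class TestSplit:
    def test_disjoint_exhaustive(self, four_cond_data):
        m, lab = four_cond_data
        (a, la), (b, lb) = mg.split_data(m, lab, seed=1)
        assert set(a.sample_ids) | set(b.sample_ids) == set(m.sample_ids)
        assert set(a.sample_ids) & set(b.sample_ids) == set()

    def test_stratified_proportions_within_one_sample(self, four_cond_data):
        m, lab = four_cond_data
        (a, la), (b, lb) = mg.split_data(m, lab, train_fraction=0.7, seed=2)
        for cond in lab.vocabulary:
            n_total = lab.labels.count(cond)
            n_a = la.labels.count(cond)
            assert abs(n_a - 0.7 * n_total) <= 1

    def test_reproducible(self, four_cond_data):
        m, lab = four_cond_data
        (a1, _), _ = mg.split_data(m, lab, seed=5)
        (a2, _), _ = mg.split_data(m, lab, seed=5)
        assert a1.sample_ids == a2.sample_ids

    def test_singleton_condition_errors(self):
        m = mg.BetaMatrix(["s1", "s2", "s3"], ["cg1"],
                          np.array([[0.1], [0.2], [0.3]]))
        lab = mg.ConditionVector(["A", "A", "B"])
        with pytest.raises(EvaluationError, match="'B'"):
            mg.split_data(m, lab)


class TestClassifiers:
    def test_all_five_fit_and_beat_chance_on_train(self, four_cond_data):
        m, lab = four_cond_data
        clfs = train_classifiers(m, lab, seed=0)
        chance = 1.0 / lab.n_conditions
        y = np.array(lab.labels)
        for tag, model in clfs.models.items():
            acc = (model.predict(m.values) == y).mean()
            assert acc >= chance, tag

    def test_svm_separable_fixture_high_accuracy(self, separable_fixture):
        m, lab, _ = separable_fixture
        clfs = train_classifiers(m, lab, algorithms=["SVM"], seed=0)
        acc = (clfs.models["SVM"].predict(m.values) == np.array(lab.labels)).mean()
        assert acc >= 0.95

    def test_unknown_algorithm(self, four_cond_data):
        m, lab = four_cond_data
        with pytest.raises(EvaluationError, match="XGB"):
            train_classifiers(m, lab, algorithms=["XGB"])


class TestOneVsRestAUC:
    def test_perfect_separation(self):
        scores = np.array([[2.0, -1], [1.5, -1], [-1, 2.0], [-1, 1.5]])
        auc = mg.one_vs_rest_auc(scores, ["A", "A", "B", "B"], ["A", "B"])
        assert auc == {"A": 1.0, "B": 1.0}

    def test_constant_scores_give_half(self):
        scores = np.zeros((6, 2))
        auc = mg.one_vs_rest_auc(scores, ["A"] * 3 + ["B"] * 3, ["A", "B"])
        assert auc["A"] == pytest.approx(0.5)

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(9)
        intended = list("AABBBA")
        scores = rng.normal(size=(6, 2))
        auc = mg.one_vs_rest_auc(scores, intended, ["A", "B"])
        for k, cond in enumerate(["A", "B"]):
            pos = [scores[i, k] for i, c in enumerate(intended) if c == cond]
            neg = [scores[i, k] for i, c in enumerate(intended) if c != cond]
            assert auc[cond] == pytest.approx(auc_pair_counting(pos, neg))

    def test_condition_without_negatives_undefined(self):
        auc = mg.one_vs_rest_auc(np.zeros((2, 1)), ["A", "A"], ["A"])
        assert np.isnan(auc["A"])


class TestEvaluateGenerated:
    def test_replayed_real_samples_recover_heldout_accuracy(self, four_cond_data):
        """Replaying held-out samples as a 'generator' reduces to plain
        held-out classification accuracy."""
        m, lab = four_cond_data
        (train, ltrain), (test, ltest) = mg.split_data(m, lab, 0.5, seed=3)
        clfs = train_classifiers(train, ltrain, algorithms=["SVM"], seed=0)
        batch = []
        idx = ltest.indices()
        for ci, cond in enumerate(ltest.vocabulary):
            rows = np.flatnonzero(idx == ci)
            batch.append((test.subset_samples(rows), cond))
        report = mg.evaluate_generated(clfs, batch)
        direct = (clfs.models["SVM"].predict(test.values)
                  == np.array(ltest.labels)).mean()
        assert report.records[0]["accuracy"] == pytest.approx(direct)

    def test_mislabelled_generator_scores_near_zero(self, separable_fixture):
        m, lab, _ = separable_fixture
        clfs = train_classifiers(m, lab, algorithms=["SVM"], seed=0)
        a, b = lab.vocabulary
        rows_a = np.flatnonzero(lab.indices() == 0)
        report = mg.evaluate_generated(clfs, [(m.subset_samples(rows_a), b)])
        assert report.records[0]["per_condition_accuracy"][b] <= 0.05

    def test_confusion_rows_sum_to_counts(self, four_cond_data):
        m, lab = four_cond_data
        clfs = train_classifiers(m, lab, algorithms=["DT"], seed=0)
        idx = lab.indices()
        batch = [
            (m.subset_samples(np.flatnonzero(idx == ci)), cond)
            for ci, cond in enumerate(lab.vocabulary)
        ]
        report = mg.evaluate_generated(clfs, batch)
        confusion = report.records[0]["confusion"]
        for ci, cond in enumerate(lab.vocabulary):
            assert confusion[ci].sum() == lab.labels.count(cond)
        assert report.records[0]["accuracy"] == pytest.approx(
            np.trace(confusion) / confusion.sum()
        )

    def test_cpg_mismatch_rejected(self, four_cond_data):
        m, lab = four_cond_data
        clfs = train_classifiers(m, lab, algorithms=["DT"], seed=0)
        other = mg.BetaMatrix(["x"], ["different_cg"], np.array([[0.5]]))
        with pytest.raises(EvaluationError, match="differ"):
            mg.evaluate_generated(clfs, [(other, lab.vocabulary[0])])


class TestEmbedding:
    def test_one_row_per_sample_and_default_3d(self, four_cond_data):
        m, lab = four_cond_data
        out = mg.embed_tsne(m, real_labels=lab, seed=0, perplexity=10)
        assert len(out) == m.n_samples
        assert {"tsne1", "tsne2", "tsne3"} <= set(out.columns)

    def test_reproducible(self, four_cond_data):
        m, lab = four_cond_data
        a = mg.embed_tsne(m, seed=4, perplexity=10)
        b = mg.embed_tsne(m, seed=4, perplexity=10)
        np.testing.assert_array_equal(
            a[["tsne1", "tsne2", "tsne3"]].to_numpy(),
            b[["tsne1", "tsne2", "tsne3"]].to_numpy(),
        )

    def test_too_few_samples_suggests_smaller_perplexity(self):
        m = mg.BetaMatrix(["s1", "s2"], ["cg1"], np.array([[0.1], [0.2]]))
        with pytest.raises(EvaluationError, match="perplexity"):
            mg.embed_tsne(m, perplexity=30.0)


class TestCompareGenerators:
    def test_scaled_protocol_structure(self, four_cond_data):
        m, lab = four_cond_data
        cfg = mg.CVAEConfig(
            encoder_hidden=(16, 8), latent_dim=4, epochs=60, batch_size=30, seed=0
        )
        report = mg.compare_generators(
            m, lab, n_generated_per_condition=10, repetitions=2, seed=2,
            cvae_config=cfg, algorithms=["SVM", "DT"], chunk_size=1000,
        )
        # one accuracy per (repetition, classifier, generator)
        tab = report.accuracy_table()
        assert len(tab) == 2 * 2 * 2
        assert set(tab["generator"]) == {"cvae", "benchmark"}
        assert ((tab["accuracy"] >= 0) & (tab["accuracy"] <= 1)).all()
        # benchmark on a separated fixture should classify well
        assert report.mean_accuracy("SVM", "benchmark") >= 0.8

    def test_single_condition_errors(self):
        m = mg.BetaMatrix(["s1", "s2"], ["cg1"], np.array([[0.1], [0.2]]))
        lab = mg.ConditionVector(["A", "A"])
        with pytest.raises(EvaluationError):
            mg.compare_generators(m, lab, repetitions=1)

    def test_missing_values_rejected(self):
        m = mg.BetaMatrix(["s1", "s2"], ["cg1"], np.array([[np.nan], [0.2]]))
        lab = mg.ConditionVector(["A", "B"])
        with pytest.raises(EvaluationError, match="preprocess"):
            mg.compare_generators(m, lab, repetitions=1)
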