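"""Naïve Bayes, random forest and PNN classifiers."""

import numpy as np
import pytest
from sklearn.naive_bayes import BernoulliNB

from simtox.evaluate import roc_auc
from simtox.featurize import FeatureTable
from simtox.learners import (
    MixedNB,
    PNNClassifier,
    ToxRandomForest,
    load_model,
    predict,
    save_model,
    train_nb,
    train_pnn,
    train_rf,
)
from simtox.synthdata import GeneratorConfig, generate

from .oracles import nb_posterior_brute


def _table(X, y=None, tag="SYNTH"):
    X = np.asarray(X, dtype=float)
    return FeatureTable(
        ids=[f"r{i}" for i in range(X.shape[0])],
        X=X,
        columns=[f"{tag}:{j:04d}" for j in range(X.shape[1])],
        labels=None if y is None else np.asarray(y),
    )


class TestMixedNB:
    def test_matches_literal_bayes_product(self, rng):
        for _ in range(30):
            n, p = int(rng.integers(4, 12)), int(rng.integers(1, 6))
            X = rng.integers(0, 2, size=(n, p))
            y = rng.integers(0, 2, size=n)
            y[:2] = [0, 1]
            model = MixedNB().fit(X, y)
            for q in rng.integers(0, 2, size=(4, p)):
                got = model.predict_proba(q[None, :])[0, 1]
                want = nb_posterior_brute(X.tolist(), y.tolist(), q.tolist())
                assert got == pytest.approx(want, abs=1e-12)

    def test_separating_bit_posterior_near_one(self):
        # one bit perfectly separates balanced classes of 10 each
        X = np.zeros((20, 1))
        X[:10, 0] = 1
        y = np.array([1] * 10 + [0] * 10)
        model = MixedNB().fit(X, y)
        # by hand: P(bit|act) = 11/12, P(bit|inact) = 1/12 -> posterior 11/12
        assert model.predict_proba([[1]])[0, 1] == pytest.approx(11 / 12, abs=1e-12)

    def test_uninformative_bit_leaves_prior(self):
        # identical class-conditional frequencies: likelihood ratio 1
        X = np.array([[1], [0], [1], [1], [0], [1]])
        y = np.array([1, 1, 1, 0, 0, 0])
        model = MixedNB().fit(X, y)
        assert model.predict_proba([[1]])[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_zero_features_returns_prior(self):
        X = np.zeros((10, 0))
        y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        model = MixedNB().fit(X, y)
        assert model.predict_proba(np.zeros((1, 0)))[0, 1] == pytest.approx(0.3)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            MixedNB().fit(np.zeros((4, 2)), np.ones(4, dtype=int))

    def test_agrees_with_sklearn_bernoulli_nb(self, small_tables):
        train, ext = small_tables
        ours = MixedNB(alpha=1.0).fit(train.X, train.labels)
        ref = BernoulliNB(alpha=1.0).fit(train.X, train.labels)
        assert np.allclose(
            ours.predict_proba(ext.X), ref.predict_proba(ext.X), atol=1e-10
        )

    def test_gaussian_columns_used_for_continuous(self, rng):
        # one continuous feature, classes separated by its mean
        x = np.concatenate([rng.normal(0, 1, 50), rng.normal(5, 1, 50)])
        y = np.array([0] * 50 + [1] * 50)
        model = MixedNB().fit(x[:, None], y)
        assert not model.binary_mask_[0]
        assert model.predict_proba([[5.0]])[0, 1] > 0.99
        assert model.predict_proba([[0.0]])[0, 1] < 0.01

    def test_scores_normalized(self, small_tables):
        train, ext = small_tables
        proba = MixedNB().fit(train.X, train.labels).predict_proba(ext.X)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-12)


class TestToxRandomForest:
    @pytest.mark.parametrize("criterion", ["gini", "info_gain_ratio"])
    def test_separable_training_scores(self, criterion):
        # two disjoint bit templates -> near-unanimous votes
        cfg = GeneratorConfig(
            n_train=200, n_external=10, active_fraction=0.3,
            n_bits=32, template_distance=32, flip_prob=0.0, seed=5,
        )
        train, _ = generate(cfg)
        rf = ToxRandomForest(
            n_trees=100, split_criterion=criterion, data_fraction=0.8, random_state=0
        ).fit(train.X, train.labels)
        scores = rf.predict_proba(train.X)[:, 1]
        assert (scores[train.labels == 1] > 0.95).all()
        assert (scores[train.labels == 0] < 0.05).all()

    def test_seeded_reproducibility(self, small_tables):
        train, ext = small_tables
        a = ToxRandomForest(n_trees=30, random_state=42).fit(train.X, train.labels)
        b = ToxRandomForest(n_trees=30, random_state=42).fit(train.X, train.labels)
        assert np.array_equal(a.predict_proba(ext.X), b.predict_proba(ext.X))

    def test_gain_ratio_comparable_to_sklearn_gini(self, small_tables):
        # independent route: both criteria should rank a separable external
        # set almost identically
        train, ext = small_tables
        aucs = {}
        for crit in ("gini", "info_gain_ratio"):
            rf = ToxRandomForest(
                n_trees=60, split_criterion=crit, data_fraction=0.8, random_state=1
            ).fit(train.X, train.labels)
            aucs[crit] = roc_auc(rf.predict_proba(ext.X)[:, 1], ext.labels).auc
        assert abs(aucs["gini"] - aucs["info_gain_ratio"]) < 0.05

    def test_vote_fraction_definition(self):
        # stump-friendly data: every tree votes identically, so the score
        # is exactly the vote fraction (here unanimous)
        X = np.array([[1.0], [1.0], [0.0], [0.0]] * 10)
        y = np.array([1, 1, 0, 0] * 10)
        rf = ToxRandomForest(
            n_trees=25, split_criterion="info_gain_ratio", data_fraction=1.0,
            random_state=0,
        ).fit(X, y)
        assert np.allclose(rf.predict_proba(np.array([[1.0]]))[:, 1], 1.0)
        assert np.allclose(rf.predict_proba(np.array([[0.0]]))[:, 1], 0.0)

    def test_degenerate_inputs_rejected(self):
        X, y = np.zeros((4, 2)), np.array([1, 1, 1, 1])
        with pytest.raises(ValueError, match="both classes"):
            ToxRandomForest(n_trees=5).fit(X, y)
        with pytest.raises(ValueError, match="n_trees"):
            ToxRandomForest(n_trees=0).fit(np.zeros((4, 2)), np.array([0, 1, 0, 1]))
        with pytest.raises(ValueError, match="data_fraction"):
            ToxRandomForest(data_fraction=1.5).fit(
                np.zeros((4, 2)), np.array([0, 1, 0, 1])
            )


class TestPNN:
    def test_equidistant_centres_score_half(self):
        X = np.array([[0.0, 1.0], [0.0, -1.0]])
        y = np.array([1, 0])
        model = PNNClassifier(sigma=0.7).fit(X, y)
        assert model.predict_proba([[0.0, 0.0]])[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_closed_form_density_ratio(self):
        # two actives at distance 0, one inactive at distance d:
        # score = 1 / (1 + exp(−d²/2σ²))
        d, sigma = 1.5, 0.8
        X = np.array([[0.0], [0.0], [d]])
        y = np.array([1, 1, 0])
        model = PNNClassifier(sigma=sigma).fit(X, y)
        want = 1.0 / (1.0 + np.exp(-(d**2) / (2 * sigma**2)))
        assert model.predict_proba([[0.0]])[0, 1] == pytest.approx(want, abs=1e-12)

    def test_tiny_sigma_is_nearest_centre(self, rng):
        # σ→0 limit: the closest training point decides the class
        for seed in range(5):
            r = np.random.default_rng(seed)
            X = r.normal(size=(50, 4))
            y = r.integers(0, 2, size=50)
            y[:2] = [0, 1]
            Q = r.normal(size=(20, 4))
            model = PNNClassifier(sigma=1e-6).fit(X, y)
            got = model.predict(Q)
            d = ((Q[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
            want = y[np.argmin(d, axis=1)]
            assert np.array_equal(got, want)

    def test_class_size_invariance(self, small_tables):
        # class-averaged densities: duplicating every inactive leaves
        # scores exactly unchanged
        train, ext = small_tables
        model = PNNClassifier(sigma=2.0).fit(train.X, train.labels)
        dup_X = np.vstack([train.X, train.X[train.labels == 0]])
        dup_y = np.concatenate([train.labels, np.zeros((train.labels == 0).sum(), int)])
        dup = PNNClassifier(sigma=2.0).fit(dup_X, dup_y)
        assert np.allclose(
            model.predict_proba(ext.X), dup.predict_proba(ext.X), atol=1e-12
        )

    def test_auto_sigma_seeded(self, small_tables):
        train, _ = small_tables
        a = PNNClassifier(sigma="auto", random_state=3).fit(train.X, train.labels)
        b = PNNClassifier(sigma="auto", random_state=3).fit(train.X, train.labels)
        assert a.sigma_ == b.sigma_ > 0

    def test_invalid_sigma_rejected(self):
        X, y = np.zeros((4, 2)), np.array([0, 1, 0, 1])
        with pytest.raises(ValueError, match="sigma"):
            PNNClassifier(sigma=-1.0).fit(X, y)

    def test_scores_normalized(self, small_tables):
        train, ext = small_tables
        proba = PNNClassifier(sigma=1.0).fit(train.X, train.labels).predict_proba(ext.X)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-12)


class TestTableLevelAPI:
    def test_train_predict_roundtrip(self, small_tables):
        train, ext = small_tables
        model = train_rf(train, n_trees=30, seed=0)
        results = predict(model, ext)
        assert len(results) == ext.n_records
        assert all(0.0 <= r.score <= 1.0 for r in results)
        assert all(r.predicted_class == (r.score >= 0.5) for r in results)
        assert model.training_summary["n"] == train.n_records
        assert model.training_summary["n_active"] == int(train.labels.sum())

    def test_column_mismatch_fatal_with_diff(self, small_tables):
        train, ext = small_tables
        model = train_nb(train)
        shuffled = FeatureTable(
            ids=ext.ids,
            X=ext.X[:, ::-1].copy(),
            columns=list(ext.columns[::-1]),
            labels=ext.labels,
        )
        with pytest.raises(ValueError, match="do not match"):
            predict(model, shuffled)

    @pytest.mark.parametrize("trainer", [train_nb, train_pnn,
                                         lambda t: train_rf(t, n_trees=20, seed=7)])
    def test_serialization_preserves_scores(self, tmp_path, small_tables, trainer):
        train, ext = small_tables
        model = trainer(train)
        before = np.array([r.score for r in predict(model, ext)])
        path = tmp_path / "model.bin"
        save_model(model, path)
        reloaded = load_model(path)
        after = np.array([r.score for r in predict(reloaded, ext)])
        assert np.array_equal(before, after)
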