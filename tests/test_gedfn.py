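from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from forgesel import (
    GEDFN,
    ImportanceScores,
    fit_forest,
    forest_to_graph,
    gcw_scores,
    generate_planted,
    select_top_k,
    train_gedfn,
    PlantedDatasetSpec,
)

from oracles import gcw_bruteforce, topk_bruteforce


def _identity_task(rng, d=16, n=128):
    X = np.eye(d)[rng.integers(0, d, n)]
    y = np.where(X[:, : d // 2].sum(axis=1) > 0, 1, -1)
    return X, y


class TestTraining:
    def test_mask_conservation_is_exact(self, small_planted):
        data, _ = small_planted
        d = data.width
        rng = np.random.default_rng(2)
        mask = rng.random((d, d)) < 0.05
        mask |= mask.T
        np.fill_diagonal(mask, True)
        net = GEDFN(adjacency=mask, epochs=3, random_state=0).fit(
            data.matrix, data.labels
        )
        assert (net.W_in_[~mask] == 0).all()
        assert (net.W_in_[mask] != 0).any()

    def test_loss_decreases_on_identity_task(self, rng):
        X, y = _identity_task(rng)
        net = GEDFN(adjacency=np.eye(16, dtype=bool), epochs=5, random_state=0).fit(X, y)
        losses = net.loss_curve_
        assert len(losses) == 5
        assert all(a > b for a, b in zip(losses, losses[1:]))

    def test_richer_mask_fits_at_least_as_well(self):
        # all-ones mask can express everything the identity mask can
        d = 16
        diffs = []
        for s in range(3):
            rng = np.random.default_rng(100 + s)
            X = rng.random((120, d))
            y = np.where(X[:, 0] + X[:, 1] + 0.5 * X[:, 2] > 1.25, 1, -1)
            final = {}
            for name, mask in [
                ("identity", np.eye(d, dtype=bool)),
                ("ones", np.ones((d, d), dtype=bool)),
            ]:
                net = GEDFN(adjacency=mask, epochs=40, lr=1e-3, random_state=s).fit(X, y)
                final[name] = net.loss_curve_[-1]
            diffs.append(final["ones"] - final["identity"])
        assert np.median(diffs) <= 0

    def test_planted_training_accuracy(self):
        data, _ = generate_planted(PlantedDatasetSpec(seed=3))
        forest = fit_forest(data.matrix, data.labels, p=100, seed=3)
        graph = forest_to_graph(forest)
        net = train_gedfn(data.matrix, data.labels, graph, epochs=50, seed=3)
        acc = (net.predict(data.matrix) == data.labels).mean()
        assert acc > 0.9

    def test_softmax_head_normalized(self, small_planted):
        data, _ = small_planted
        d = data.width
        net = GEDFN(adjacency=np.eye(d, dtype=bool), epochs=2, random_state=1).fit(
            data.matrix, data.labels
        )
        p = net.predict_proba(data.matrix)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_dimension_mismatch_raises(self, small_planted):
        data, _ = small_planted
        with pytest.raises(ValueError, match="adjacency shape"):
            GEDFN(adjacency=np.eye(7, dtype=bool), epochs=1).fit(
                data.matrix, data.labels
            )

    def test_divergent_training_aborts_with_diagnostic(self, rng):
        X = rng.normal(size=(64, 8)) * 1e3
        y = np.where(X[:, 0] > 0, 1, -1)
        with pytest.raises(RuntimeError, match="learning rate"), np.errstate(all="ignore"):
            GEDFN(
                adjacency=np.ones((8, 8), dtype=bool),
                epochs=6,
                lr=1e30,
                optimizer="sgd",
                random_state=0,
            ).fit(X, y)

    def test_reproducible_under_seed(self, small_planted):
        data, _ = small_planted
        d = data.width
        kw = dict(adjacency=np.eye(d, dtype=bool), epochs=3, random_state=11)
        n1 = GEDFN(**kw).fit(data.matrix, data.labels)
        n2 = GEDFN(**kw).fit(data.matrix, data.labels)
        assert np.array_equal(n1.W_in_, n2.W_in_)
        assert n1.loss_curve_ == n2.loss_curve_


def _random_model(rng, n, h, gated=False):
    mask = rng.random((n, n)) < 0.5
    mask |= mask.T
    np.fill_diagonal(mask, True)
    W_in = rng.normal(size=(n, n)) * mask
    W1 = rng.normal(size=(n, h))
    return SimpleNamespace(W_in_=W_in, W1_=W1, mask_=mask.astype(float), gcw_gated=gated)


class TestGCW:
    @pytest.mark.parametrize("gated", [False, True])
    def test_matches_bruteforce_on_random_models(self, rng, gated):
        for _ in range(20):
            n = int(rng.integers(2, 9))
            h = int(rng.integers(1, 5))
            model = _random_model(rng, n, h, gated)
            got = gcw_scores(model).scores
            want = gcw_bruteforce(model.W_in_, model.W1_, model.mask_ != 0, gated)
            assert np.max(np.abs(got - want)) <= 1e-10

    def test_zero_weights_give_zero_scores(self, rng):
        model = _random_model(rng, 5, 3)
        model.W_in_ = np.zeros_like(model.W_in_)
        model.W1_ = np.zeros_like(model.W1_)
        assert (gcw_scores(model).scores == 0).all()

    def test_absolute_homogeneity(self, rng):
        model = _random_model(rng, 6, 4)
        c1 = gcw_scores(model).scores
        model.W_in_ = model.W_in_ * 2
        model.W1_ = model.W1_ * 2
        assert np.allclose(gcw_scores(model).scores, 2 * c1)

    def test_scores_nonnegative(self, rng):
        model = _random_model(rng, 8, 4)
        assert (gcw_scores(model).scores >= 0).all()


class TestSelectTopK:
    def test_basic_example(self):
        s = ImportanceScores.from_scores([3.0, 1.0, 2.0])
        assert select_top_k(s, 2).tolist() == [0, 2]

    def test_ties_break_by_ascending_index(self):
        s = ImportanceScores.from_scores([1.0, 1.0, 1.0])
        assert select_top_k(s, 3).tolist() == [0, 1, 2]

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 100), min_size=1, max_size=30), st.data())
    def test_matches_sort_oracle(self, scores, data):
        k = data.draw(st.integers(1, len(scores)))
        s = ImportanceScores.from_scores(scores)
        assert select_top_k(s, k).tolist() == topk_bruteforce(scores, k)

    def test_idempotent(self, rng):
        scores = rng.random(30)
        s = ImportanceScores.from_scores(scores)
        top = select_top_k(s, 10)
        again = select_top_k(ImportanceScores.from_scores(scores[top]), 10)
        assert np.array_equal(scores[top][again], scores[top])

    @pytest.mark.parametrize("k", [0, 31])
    def test_out_of_range_k_raises(self, k):
        s = ImportanceScores.from_scores(np.arange(30.0))
        with pytest.raises(ValueError):
            select_top_k(s, k)

    def test_importance_tsv_export(self, tmp_path):
        s = ImportanceScores.from_scores([0.5, 2.0, 1.0])
        path = tmp_path / "imp.tsv"
        s.to_tsv(path, feature_names=["a", "b", "c"])
        lines = path.read_text().splitlines()
        assert lines[0] == "feature_name\tscore\trank"
        assert lines[2].split("\t") == ["b", "2", "0"]
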