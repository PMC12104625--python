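import numpy as np
import pytest

from gravgrn import (
    DirectedGRN,
    TrainConfig,
    TrainedModel,
    evaluate,
    make_fixture,
    rank_novel_edges,
    split_edges,
    train,
)
from gravgrn.train import VARIANTS


def auroc_pair_counting(labels, scores):
    """O(n^2) oracle: fraction of (positive, negative) pairs ranked correctly,
    ties counting one half."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = correct = 0.0
    for p in pos:
        for q in neg:
            total += 1
            if p > q:
                correct += 1
            elif p == q:
                correct += 0.5
    return correct / total


def auprc_step_reference(labels, scores):
    """Step-wise average precision: sum of precision at each recall increment."""
    order = np.argsort(-scores, kind="stable")
    labels = labels[order]
    tp = fp = 0
    n_pos = labels.sum()
    ap = 0.0
    for y in labels:
        if y == 1:
            tp += 1
            ap += tp / (tp + fp)
        else:
            fp += 1
    return ap / n_pos


def _model_from_scores(score_map):
    """Minimal stand-in scored model: Z chosen so decode reproduces score_map."""

    class Fixed:
        def score_pairs(self, pairs):
            return np.array([score_map[tuple(p)] for p in np.asarray(pairs)])

    return Fixed()


class TestEvaluate:
    def test_perfect_separation(self):
        model = _model_from_scores({(0, 1): 0.9, (1, 2): 0.8, (2, 0): 0.1, (0, 2): 0.2})
        res = evaluate(model, [(0, 1), (1, 2)], [(2, 0), (0, 2)])
        assert res.auroc == 1.0 and res.auprc == 1.0
        assert res.n_pos == res.n_neg == 2

    def test_perfect_inversion(self):
        model = _model_from_scores({(0, 1): 0.4, (1, 0): 0.6})
        res = evaluate(model, [(0, 1)], [(1, 0)])
        assert res.auroc == 0.0

    def test_empty_edge_set_errors(self):
        model = _model_from_scores({})
        with pytest.raises(ValueError, match="non-empty"):
            evaluate(model, [], [(0, 1)])

    @pytest.mark.parametrize("seed", range(20))
    def test_auroc_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        labels = (rng.random(n) < 0.5).astype(int)
        labels[0], labels[1] = 1, 0  # both classes present
        scores = np.round(rng.random(n), 2)  # rounding forces ties
        pairs = [(i, (i + 1) % n) for i in range(n)]
        model = _model_from_scores(dict(zip(pairs, scores)))
        pos = [p for p, y in zip(pairs, labels) if y == 1]
        neg = [p for p, y in zip(pairs, labels) if y == 0]
        res = evaluate(model, pos, neg)
        want = auroc_pair_counting(labels, scores)
        assert abs(res.auroc - want) < 1e-9

    @pytest.mark.parametrize("seed", range(10))
    def test_auprc_matches_step_reference(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = 24
        labels = (rng.random(n) < 0.5).astype(int)
        labels[0], labels[1] = 1, 0
        scores = rng.random(n)  # distinct scores: step integration is unambiguous
        pairs = [(i, (i + 1) % n) for i in range(n)]
        model = _model_from_scores(dict(zip(pairs, scores)))
        pos = [p for p, y in zip(pairs, labels) if y == 1]
        neg = [p for p, y in zip(pairs, labels) if y == 0]
        res = evaluate(model, pos, neg)
        want = auprc_step_reference(labels, scores)
        assert abs(res.auprc - want) < 1e-9


SMALL = dict(epochs=8, hidden_dim=16, latent_dim=8)


class TestTraining:
    def test_loss_trace_is_finite_everywhere(self, tiny_dataset):
        split = split_edges(tiny_dataset.grn, seed=0)
        model = train(split, tiny_dataset.expression, TrainConfig(seed=0, **SMALL))
        assert np.all(np.isfinite(model.loss_trace))
        assert len(model.loss_trace) == 8

    def test_same_seed_reproduces_validation_trace(self, tiny_dataset):
        split = split_edges(tiny_dataset.grn, seed=1)
        cfg = TrainConfig(seed=5, **SMALL)
        a = train(split, tiny_dataset.expression, cfg)
        b = train(split, tiny_dataset.expression, cfg)
        assert a.val_auroc_trace == b.val_auroc_trace
        np.testing.assert_array_equal(a.Z, b.Z)

    @pytest.mark.parametrize("variant", VARIANTS)
    def test_every_variant_trains(self, tiny_dataset, variant):
        split = split_edges(tiny_dataset.grn, seed=2)
        model = train(
            split, tiny_dataset.expression, TrainConfig(variant=variant, seed=0, **SMALL)
        )
        res = evaluate(model, split.test_pos, split.test_neg)
        assert 0.0 <= res.auroc <= 1.0

    def test_gae_variant_scores_symmetrically(self, tiny_dataset):
        split = split_edges(tiny_dataset.grn, seed=3)
        model = train(
            split, tiny_dataset.expression, TrainConfig(variant="gae", seed=0, **SMALL)
        )
        fwd = model.score_pairs([(0, 5)])[0]
        bwd = model.score_pairs([(5, 0)])[0]
        assert fwd == pytest.approx(bwd, abs=1e-12)

    def test_sampled_negative_training_mode(self, tiny_dataset):
        split = split_edges(tiny_dataset.grn, seed=4)
        cfg = TrainConfig(variant="gigae", seed=0, train_mode="sampled", **SMALL)
        model = train(split, tiny_dataset.expression, cfg)
        assert np.all(np.isfinite(model.loss_trace))

    def test_invalid_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            TrainConfig(variant="banana")

    def test_checkpoint_roundtrip_preserves_scores(self, tiny_dataset, tmp_path):
        split = split_edges(tiny_dataset.grn, seed=0)
        model = train(split, tiny_dataset.expression, TrainConfig(seed=0, **SMALL))
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = TrainedModel.load(path)
        pairs = [(0, 1), (3, 7), (10, 2)]
        np.testing.assert_allclose(model.score_pairs(pairs), loaded.score_pairs(pairs))
        assert loaded.config.variant == "full"


class TestSkipGramGradientPath:
    def test_regularizer_alone_produces_encoder_gradients(self, tiny_dataset):
        """With the reconstruction loss silenced, one Skip-Gram step must still
        reach the encoder weights through Z'."""
        import gravgrn.model as M
        import gravgrn.walks as W

        split = split_edges(tiny_dataset.grn, seed=0)
        grn = split.train_grn
        X = tiny_dataset.expression.values
        A = M.normalize_adjacency(grn)
        net = M.GravityGAE(n_features=X.shape[1], hidden_dim=16, latent_dim=8, seed=0)
        corpus = W.generate_walks(grn, seed=1)
        pairs = W.skipgram_pairs(corpus, window=3)
        rng = np.random.default_rng(2)
        negs = W.sample_negatives(grn.n_genes, len(pairs), 5, rng, corpus=corpus)
        Z, m, cache = net.encode(A, X)
        Zp = np.column_stack([Z, m])
        loss, grad = W.skipgram_loss_grads(Zp, pairs, negs)
        gW1, gW2 = net.backward(A, cache, grad)
        assert loss > 0
        assert np.abs(gW1).max() > 0 and np.abs(gW2).max() > 0


class TestRankNovelEdges:
    def _trained(self, dataset):
        split = split_edges(dataset.grn, seed=0)
        return train(split, dataset.expression, TrainConfig(seed=0, **SMALL))

    def test_known_edges_never_returned(self, tiny_dataset):
        model = self._trained(tiny_dataset)
        ranked = rank_novel_edges(model, tiny_dataset.grn, top_k=100)
        for i, j, _ in ranked:
            assert (i, j) not in tiny_dataset.grn.edges

    def test_top_k_larger_than_candidates_returns_all(self):
        n = 4
        grn = DirectedGRN(edges=frozenset({(0, 1)}), n_genes=n)
        rng = np.random.default_rng(0)

        class Fixed:
            def score_pairs(self, pairs):
                return rng.random(len(pairs))

        ranked = rank_novel_edges(Fixed(), grn, top_k=10_000)
        assert len(ranked) == n * (n - 1) - 1

    def test_scores_sorted_descending_with_lexicographic_ties(self):
        grn = DirectedGRN(edges=frozenset(), n_genes=3)

        class Constant:
            def score_pairs(self, pairs):
                return np.full(len(pairs), 0.5)

        ranked = rank_novel_edges(Constant(), grn, top_k=6)
        assert [(i, j) for i, j, _ in ranked] == sorted((i, j) for i, j, _ in ranked)

    def test_source_restriction(self, tiny_dataset):
        model = self._trained(tiny_dataset)
        ranked = rank_novel_edges(model, tiny_dataset.grn, sources={0}, top_k=50)
        assert ranked and all(i == 0 for i, _, _ in ranked)
        scores = [s for _, _, s in ranked]
        assert scores == sorted(scores, reverse=True)


def test_rwr_tightens_within_community_embeddings():
    """On a two-community network, the random-walk regularizer should pull
    genes of the same community closer in latent space than training without
    it, in most seeds."""
    from scipy.spatial.distance import pdist

    wins = 0
    n_seeds = 10
    for seed in range(n_seeds):
        ds = make_fixture("two-community", seed=100 + seed)
        split = split_edges(ds.grn, seed=seed)
        kw = dict(epochs=50, hidden_dim=64, latent_dim=32, seed=seed)
        plain = train(split, ds.expression, TrainConfig(variant="gigae", **kw))
        reg = train(split, ds.expression, TrainConfig(variant="gigae_rwr", **kw))

        def within(m):
            return (pdist(m.Z[:30]).mean() + pdist(m.Z[30:]).mean()) / 2

        wins += within(reg) < within(plain)
    assert wins >= 0.8 * n_seeds
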