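"""Contrastive/supervised training mechanics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from screenkit.benchmark import benchmark_model_config
from screenkit.synthetic import GeneratorConfig, generate_dataset
from screenkit.train import (TrainConfig, train, triplet_margin_loss,
                             update_cluster_centers, sample_triplet,
                             lambda_schedule)


class TestTripletMarginLoss:
    def test_hinge_boundary_is_zero(self):
        za = np.zeros(4)
        zn = np.array([1.0, 0, 0, 0])  # ||za-zn|| = 1 = alpha, za = zp
        assert triplet_margin_loss(za, za, zn, alpha=1.0) == 0.0

    def test_identical_positive_and_negative_give_margin(self):
        """With zp = zn the distances cancel and the loss is alpha = 1."""
        rng = np.random.default_rng(0)
        za, zpn = rng.normal(size=6), rng.normal(size=6)
        assert triplet_margin_loss(za, zpn, zpn, alpha=1.0) == pytest.approx(1.0)

    def test_matches_norm_arithmetic_oracle(self, rng):
        for _ in range(20):
            za, zp, zn = rng.normal(size=(3, 10))
            raw = (np.sqrt(((za - zp) ** 2).sum())
                   - np.sqrt(((za - zn) ** 2).sum()) + 1.0)
            assert triplet_margin_loss(za, zp, zn) == pytest.approx(
                max(0.0, raw))
            assert triplet_margin_loss(za, zp, zn, hinge=False) == \
                pytest.approx(raw)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            triplet_margin_loss(np.zeros(3), np.zeros(4), np.zeros(4))

    @settings(deadline=None, max_examples=60)
    @given(st.integers(0, 2**31 - 1))
    def test_nonnegative_and_zero_when_negative_is_far(self, seed):
        rng = np.random.default_rng(seed)
        za, zp, zn = rng.normal(size=(3, 5))
        loss = triplet_margin_loss(za, zp, zn, alpha=1.0)
        assert loss >= 0.0
        if np.linalg.norm(za - zn) >= np.linalg.norm(za - zp) + 1.0:
            assert loss == 0.0


class TestClusterCenters:
    def test_singleton_classes_return_member_vectors(self, rng):
        emb = {f"e{i}": rng.normal(size=4) for i in range(3)}
        classes = {f"e{i}": i + 1 for i in range(3)}
        centers = update_cluster_centers(emb, classes)
        for i in range(3):
            np.testing.assert_array_equal(centers[i + 1], emb[f"e{i}"])

    def test_opposite_members_cancel(self, rng):
        v = rng.normal(size=5)
        centers = update_cluster_centers({"a": v, "b": -v}, {"a": 1, "b": 1})
        np.testing.assert_allclose(centers[1], np.zeros(5), atol=1e-15)

    def test_matches_groupwise_mean_oracle(self, rng):
        vecs = {f"e{i}": rng.normal(size=6) for i in range(15)}
        classes = {f"e{i}": 1 + i % 3 for i in range(15)}
        centers = update_cluster_centers(vecs, classes)
        for c in (1, 2, 3):
            members = [vecs[k] for k, cl in classes.items() if cl == c]
            np.testing.assert_allclose(centers[c], np.mean(members, axis=0))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            update_cluster_centers({}, {})


class TestSampleTriplet:
    def test_two_classes_force_the_negative(self, rng):
        centers = {1: np.zeros(3), 2: np.ones(3)}
        zp, zn = sample_triplet(1, centers, rng)
        np.testing.assert_array_equal(zp, centers[1])
        np.testing.assert_array_equal(zn, centers[2])

    def test_seeded_draws_are_reproducible(self):
        centers = {c: np.full(2, c) for c in range(1, 8)}
        rng_a, rng_b = np.random.default_rng(7), np.random.default_rng(7)
        seq_a = [sample_triplet(3, centers, rng_a)[1][0] for _ in range(20)]
        seq_b = [sample_triplet(3, centers, rng_b)[1][0] for _ in range(20)]
        assert seq_a == seq_b

    def test_negative_choice_is_uniform(self):
        centers = {c: np.full(1, c) for c in (1, 2, 3, 4)}
        rng = np.random.default_rng(0)
        draws = np.array([sample_triplet(1, centers, rng)[1][0]
                          for _ in range(10_000)])
        counts = np.array([(draws == c).sum() for c in (2, 3, 4)])
        expected = 10_000 / 3
        sigma = np.sqrt(10_000 * (1 / 3) * (2 / 3))
        assert (np.abs(counts - expected) < 3 * sigma).all()

    def test_single_class_errors_with_guidance(self, rng):
        with pytest.raises(ValueError, match="contrastive"):
            sample_triplet(1, {1: np.zeros(2)}, rng)


class TestSchedule:
    def test_endpoints(self):
        assert lambda_schedule(0, 30, 0.3) == 1.0
        assert lambda_schedule(9, 30, 0.3) == 0.0
        assert lambda_schedule(29, 30, 0.3) == 0.0

    def test_monotone_decreasing(self):
        vals = [lambda_schedule(e, 20, 0.5) for e in range(20)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


@pytest.fixture(scope="module")
def trained_small():
    cfg = GeneratorConfig(n_enzymes=12, residues_per_enzyme=40,
                          catalytic_per_enzyme=4, n_classes=3, seed=31)
    _, graphs = generate_dataset(cfg)
    tc = TrainConfig(epochs=30, seed=31,
                     model=benchmark_model_config(31))
    model, state = train(graphs, tc)
    return graphs, model, state, tc


class TestTrainLoop:
    def test_schedule_recorded_in_history(self, trained_small):
        _, _, state, tc = trained_small
        assert state.history[0]["lambda"] == 1.0
        boundary = int(np.ceil(tc.contrastive_fraction * tc.epochs))
        assert all(h["lambda"] == 0.0 for h in state.history[boundary:])

    def test_supervised_loss_improves_after_phase_boundary(self, trained_small):
        _, _, state, tc = trained_small
        boundary = int(np.ceil(tc.contrastive_fraction * tc.epochs))
        assert state.history[-1]["loss_supervised"] < \
            state.history[boundary]["loss_supervised"]

    def test_contrastive_phase_separates_class_centers(self, trained_small):
        graphs, model, _, _ = trained_small
        z = {g.id: model.sequence_embedding(g).ravel() for g in graphs}
        classes = {g.id: g.ec_class for g in graphs}
        centers = update_cluster_centers(z, classes)
        within, between = [], []
        for gid, vec in z.items():
            for c, center in centers.items():
                d = np.linalg.norm(vec - center)
                (within if c == classes[gid] else between).append(d)
        assert np.mean(within) < np.mean(between)

    def test_training_is_bit_reproducible(self):
        cfg = GeneratorConfig(n_enzymes=4, residues_per_enzyme=25,
                              catalytic_per_enzyme=3, seed=13)
        _, graphs = generate_dataset(cfg)
        tc = TrainConfig(epochs=3, seed=13, model=benchmark_model_config(13))
        m1, s1 = train(graphs, tc)
        _, graphs2 = generate_dataset(cfg)
        m2, s2 = train(graphs2, TrainConfig(epochs=3, seed=13,
                                            model=benchmark_model_config(13)))
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k].data,
                                          m2.params[k].data)
        assert s1.history == s2.history

    def test_single_class_dataset_rejected(self):
        cfg = GeneratorConfig(n_enzymes=3, residues_per_enzyme=25,
                              catalytic_per_enzyme=3, n_classes=1, seed=3)
        _, graphs = generate_dataset(cfg)
        with pytest.raises(ValueError, match="use_contrastive"):
            train(graphs, TrainConfig(epochs=2, model=benchmark_model_config()))
        # and the documented escape hatch works
        model, state = train(graphs, TrainConfig(
            epochs=1, use_contrastive=False, model=benchmark_model_config()))
        assert state.history[0]["lambda"] == 0.0

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train([], TrainConfig(epochs=1))
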