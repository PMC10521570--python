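"""Soft-Dice objective and fit loop on reduced-geometry models."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import strokeseg as ss
from strokeseg.errors import ShapeError
from strokeseg.training import (
    DESK_SCALE_OVERRIDES,
    TrainingConfig,
    batch_loss,
    load_checkpoint,
    save_checkpoint,
    soft_dice_loss,
    soft_dice_loss_and_grad,
    stack_slices,
    train,
)


class TestSoftDiceLoss:
    def test_zero_at_perfect_prediction(self):
        rng = np.random.default_rng(0)
        t = (rng.random((12, 12)) > 0.8).astype(np.float32)
        assert soft_dice_loss(t, t, eps=1.0) == pytest.approx(0.0, abs=1e-12)

    def test_zero_for_both_empty(self):
        z = np.zeros((6, 6))
        assert soft_dice_loss(z, z, eps=1.0) == pytest.approx(0.0)

    def test_disjoint_example_arithmetic(self):
        """4 true pixels, 4 disjoint predicted pixels, eps=1:
        1 - (0 + 1)/(4 + 4 + 1) = 8/9."""
        t = np.zeros((4, 4))
        p = np.zeros((4, 4))
        t[0, :] = 1
        p[2, :] = 1
        assert soft_dice_loss(t, p, eps=1.0) == pytest.approx(1 - 1 / 9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            soft_dice_loss(np.zeros((3, 3)), np.zeros((4, 4)))

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_bounded_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        t = (rng.random((8, 8)) > 0.7).astype(np.float64)
        p = rng.random((8, 8))
        loss = soft_dice_loss(t, p, eps=1.0)
        assert 0.0 <= loss <= 1.0


class TestBatchLoss:
    def test_mean_of_per_image_losses(self):
        t = np.zeros((2, 2))
        p_perfect = np.zeros((2, 2))
        t2 = np.ones((2, 2))
        p_half = np.full((2, 2), 1 / 3)
        losses = [soft_dice_loss(t, p_perfect), soft_dice_loss(t2, p_half)]
        assert batch_loss([t, t2], [p_perfect, p_half]) == pytest.approx(np.mean(losses))

    def test_identical_pairs_leave_loss_unchanged(self):
        rng = np.random.default_rng(1)
        t = (rng.random((6, 6)) > 0.7).astype(np.float64)
        p = rng.random((6, 6))
        single = soft_dice_loss(t, p)
        assert batch_loss([t] * 5, [p] * 5) == pytest.approx(single)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            batch_loss([], [])

    def test_vectorised_loss_equals_per_image_oracle(self):
        rng = np.random.default_rng(2)
        t = (rng.random((7, 5, 5, 1)) > 0.6).astype(np.float32)
        p = rng.random((7, 5, 5, 1)).astype(np.float32)
        vec, _ = soft_dice_loss_and_grad(t, p, eps=1.0)
        oracle = np.mean([soft_dice_loss(t[i], p[i], eps=1.0) for i in range(7)])
        assert vec == pytest.approx(oracle, rel=1e-6)

    def test_loss_gradient_matches_finite_difference(self):
        rng = np.random.default_rng(3)
        t = (rng.random((2, 4, 4, 1)) > 0.6).astype(np.float32)
        p = rng.random((2, 4, 4, 1)).astype(np.float32) * 0.8 + 0.1
        _, grad = soft_dice_loss_and_grad(t, p, eps=1.0)
        h = 1e-3  # the loss is a smooth rational function; float32 noise
        for idx in [(0, 1, 2, 0), (1, 3, 0, 0), (0, 0, 0, 0)]:  # dominates at tiny h
            pp = p.copy()
            pp[idx] += h
            lp, _ = soft_dice_loss_and_grad(t, pp, eps=1.0)
            pm = p.copy()
            pm[idx] -= h
            lm, _ = soft_dice_loss_and_grad(t, pm, eps=1.0)
            fd = (lp - lm) / (2 * h)
            assert grad[idx] == pytest.approx(fd, rel=5e-3, abs=1e-6)


def _toy_slices(n, size=32, seed=0):
    """Phantom lesion slices mapped to a reduced 32x32 model grid."""
    params = ss.PhantomParams(n_subjects=max(2, (n // 4) + 1), slices_per_volume=12,
                              height=64, width=64, lesion_slice_range=(4, 6),
                              lesion_radius_range=(6, 14), seed=seed)
    pairs = []
    for v in ss.generate_cohort(params):
        if v.modality != "DWI":
            continue
        pairs.extend(ss.prepare_volume(v, size=size))
    return pairs[:n]


def _toy_model(seed=0):
    model, _ = ss.build_cnnres(levels=2, base_filters=8, input_size=32, seed=seed)
    return model


class TestTrainLoop:
    def test_loss_decreases_on_toy_cohort(self):
        pairs = _toy_slices(24)
        model = _toy_model()
        cfg = TrainingConfig(learning_rate=1e-3, batch_size=8, epochs=5, seed=0)
        result = train(model, pairs, [], cfg)
        hist = result.history
        assert len(hist) == 5
        assert hist.train_loss.iloc[-1] < hist.train_loss.iloc[0]

    def test_zero_learning_rate_freezes_parameters(self):
        pairs = _toy_slices(8)
        model = _toy_model()
        before = {k: v.copy() for k, v in model.state_dict().items()}
        cfg = TrainingConfig(learning_rate=0.0, batch_size=8, epochs=1, seed=0,
                             l2_coefficient=0.0)
        train(model, pairs, [], cfg)
        after = model.state_dict()
        for k in before:
            if k.endswith((".w", ".b", ".gamma", ".beta")):
                assert np.array_equal(before[k], after[k]), k

    def test_same_seed_reproduces_history(self):
        pairs = _toy_slices(16)
        val = _toy_slices(8, seed=1)
        cfg = TrainingConfig(learning_rate=1e-3, batch_size=8, epochs=3, seed=5)
        r1 = train(_toy_model(seed=2), pairs, val, cfg)
        r2 = train(_toy_model(seed=2), pairs, val, cfg)
        assert r1.history.equals(r2.history)

    def test_objective_dominates_dice_term(self):
        """With a positive L2 coefficient the logged objective is the Dice
        term plus a non-negative penalty."""
        pairs = _toy_slices(8)
        model = _toy_model()
        cfg = TrainingConfig(learning_rate=0.0, batch_size=8, epochs=1, seed=0,
                             l2_coefficient=1e-4)
        result = train(model, pairs, [], cfg)
        x, t = stack_slices(pairs)
        probs = model.predict(x)
        dice_term = np.mean([soft_dice_loss(t[i], probs[i]) for i in range(len(x))])
        assert result.history.train_loss.iloc[0] >= dice_term

    def test_best_checkpoint_restored(self):
        pairs = _toy_slices(16)
        val = _toy_slices(8, seed=1)
        cfg = TrainingConfig(learning_rate=1e-3, batch_size=8, epochs=4, seed=0)
        model = _toy_model()
        result = train(model, pairs, val, cfg)
        best_epoch_dice = result.history.val_dice.iloc[result.best_epoch]
        assert best_epoch_dice == pytest.approx(result.history.val_dice.max())
        assert result.best_val_dice == pytest.approx(best_epoch_dice)

    def test_checkpoint_round_trip(self, tmp_path):
        model = _toy_model(seed=4)
        path = save_checkpoint(model, tmp_path / "ckpt.npz")
        clone = load_checkpoint(path)
        x = np.random.default_rng(0).random((2, 32, 32, 1), dtype=np.float32)
        assert np.array_equal(model.forward(x), clone.forward(x))


def test_config_validation():
    with pytest.raises(ValueError):
        TrainingConfig(learning_rate=-1.0)
    with pytest.raises(ValueError):
        TrainingConfig(batch_size=0)
    with pytest.raises(ValueError):
        TrainingConfig(smooth_epsilon=0.0)
    with pytest.raises(ValueError):
        TrainingConfig(initializer="orthogonal")
    assert DESK_SCALE_OVERRIDES["batch_size"] == 8
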