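"""Dice metric, thresholding and report generation."""

import numpy as np
import pytest

from strokeseg.augment import apply_transform, train_policy
from strokeseg.errors import ShapeError
from strokeseg.evaluation import (
    binarize,
    dice_coefficient,
    evaluate,
    predict_volume,
    write_prediction_nifti,
)
from strokeseg.io import SlicePair
from strokeseg.training import soft_dice_loss


class TestBinarize:
    def test_below_threshold_all_zero(self):
        assert binarize(np.full((3, 3), 0.4)).sum() == 0

    def test_above_threshold_all_one(self):
        assert binarize(np.full((3, 3), 0.6)).sum() == 9

    def test_exactly_at_threshold_is_background(self):
        assert binarize(np.full((3, 3), 0.5)).sum() == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            binarize(np.array([0.2, 1.3]))


class TestDice:
    def test_identical_masks(self):
        m = (np.random.default_rng(0).random((8, 8)) > 0.6).astype(np.uint8)
        assert dice_coefficient(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4), np.uint8)
        b = np.zeros((4, 4), np.uint8)
        a[0] = 1
        b[2] = 1
        assert dice_coefficient(a, b) == 0.0

    def test_overlap_arithmetic(self):
        """|A|=4, |B|=6, |A∩B|=3 -> 2*3/(4+6) = 0.6."""
        a = np.zeros(12, np.uint8)
        b = np.zeros(12, np.uint8)
        a[:4] = 1
        b[1:7] = 1
        assert dice_coefficient(a, b) == pytest.approx(0.6)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a = (rng.random((6, 6)) > 0.5).astype(np.uint8)
        b = (rng.random((6, 6)) > 0.5).astype(np.uint8)
        assert dice_coefficient(a, b) == dice_coefficient(b, a)

    def test_empty_conventions(self):
        z = np.zeros((5, 5), np.uint8)
        o = np.ones((5, 5), np.uint8)
        assert dice_coefficient(z, z) == 1.0
        assert dice_coefficient(z, o) == 0.0
        assert dice_coefficient(o, z) == 0.0

    def test_one_iff_equal_for_nonempty(self):
        rng = np.random.default_rng(2)
        a = (rng.random((7, 7)) > 0.5).astype(np.uint8)
        b = a.copy()
        b[0, 0] ^= 1
        assert dice_coefficient(a, a) == 1.0
        assert dice_coefficient(a, b) < 1.0

    def test_invariant_under_joint_transforms(self, asymmetric_slice):
        rng = np.random.default_rng(3)
        other = (rng.random(asymmetric_slice.mask.shape) > 0.5).astype(np.uint8)
        base = dice_coefficient(asymmetric_slice.mask, other)
        pair_b = SlicePair(image=other.astype(np.float32), mask=other,
                           subject_id="s", modality="DWI", slice_index=0)
        for flip, qt in train_policy().transforms:
            ta = apply_transform(asymmetric_slice, flip, qt)
            tb = apply_transform(pair_b, flip, qt)
            assert dice_coefficient(ta.mask, tb.mask) == pytest.approx(base)

    def test_shape_mismatch_and_non_binary_rejected(self):
        with pytest.raises(ShapeError):
            dice_coefficient(np.zeros((2, 2)), np.zeros((3, 3)))
        with pytest.raises(ValueError, match="binary"):
            dice_coefficient(np.array([0, 2]), np.array([0, 1]))

    def test_soft_dice_converges_to_hard_dice_for_binary_prediction(self):
        rng = np.random.default_rng(4)
        t = (rng.random((10, 10)) > 0.7).astype(np.float64)
        p = (rng.random((10, 10)) > 0.7).astype(np.float64)
        hard = dice_coefficient(t.astype(np.uint8), p.astype(np.uint8))
        soft = 1.0 - soft_dice_loss(t, p, eps=1e-9)
        assert soft == pytest.approx(hard, abs=1e-6)


class _StubModel:
    """Prediction stub: returns a fixed map per slice index."""

    def __init__(self, fn):
        self.fn = fn
        self.input_size = 16

    def predict(self, x, batch_size=8):
        return np.stack([self.fn(x[i]) for i in range(len(x))])


def _slices(n=6, size=16, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        mask = (rng.random((size, size)) > 0.7).astype(np.uint8)
        out.append(SlicePair(image=rng.random((size, size)).astype(np.float32),
                             mask=mask, subject_id=f"sub-{i % 2}", modality="DWI",
                             slice_index=i))
    return out


class TestEvaluate:
    def test_oracle_model_scores_one(self):
        # make each image equal to its mask so an identity model is an oracle
        slices = _slices()
        for p in slices:
            p.image = p.mask.astype(np.float32)
        model = _StubModel(lambda xi: xi)
        result = evaluate(model, slices)
        assert result.original.mean_dice == pytest.approx(1.0)
        assert result.flip_augmented.mean_dice == pytest.approx(1.0)

    def test_constant_zero_model_scores_zero(self):
        slices = [p for p in _slices() if p.mask.sum() > 0]
        model = _StubModel(lambda xi: np.zeros_like(xi))
        result = evaluate(model, slices)
        assert result.original.mean_dice == 0.0

    def test_report_matches_per_slice_oracle(self):
        slices = _slices(8)
        rng = np.random.default_rng(9)
        maps = rng.random((16, len(slices), 16, 16)).astype(np.float32)[0]
        model = _StubModel(lambda xi: None)
        counter = {"i": 0}

        def fn(xi):
            out = maps[counter["i"] % len(slices)][..., None]
            counter["i"] += 1
            return out

        model.fn = fn
        result = evaluate(model, slices)
        counter["i"] = 0
        expected = [dice_coefficient(p.mask, (maps[i] > 0.5).astype(np.uint8))
                    for i, p in enumerate(slices)]
        assert list(result.original.records.dice) == pytest.approx(expected)
        assert result.original.mean_dice == pytest.approx(np.mean(expected))

    def test_flip_report_counts_each_flip_as_a_sample(self):
        slices = _slices(5)
        model = _StubModel(lambda xi: xi)
        for p in slices:
            p.image = p.mask.astype(np.float32)
        result = evaluate(model, slices)
        assert result.original.count == 5
        assert result.flip_augmented.count == 10

    def test_per_subject_aggregation_present(self):
        slices = _slices(6)
        model = _StubModel(lambda xi: np.zeros_like(xi))
        result = evaluate(model, slices)
        assert set(result.original.per_subject.index) == {"sub-0", "sub-1"}

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            evaluate(_StubModel(lambda xi: xi), [])

    def test_predict_volume_aligned_nifti_stack(self, tmp_path, small_cohort):
        import nibabel as nib
        from strokeseg.models import build_cnnres
        model, _ = build_cnnres(levels=2, base_filters=8, input_size=32, seed=0)
        vol = small_cohort[0]
        probs = predict_volume(model, vol)
        assert probs.shape == (32, 32, vol.image.shape[2])
        assert probs.min() >= 0.0 and probs.max() <= 1.0
        out = write_prediction_nifti(probs, tmp_path / "prob.nii.gz")
        assert np.allclose(nib.load(out).get_fdata(), probs, atol=1e-6)

    def test_report_serialisation(self, tmp_path):
        import json
        slices = _slices(4)
        model = _StubModel(lambda xi: np.zeros_like(xi))
        result = evaluate(model, slices)
        result.original.write(tmp_path / "report")
        data = json.loads((tmp_path / "report.json").read_text())
        assert data["dataset"] == "synthetic"
        assert data["count"] == 4
        assert (tmp_path / "report.tsv").exists()
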