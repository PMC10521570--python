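"""Residual encoder-decoder network: shape schedule, parameter audit,
convention reconciliation, forward/backward contracts."""

import numpy as np
import pytest

from strokeseg.errors import ArchitectureError, ShapeError
from strokeseg.models import (
    BlockConvention,
    CNNRes,
    PUBLISHED_NON_TRAINABLE,
    PUBLISHED_SCHEDULE,
    PUBLISHED_TRAINABLE,
    build_cnnres,
    cnnres_spec,
    count_parameters,
    default_convention_space,
    reconcile_conventions,
    render_reconciliation,
    verify_parameter_counts,
)


@pytest.fixture(scope="module")
def default_model():
    model, _ = build_cnnres(seed=0)
    return model


class TestShapeSchedule:
    def test_arithmetic_table_matches_published_rows(self):
        spec = cnnres_spec()
        assert spec.block_output_shapes() == PUBLISHED_SCHEDULE

    def test_traced_forward_matches_published_rows(self, default_model):
        assert default_model.trace_block_shapes() == PUBLISHED_SCHEDULE

    def test_toy_variant_shape_contract(self):
        """2 levels, base 8, 32x32 input: stride-2 pooling halves the grid and
        residual concatenation doubles the channels at each level."""
        spec = cnnres_spec(levels=2, base_filters=8, input_size=32)
        blocks = dict(spec.block_output_shapes())
        assert blocks["Transition Block 1"] == (16, 16, 8)
        assert blocks["Residual Block 1"] == (16, 16, 16)
        assert blocks["Transition Block 2"] == (8, 8, 16)
        assert blocks["Residual Block 2"] == (8, 8, 32)

    def test_indivisible_input_rejected(self):
        with pytest.raises(ArchitectureError, match="divisible"):
            cnnres_spec(input_size=150)
        with pytest.raises(ArchitectureError, match="divisible"):
            CNNRes(input_size=150)

    def test_residual_concatenation_doubles_channels(self):
        spec = cnnres_spec()
        transitions = iter([32, 64, 128, 256, 512])
        for block, shape in spec.block_output_shapes():
            if block.startswith("Residual Block") or block == "Bottleneck (residual)":
                assert shape[2] == 2 * next(transitions)


class TestParameterCounts:
    def test_non_trainable_matches_published(self, default_model):
        report = verify_parameter_counts(default_model)
        assert report.non_trainable == PUBLISHED_NON_TRAINABLE
        # closed-form route independently
        assert cnnres_spec().non_trainable == PUBLISHED_NON_TRAINABLE

    def test_counts_invariant_to_seed_and_batch(self):
        a, _ = build_cnnres(seed=1, levels=2, base_filters=8, input_size=32)
        b, _ = build_cnnres(seed=99, levels=2, base_filters=8, input_size=32)
        assert count_parameters(a).total == count_parameters(b).total
        a.forward(np.zeros((1, 32, 32, 1), np.float32))
        a.forward(np.zeros((5, 32, 32, 1), np.float32))
        assert count_parameters(a).total == count_parameters(b).total

    @pytest.mark.parametrize("convention", default_convention_space(),
                             ids=lambda c: f"{c.combine}-w{c.width_factor}"
                                           f"-bn{int(c.compress_bn)}-b{int(c.conv_bias)}")
    def test_engine_equals_closed_form_for_every_convention(self, convention):
        # reduced geometry keeps the sweep cheap; the formulas are identical
        model = CNNRes(convention, levels=2, base_filters=8, input_size=32, seed=0)
        verify_parameter_counts(model)

    def test_disagreement_is_reported_with_layer_name(self, default_model):
        report = count_parameters(default_model)
        assert report.total == report.trainable + report.non_trainable
        # corrupt the closed-form table and expect the audit to name the layer
        bad = default_model.spec.records[2]
        object.__setattr__(bad, "trainable", bad.trainable + 1)
        with pytest.raises(ArchitectureError, match=bad.name):
            verify_parameter_counts(default_model)
        object.__setattr__(bad, "trainable", bad.trainable - 1)


class TestReconciliation:
    def test_default_convention_matches_non_trainable_exactly(self):
        report = reconcile_conventions()
        row = report[(report["combine"] == "concatenate") & (report["width_factor"] == 1.0)
                     & (~report.compress_bn) & (report.conv_bias)]
        assert len(row) == 1
        assert bool(row.exact_non_trainable.iloc[0])
        assert int(row.non_trainable.iloc[0]) == 5952

    def test_half_width_with_compress_bn_does_not_match(self):
        cv = BlockConvention(combine="concatenate", width_factor=0.5, compress_bn=True)
        report = reconcile_conventions([cv])
        assert int(report.non_trainable.iloc[0]) == 7008
        assert not bool(report.exact_non_trainable.iloc[0])

    def test_no_convention_reproduces_published_trainable_total(self):
        report = reconcile_conventions()
        assert not report.exact_trainable.any()
        assert (report.dist_trainable > 0).all()
        text = render_reconciliation(report)
        assert f"{PUBLISHED_TRAINABLE:,}" in text
        assert "no enumerated convention" in text

    def test_empty_space_gives_empty_report(self):
        report = reconcile_conventions([])
        assert len(report) == 0
        assert "empty search space" in render_reconciliation(report)


class TestForwardBackward:
    def test_output_shape_and_sigmoid_range(self):
        model, _ = build_cnnres(levels=2, base_filters=8, input_size=32, seed=0)
        x = np.random.default_rng(0).random((3, 32, 32, 1), dtype=np.float32)
        out = model.forward(x)
        assert out.shape == (3, 32, 32, 1)
        assert np.all(out > 0.0) and np.all(out < 1.0)

    def test_wrong_input_shape_rejected(self):
        model, _ = build_cnnres(levels=2, base_filters=8, input_size=32, seed=0)
        with pytest.raises(ShapeError):
            model.forward(np.zeros((1, 64, 64, 1), np.float32))

    @pytest.mark.parametrize("combine", ["concatenate", "projected_add"])
    def test_whole_network_gradient(self, combine):
        cv = BlockConvention(combine=combine)
        model = CNNRes(cv, levels=2, base_filters=8, input_size=32,
                       dropout_rate=0.0, seed=3)
        rng = np.random.default_rng(0)
        x = rng.random((2, 32, 32, 1), dtype=np.float32)
        t = (rng.random((2, 32, 32, 1)) > 0.7).astype(np.float32)
        for p in model.params():
            p.grad[:] = 0
        pred = model.forward(x, training=True)
        model.backward(2.0 * (pred - t))
        params = model.params()
        ds = [rng.standard_normal(p.value.shape).astype(np.float32) for p in params]
        norm = np.sqrt(sum(float(np.sum(d * d)) for d in ds))
        ds = [d / norm for d in ds]
        analytic = sum(float(np.sum(p.grad.astype(np.float64) * d))
                       for p, d in zip(params, ds))
        h = 1e-3
        for p, d in zip(params, ds):
            p.value += h * d
        lp = float(np.sum((model.forward(x, training=True).astype(np.float64) - t) ** 2))
        for p, d in zip(params, ds):
            p.value -= 2 * h * d
        lm = float(np.sum((model.forward(x, training=True).astype(np.float64) - t) ** 2))
        fd = (lp - lm) / (2 * h)
        assert abs(analytic - fd) <= 0.03 * max(abs(fd), 1e-6)

    def test_state_dict_round_trip(self):
        a = CNNRes(levels=2, base_filters=8, input_size=32, seed=0)
        b = CNNRes(levels=2, base_filters=8, input_size=32, seed=5)
        x = np.random.default_rng(0).random((2, 32, 32, 1), dtype=np.float32)
        assert not np.allclose(a.forward(x), b.forward(x))
        b.load_state_dict(a.state_dict())
        assert np.array_equal(a.forward(x), b.forward(x))
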