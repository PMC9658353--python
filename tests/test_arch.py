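"""Architecture family: block construction, model shapes, parameter census,
multiply counts and seeded Gaussian initialization."""

import numpy as np
import pytest

from incunet import (
    BlockSpec,
    FAMILIES,
    InitSpec,
    ModelSpec,
    build_block,
    build_model,
    count_multiplies,
    count_parameters,
    describe_model,
    init_weights,
)
from incunet.nn import Conv2d, SeparableConv2d, Tensor

SEG_FAMILIES = [f for f in FAMILIES if f != "classifier"]


# -- blocks -------------------------------------------------------------------


def test_inception_block_concatenates_branches():
    spec = BlockSpec.inception_1(16)
    block = build_block(spec, in_channels=8)
    out = block(Tensor(np.random.default_rng(0).normal(size=(2, 8, 12, 12))))
    assert out.data.shape == (2, sum(spec.branch_filters), 12, 12)
    assert sum(spec.branch_filters) == 16


@pytest.mark.parametrize("kind", ["plain_conv", "inception_1", "inception_2"])
def test_blocks_preserve_spatial_size(kind):
    block = build_block(BlockSpec.for_kind(kind, 8), in_channels=4)
    out = block(Tensor(np.zeros((1, 4, 10, 14))))
    assert out.data.shape[2:] == (10, 14)


@pytest.mark.parametrize("kind", ["plain_conv", "inception_1", "inception_2"])
def test_separable_blocks_have_fewer_parameters(kind):
    dense = build_block(BlockSpec.for_kind(kind, 16, ds=False), in_channels=8)
    sep = build_block(BlockSpec.for_kind(kind, 16, ds=True), in_channels=8)
    assert count_parameters(sep) < count_parameters(dense)


def test_block_spec_invariants():
    with pytest.raises(ValueError, match="more filters to 5x5/7x7"):
        BlockSpec("inception_1", ((3, 3), (5, 5)), (12, 4))
    with pytest.raises(ValueError, match="no 7x7"):
        BlockSpec("inception_2", ((3, 3), (7, 7)), (8, 2))
    with pytest.raises(ValueError, match="equal length"):
        BlockSpec("plain_conv", ((3, 3),), (8, 8))


def test_extra_branch_increases_parameters():
    base = BlockSpec("inception_2", ((1, 1), (3, 3), (5, 5)), (4, 8, 2))
    extended = BlockSpec("inception_2", ((1, 1), (3, 3), (5, 5), (5, 5)), (4, 8, 2, 2))
    assert count_parameters(build_block(extended, 4)) > count_parameters(build_block(base, 4))


# -- models -------------------------------------------------------------------


@pytest.mark.parametrize("family", SEG_FAMILIES)
def test_segmentation_forward_contract(family):
    model = init_weights(build_model(ModelSpec(family=family, depth=2, base_filters=8)),
                         seed=0)
    out = model(Tensor(np.random.default_rng(1).normal(size=(2, 4, 24, 24))))
    assert out.data.shape == (2, 1, 24, 24)
    assert out.data.min() >= 0.0 and out.data.max() <= 1.0


def test_classifier_forward_contract():
    model = init_weights(build_model(ModelSpec(family="classifier", in_channels=2,
                                               base_filters=4)), seed=0, scheme="glorot")
    out = model(Tensor(np.random.default_rng(1).normal(size=(3, 2, 24, 24))))
    assert out.data.shape == (3, 1)
    assert ((out.data >= 0) & (out.data <= 1)).all()


def test_classifier_has_nine_weight_layers():
    from incunet.nn import Dense

    model = build_model(ModelSpec(family="classifier", in_channels=2, base_filters=4))
    convs = [m for m in model.modules() if isinstance(m, Conv2d)]
    denses = [m for m in model.modules() if isinstance(m, Dense)]
    assert len(convs) == 5 and len(denses) == 4
    assert [c.out_channels for c in convs] == [4, 8, 16, 32, 64]


def test_indivisible_input_size_rejected():
    model = build_model(ModelSpec(family="baseline_unet", depth=2, base_filters=8))
    with pytest.raises(ValueError, match="divisible"):
        model(Tensor(np.zeros((1, 4, 30, 30))))


def test_unknown_family_rejected():
    with pytest.raises(ValueError, match="unknown family"):
        ModelSpec(family="resnet")
    with pytest.raises(ValueError):
        ModelSpec(in_channels=0)


def test_model_spec_round_trips_through_dict():
    spec = ModelSpec(family="hybrid", depth=3, base_filters=8)
    assert ModelSpec.from_dict(spec.to_dict()) == spec


# -- parameter and multiply census --------------------------------------------


def test_parameter_count_closed_forms():
    assert count_parameters(Conv2d(1, 1, 3, bias=False)) == 9
    # depthwise 4*(3*3) + pointwise 4*8
    assert count_parameters(SeparableConv2d(4, 8, 3, bias=False)) == 68


@pytest.mark.parametrize("dense,separable", [("mi_unet", "ds_mi_unet"),
                                             ("hybrid", "ds_hybrid")])
def test_separable_families_are_lighter(dense, separable):
    kw = dict(depth=2, base_filters=8)
    m_dense = build_model(ModelSpec(family=dense, **kw))
    m_sep = build_model(ModelSpec(family=separable, encoder_residual=False, **kw))
    assert count_parameters(m_sep) < count_parameters(m_dense)
    shape = (4, 16, 16)
    assert count_multiplies(m_sep, shape) < count_multiplies(m_dense, shape)


def test_describe_model_lists_layers():
    table = describe_model(ModelSpec(family="ds_hybrid", depth=2, base_filters=8),
                           input_hw=(16, 16))
    assert {"layer", "kernel", "parameters", "multiplies"} <= set(table.columns)
    assert (table.multiplies > 0).all()
    assert "depthwise" in set(table.layer)


# -- initialization -----------------------------------------------------------


def test_gaussian_init_moments_and_determinism():
    spec = ModelSpec(family="baseline_unet", depth=2, base_filters=32)
    model = init_weights(build_model(spec), InitSpec(0.0, 0.01), seed=42)
    weights = np.concatenate([p.data.ravel() for p in model.parameters() if p.is_weight])
    assert weights.size >= 100_000
    assert abs(weights.std() - 0.01) / 0.01 < 0.02
    assert abs(weights.mean()) < 3 * 0.01 / np.sqrt(weights.size)
    again = init_weights(build_model(spec), InitSpec(0.0, 0.01), seed=42)
    for a, b in zip(model.parameters(), again.parameters()):
        assert np.array_equal(a.data, b.data)


def test_init_zeroes_biases_and_keeps_batchnorm_identity():
    from incunet.nn import BatchNorm2d

    model = init_weights(build_model(ModelSpec(family="hybrid", depth=2, base_filters=8)),
                         seed=0)
    for m in model.modules():
        if isinstance(m, BatchNorm2d):
            assert (m.gamma.data == 1).all() and (m.beta.data == 0).all()
        bias = getattr(m, "bias", None)
        if bias is not None and hasattr(bias, "data"):
            assert not bias.data.any()


def test_init_spec_requires_positive_sigma():
    with pytest.raises(ValueError):
        InitSpec(0.0, 0.0)


# -- gradient flow ------------------------------------------------------------


@pytest.mark.parametrize("family", SEG_FAMILIES)
def test_one_step_changes_the_loss(family, seg_dataset):
    """No dead graph: a single optimization step moves the dice loss."""
    from incunet.nn import Adam, soft_dice_loss

    X, y = seg_dataset
    X, y = X[:4], y[:4]
    model = init_weights(build_model(ModelSpec(family=family, depth=2, base_filters=8)),
                         seed=3)
    opt = Adam(model.parameters(), lr=1e-3)
    pred = model(Tensor(X)).reshape(*y.shape)
    loss0 = soft_dice_loss(pred, y)
    model.zero_grad()
    loss0.backward()
    opt.step()
    loss1 = soft_dice_loss(model(Tensor(X)).reshape(*y.shape), y)
    assert float(loss1.data) != pytest.approx(float(loss0.data), abs=1e-12)
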