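"""Interaction modules, block arithmetic, model wiring and losses."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from disfc import nn
from disfc._autodiff import Tensor
from disfc.errors import ConfigurationError, DimensionError
from disfc.fusioncore import (
    DISFCModel,
    LossWeights,
    ModelConfig,
    bce_loss,
    build_model,
    expanded_feature_names,
    full_conv3d_weight_count,
    inter_modal_outer,
    intra_modal_expand,
    separable_conv3d_weight_count,
    total_loss,
)

rng = np.random.default_rng(0)


# ---------------------------------------------------------------------------
# Intra-modal expansion
# ---------------------------------------------------------------------------

class TestIntraModalExpand:
    def test_pair_example(self):
        np.testing.assert_allclose(intra_modal_expand([2.0, 3.0]), [2, 3, 6])

    def test_clinical_width_gives_105_features(self):
        out = intra_modal_expand(np.ones(14))
        assert out.shape == (105,)  # 14 raw + C(14,2)=91 products

    @given(st.integers(min_value=1, max_value=20))
    @settings(deadline=None, max_examples=20)
    def test_expanded_length_formula(self, d):
        x = np.arange(1.0, d + 1.0)
        assert len(intra_modal_expand(x)) == d + d * (d - 1) // 2
        assert len(intra_modal_expand(x, include_squares=True)) \
            == 2 * d + d * (d - 1) // 2

    def test_zero_vector_maps_to_zero_vector(self):
        np.testing.assert_array_equal(intra_modal_expand(np.zeros(5)), np.zeros(15))

    def test_permutation_consistency(self):
        """Permuting inputs permutes outputs (up to the induced pair order)."""
        x = rng.normal(size=6)
        perm = rng.permutation(6)
        a = sorted(intra_modal_expand(x))
        b = sorted(intra_modal_expand(x[perm]))
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_empty_vector_rejected(self):
        with pytest.raises(DimensionError):
            intra_modal_expand(np.array([]))

    def test_names_align_with_columns(self):
        names = expanded_feature_names(["a", "b", "c"])
        assert names == ["a", "b", "c", "a*b", "a*c", "b*c"]
        out = intra_modal_expand([1.0, 2.0, 3.0])
        assert out[names.index("b*c")] == 6.0


# ---------------------------------------------------------------------------
# Inter-modal outer product
# ---------------------------------------------------------------------------

class TestInterModalOuter:
    def test_unit_basis_places_single_one(self):
        u = np.eye(4)[2]
        v = np.eye(4)[3]
        out = inter_modal_outer(u, v)
        assert out[2 * 4 + 3] == 1.0 and out.sum() == 1.0

    def test_embedding_pair_gives_64(self):
        assert inter_modal_outer(np.ones(8), np.ones(8)).shape == (64,)

    def test_sum_identity(self):
        u, v = rng.normal(size=5), rng.normal(size=7)
        assert inter_modal_outer(u, v).sum() == pytest.approx(u.sum() * v.sum())

    def test_bilinearity(self):
        u, up, v = rng.normal(size=4), rng.normal(size=4), rng.normal(size=6)
        lhs = inter_modal_outer(2.0 * u + 3.0 * up, v)
        rhs = 2.0 * inter_modal_outer(u, v) + 3.0 * inter_modal_outer(up, v)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(DimensionError):
            inter_modal_outer(np.array([]), np.ones(3))


# ---------------------------------------------------------------------------
# Convolution block arithmetic
# ---------------------------------------------------------------------------

class TestSepConv:
    def test_weight_count_example(self):
        assert separable_conv3d_weight_count(16, 32, 3) == 944
        assert full_conv3d_weight_count(16, 32, 3) == 13824

    @pytest.mark.parametrize("cin", [2, 4, 16])
    @pytest.mark.parametrize("cout", [2, 8, 32])
    @pytest.mark.parametrize("k", [3, 5])
    def test_separable_cheaper_than_classical(self, cin, cout, k):
        sep = separable_conv3d_weight_count(cin, cout, k)
        full = full_conv3d_weight_count(cin, cout, k)
        assert sep == k**3 * cin + cin * cout
        assert sep < full

    def test_layer_parameter_count_matches_formula(self):
        layer = nn.SepConv3d(16, 32, 3, rng, bias=False)
        assert layer.parameter_count() == 944

    def test_identity_weights_identity_map(self):
        layer = nn.SepConv3d(1, 1, 1, rng, bias=False)
        layer.dw.data = np.ones((1, 1, 1, 1))
        layer.pw.data = np.ones((1, 1))
        x = rng.normal(size=(1, 1, 4, 4, 4))
        np.testing.assert_allclose(layer(Tensor(x)).data, x)


class TestResidualGroup:
    def test_zero_block_weights_leave_shortcut(self):
        group = nn.ResidualGroup(4, 4, 3, rng, n_blocks=4, dropout=0.0)
        group.set_training(False)
        for blk in group.blocks:
            blk.conv.dw.data[:] = 0
            blk.conv.pw.data[:] = 0
            blk.conv.b.data[:] = 0
            blk.bn.beta.data[:] = 0
        x = rng.normal(size=(2, 4, 5, 5, 5))
        np.testing.assert_allclose(group(Tensor(x)).data, x, atol=1e-10)

    def test_default_depth_is_four_blocks(self):
        assert len(nn.ResidualGroup(2, 2, 3, rng).blocks) == 4

    def test_skip_path_gradient_nonzero_with_zeroed_blocks(self):
        group = nn.ResidualGroup(2, 2, 3, rng, n_blocks=2, dropout=0.0)
        group.set_training(False)
        for blk in group.blocks:
            blk.conv.dw.data[:] = 0
            blk.conv.pw.data[:] = 0
        x = Tensor(rng.normal(size=(1, 2, 4, 4, 4)), requires_grad=True)
        group(x).sum().backward()
        assert np.abs(x.grad).max() > 0


# ---------------------------------------------------------------------------
# Model wiring
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def model():
    return build_model(
        ModelConfig(volume_shape=(8, 8, 8), n_snp_features=10), seed=0)


class TestModel:
    def test_four_heads_with_valid_probabilities(self, model):
        out = model.forward(
            volumes=rng.random((3, 1, 8, 8, 8)),
            clinical=rng.random((3, 14)),
            snps=rng.random((3, 10)))
        assert set(out) == {"mri", "clin", "snp", "fusion"}
        for head, t in out.items():
            assert t.shape == (3, 1)
            assert np.all((t.data > 0) & (t.data < 1)), head

    def test_fusion_stage_input_lengths(self, model):
        # stage 1: 8 + 8 + 64 = 80; stage 2: hidden 16 + 8 = 24
        assert model.fuse_fc1.fc.w.shape[0] == 80
        assert model.fuse_out.w.shape[0] == 24

    def test_parameter_count_matches_analytic_sum(self, model):
        cfg = model.cfg
        k3 = cfg.kernel_size ** 3
        e = cfg.embedding_dim

        def sepblock(cin, cout):
            return (k3 * cin + cin * cout + cout) + 2 * cout  # conv+bias, BN

        c1, c2 = cfg.stage_channels
        spatial = (sepblock(1, cfg.stem_channels)
                   + sepblock(cfg.stem_channels, c1)
                   + cfg.n_residual_blocks * sepblock(c1, c1)
                   + sepblock(c1, c2)
                   + (c2 * e + e) + (e + 1))
        h = cfg.branch_hidden_dim
        clin = (105 * h + h + 2 * h) + (h * e + e) + (e + 1)
        snp = (cfg.n_snp_features * h + h + 2 * h) + (h * e + e) + (e + 1)
        f = cfg.fusion_hidden_dim
        fusion = ((2 * e + e * e) * f + f + 2 * f) + ((f + e) * 1 + 1)
        assert model.parameter_count() == spatial + clin + snp + fusion

    def test_fresh_model_near_chance_loss_on_balanced_data(self):
        model = build_model(
            ModelConfig(volume_shape=(8, 8, 8), n_snp_features=10), seed=3)
        model.set_training(False)
        n = 40
        out = model.forward(
            volumes=rng.random((n, 1, 8, 8, 8)),
            clinical=rng.random((n, 14)),
            snps=rng.random((n, 10)))
        y = np.tile([0.0, 1.0], n // 2)
        assert bce_loss(y, out["fusion"].data) == pytest.approx(np.log(2), abs=0.15)

    def test_single_modality_config_uses_branch_head(self):
        model = build_model(
            ModelConfig(volume_shape=(8, 8, 8), modalities=("clin",)), seed=0)
        out = model.forward(clinical=rng.random((4, 14)))
        np.testing.assert_array_equal(out["fusion"].data, out["clin"].data)

    def test_genetic_embedding_permutation_changes_output(self, model):
        vol = rng.random((2, 1, 8, 8, 8))
        clin = rng.random((2, 14))
        snp = rng.random((2, 10))
        base = model.predict_proba(volumes=vol, clinical=clin, snps=snp)
        flipped = model.predict_proba(volumes=vol, clinical=clin,
                                      snps=snp[:, ::-1])
        assert not np.allclose(base, flipped)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(n_residual_blocks=0)
        with pytest.raises(ConfigurationError):
            ModelConfig(embedding_dim=0)
        with pytest.raises(ConfigurationError):
            ModelConfig(modalities=("mri", "pet"))

    def test_checkpoint_round_trip_and_fingerprint_guard(self, model, tmp_path):
        path = tmp_path / "w.npz"
        model.save_weights(path)
        clone = build_model(model.cfg, seed=99)
        clone.load_weights(path)
        x = rng.random((2, 1, 8, 8, 8))
        np.testing.assert_allclose(
            clone.predict_proba(volumes=x, clinical=rng.random((2, 14)),
                                snps=rng.random((2, 10))).shape, (2,))
        for (_, a), (_, b) in zip(model.named_parameters(),
                                  clone.named_parameters()):
            np.testing.assert_array_equal(a.data, b.data)
        other = build_model(
            ModelConfig(volume_shape=(8, 8, 8), n_snp_features=11), seed=0)
        with pytest.raises(ConfigurationError):
            other.load_weights(path)


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

class TestLosses:
    def test_bce_matches_hand_arithmetic(self):
        assert bce_loss([1, 0], [0.9, 0.2]) == pytest.approx(
            -0.5 * (np.log(0.9) + np.log(0.8)))
        assert bce_loss([1, 0], [0.9, 0.2]) == pytest.approx(0.1643, abs=5e-5)

    def test_bce_at_half_is_log_two(self):
        assert bce_loss(np.array([1, 0, 1]), np.full(3, 0.5)) \
            == pytest.approx(np.log(2))

    def test_bce_perfect_predictions_near_zero(self):
        assert bce_loss([1.0, 0.0], [1.0, 0.0]) == pytest.approx(0.0, abs=1e-6)

    def test_bce_length_mismatch(self):
        with pytest.raises(DimensionError):
            bce_loss([1, 0, 1], [0.5, 0.5])

    def test_total_loss_uniform_heads_scale_by_3_5(self):
        losses = dict.fromkeys(("fusion", "mri", "clin", "snp"), 0.4)
        assert total_loss(losses) == pytest.approx(3.5 * 0.4)

    def test_total_loss_default_weighted_example(self):
        assert total_loss((0.2, 0.4, 0.6, 0.8)) == pytest.approx(1.5)

    def test_total_loss_fusion_only_weights(self):
        w = LossWeights(alpha=1.0, beta_mri=0, beta_clin=0, beta_snp=0)
        assert total_loss((0.7, 9.9, 9.9, 9.9), w) == pytest.approx(0.7)

    def test_total_loss_rejects_negative(self):
        with pytest.raises(ValueError):
            total_loss((0.1, -0.2, 0.3, 0.4))

    def test_total_loss_monotone_in_each_head(self):
        base = dict.fromkeys(("fusion", "mri", "clin", "snp"), 0.3)
        ref = total_loss(base)
        for head in base:
            bumped = dict(base, **{head: 0.5})
            assert total_loss(bumped) > ref

    def test_loss_weights_validate(self):
        with pytest.raises(ConfigurationError):
            LossWeights(alpha=0.0)
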