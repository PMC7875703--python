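"""The disease-embedding encoder: projections, input assembly, masking,
augmentation, and the attention oracle."""

import numpy as np
import pytest

from edembed.model import DimDiscriminator, DiseaseEncoder, ModelConfig, augment
from edembed.nn import Tensor


@pytest.fixture(scope="module")
def encoder(small_model_config):
    return DiseaseEncoder(small_model_config, np.random.default_rng(0))


def _random_inputs(rng, config, b=3):
    s = rng.normal(size=(b, config.d_struct))
    cc = rng.normal(size=(b, config.d_text))
    hx = rng.normal(size=(b, config.d_text))
    return s, cc, hx


class TestProjections:
    def test_structural_projection_matches_matrix_oracle(self, small_model_config):
        enc = DiseaseEncoder(small_model_config, np.random.default_rng(1))
        rng = np.random.default_rng(2)
        s = rng.normal(size=(4, 15))
        out = enc.project_structural(s).data
        # independent oracle: explicit matrix products + exact GELU
        from scipy.special import erf

        h = s @ enc.l_s.layers[0].weight.data + enc.l_s.layers[0].bias.data
        h = h * 0.5 * (1 + erf(h / np.sqrt(2)))
        expected = h @ enc.l_s.layers[1].weight.data + enc.l_s.layers[1].bias.data
        assert np.allclose(out, expected)

    def test_zero_parameters_give_zero_output(self, small_model_config):
        enc = DiseaseEncoder(small_model_config, np.random.default_rng(3))
        for layer in enc.l_s.layers:
            layer.weight.data[:] = 0.0
            layer.bias.data[:] = 0.0
        assert not enc.project_structural(np.ones((2, 15))).data.any()

    def test_text_slots_share_one_network(self, encoder, small_model_config):
        rng = np.random.default_rng(4)
        f = rng.normal(size=(2, small_model_config.d_text))
        assert np.array_equal(encoder.project_text(f).data, encoder.l_b(Tensor(f)).data)

    def test_wrong_width_rejected(self, encoder):
        with pytest.raises(ValueError):
            encoder.project_structural(np.ones((2, 14)))
        with pytest.raises(ValueError):
            encoder.project_text(np.ones((2, 10)))


class TestAssembly:
    def test_mask_follows_history_validity(self, encoder, small_model_config):
        rng = np.random.default_rng(5)
        s, cc, hx = _random_inputs(rng, small_model_config)
        m_s = encoder.project_structural(s)
        m_cc, m_hx = encoder.project_text(cc), encoder.project_text(hx)
        asm = encoder.assemble_input(m_s, m_cc, m_hx, [1, 0, 1])
        assert np.array_equal(asm.mask, [[1, 1, 1, 1], [1, 1, 1, 0], [1, 1, 1, 1]])
        assert (asm.segment_ids == 0).all()
        assert np.array_equal(asm.position_ids[0], [0, 1, 2, 3])

    def test_zero_tables_reduce_to_token_embeddings(self, small_model_config):
        enc = DiseaseEncoder(small_model_config, np.random.default_rng(6))
        enc.position_table.data[:] = 0.0
        enc.segment_table.data[:] = 0.0
        rng = np.random.default_rng(7)
        s, cc, hx = _random_inputs(rng, small_model_config, b=2)
        m_s = enc.project_structural(s)
        m_cc, m_hx = enc.project_text(cc), enc.project_text(hx)
        asm = enc.assemble_input(m_s, m_cc, m_hx, [1, 1])
        assert np.allclose(asm.tokens.data[:, 1, :], m_s.data)
        assert np.allclose(asm.tokens.data[:, 0, :], enc.cls_token.data)


class TestEmbed:
    def test_coordinates_bounded_by_tanh(self, encoder, small_model_config):
        rng = np.random.default_rng(8)
        s, cc, hx = _random_inputs(rng, small_model_config, b=16)
        eps = encoder(10.0 * s, cc, hx, np.ones(16, dtype=int)).data
        assert np.abs(eps).max() <= 1.0

    def test_masked_history_content_cannot_change_embedding(self, small_model_config):
        """Mask contract on the encoder: with hx_valid=0, any change to the
        history feature leaves epsilon exactly unchanged (100 random
        parameterizations and perturbations)."""
        rng = np.random.default_rng(9)
        for trial in range(100):
            enc = DiseaseEncoder(small_model_config, np.random.default_rng(trial))
            s, cc, hx = _random_inputs(rng, small_model_config, b=2)
            base = enc(s, cc, hx, [0, 0]).data
            out = enc(s, cc, hx + rng.normal(scale=10.0, size=hx.shape), [0, 0]).data
            assert np.array_equal(base, out)

    def test_valid_history_content_does_change_embedding(self, encoder, small_model_config):
        rng = np.random.default_rng(10)
        s, cc, hx = _random_inputs(rng, small_model_config, b=2)
        base = encoder(s, cc, hx, [1, 1]).data
        out = encoder(s, cc, hx + 1.0, [1, 1]).data
        assert not np.array_equal(base, out)

    def test_position_embeddings_make_slot_order_matter(self, encoder, small_model_config):
        rng = np.random.default_rng(11)
        s, cc, hx = _random_inputs(rng, small_model_config, b=4)
        m_s = encoder.project_structural(s)
        m_cc, m_hx = encoder.project_text(cc), encoder.project_text(hx)
        ones = np.ones(4, dtype=int)
        a = encoder.embed(encoder.assemble_input(m_s, m_cc, m_hx, ones)).data
        b = encoder.embed(encoder.assemble_input(m_cc, m_s, m_hx, ones)).data
        assert not np.allclose(a, b)

    def test_single_layer_matches_hand_rolled_attention_oracle(self):
        """1-layer 1-head encoder vs an independent numpy softmax-attention
        + post-norm computation."""
        config = ModelConfig(d_hidden=8, n_layers=1, n_heads=1, d_text=16)
        enc = DiseaseEncoder(config, np.random.default_rng(12))
        rng = np.random.default_rng(13)
        s, cc, hx = _random_inputs(rng, config, b=1)
        m_s = enc.project_structural(s)
        m_cc, m_hx = enc.project_text(cc), enc.project_text(hx)
        asm = enc.assemble_input(m_s, m_cc, m_hx, [1])
        eps = enc.embed(asm).data[0]

        x = asm.tokens.data[0]  # (4, 8)
        layer = enc.encoder.layers[0]
        W = {n: getattr(layer, n).weight.data for n in ("wq", "wk", "wv", "wo", "ff1", "ff2")}
        B = {n: getattr(layer, n).bias.data for n in ("wq", "wk", "wv", "wo", "ff1", "ff2")}
        q, k, v = x @ W["wq"] + B["wq"], x @ W["wk"] + B["wk"], x @ W["wv"] + B["wv"]
        scores = q @ k.T / np.sqrt(8)
        attn = np.exp(scores - scores.max(axis=-1, keepdims=True))
        attn /= attn.sum(axis=-1, keepdims=True)
        h = (attn @ v) @ W["wo"] + B["wo"]

        def layer_norm(y, norm):
            mu, var = y.mean(-1, keepdims=True), y.var(-1, keepdims=True)
            return (y - mu) / np.sqrt(var + 1e-5) * norm.gain.data + norm.shift.data

        from scipy.special import erf

        x1 = layer_norm(x + h, layer.norm1)
        ff = x1 @ W["ff1"] + B["ff1"]
        ff = ff * 0.5 * (1 + erf(ff / np.sqrt(2)))
        x2 = layer_norm(x1 + ff @ W["ff2"] + B["ff2"], layer.norm2)
        assert np.allclose(eps, np.tanh(x2[0]), atol=1e-12)

    def test_deterministic_in_inference(self, encoder, small_model_config):
        rng = np.random.default_rng(14)
        s, cc, hx = _random_inputs(rng, small_model_config)
        a = encoder(s, cc, hx, [1, 1, 0]).data
        b = encoder(s, cc, hx, [1, 1, 0]).data
        assert np.array_equal(a, b)


class TestDiscriminator:
    def test_scores_in_unit_interval(self, small_model_config):
        disc = DimDiscriminator(small_model_config, np.random.default_rng(15))
        rng = np.random.default_rng(16)
        d = small_model_config.d_hidden
        eps, m = Tensor(rng.uniform(-1, 1, (5, d))), Tensor(rng.normal(size=(5, d)))
        out = disc(eps, m, m, m, np.ones(5, dtype=int)).data
        assert ((out > 0) & (out < 1)).all()

    def test_masked_history_slot_cannot_change_score(self, small_model_config):
        rng = np.random.default_rng(17)
        d = small_model_config.d_hidden
        for trial in range(100):
            disc = DimDiscriminator(small_model_config, np.random.default_rng(200 + trial))
            eps = Tensor(rng.uniform(-1, 1, (2, d)))
            m_s, m_cc = Tensor(rng.normal(size=(2, d))), Tensor(rng.normal(size=(2, d)))
            hx_a = Tensor(rng.normal(size=(2, d)))
            hx_b = hx_a + Tensor(rng.normal(scale=10.0, size=(2, d)))
            a = disc(eps, m_s, m_cc, hx_a, [0, 0]).data
            b = disc(eps, m_s, m_cc, hx_b, [0, 0]).data
            assert np.array_equal(a, b)

    def test_segment_layout(self, small_model_config):
        # level 0 on [CLS] and epsilon, level 1 on [SEP] and the M tokens:
        # changing segment row 1 must not affect a model where those tokens
        # are re-zeroed, but must affect the full forward pass
        disc = DimDiscriminator(small_model_config, np.random.default_rng(18))
        rng = np.random.default_rng(19)
        d = small_model_config.d_hidden
        args = (Tensor(rng.uniform(-1, 1, (2, d))), Tensor(rng.normal(size=(2, d))),
                Tensor(rng.normal(size=(2, d))), Tensor(rng.normal(size=(2, d))),
                np.ones(2, dtype=int))
        base = disc(*args).data
        disc.segment_table.data[1] += 1.0
        assert not np.array_equal(base, disc(*args).data)


class TestAugment:
    def test_identity_when_disabled(self, small_model_config):
        config = ModelConfig.small_preset(history_mask_prob=0.0, noise_fraction=0.0)
        rng = np.random.default_rng(20)
        s = rng.normal(size=(5, 15))
        hxv = np.ones(5, dtype=int)
        s2, hxv2 = augment(s, hxv, np.ones(15), config, rng)
        assert np.array_equal(s, s2) and np.array_equal(hxv, hxv2)

    def test_full_mask_probability_drops_all_histories(self, small_model_config):
        config = ModelConfig.small_preset(history_mask_prob=1.0)
        rng = np.random.default_rng(21)
        _, hxv2 = augment(np.zeros((8, 15)), np.ones(8, dtype=int), np.ones(15),
                          config, rng)
        assert not hxv2.any()

    def test_masking_frequency_monte_carlo(self):
        config = ModelConfig.small_preset(history_mask_prob=0.3, noise_fraction=0.0)
        rng = np.random.default_rng(22)
        _, hxv2 = augment(np.zeros((10_000, 15)), np.ones(10_000, dtype=int),
                          np.ones(15), config, rng)
        assert 1.0 - hxv2.mean() == pytest.approx(0.3, abs=0.02)

    def test_noise_respects_field_sd_and_skips_gender(self):
        config = ModelConfig.small_preset(history_mask_prob=0.0, noise_fraction=0.1)
        rng = np.random.default_rng(23)
        sd = np.arange(1.0, 16.0)
        s2, _ = augment(np.zeros((20_000, 15)), np.ones(20_000, dtype=int), sd,
                        config, rng)
        emp = s2.std(axis=0)
        assert np.allclose(emp[2:], 0.1 * sd[2:], rtol=0.05)
        assert emp[1] == 0.0  # gender slot untouched
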