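"""Encoder contracts: shapes, determinism, bidirectionality, subword alignment."""

import numpy as np
import pytest

from wcrf.encoder import (
    IGN_LABEL,
    UNK_ID,
    EncoderConfig,
    Vocabulary,
    align_subword_labels,
    encode_batch,
    encode_tokens,
    init_encoder_params,
    self_attention,
)


@pytest.fixture(scope="module")
def setup():
    cfg = EncoderConfig(vocab_size=30, embed_dim=8, hidden_dim=8, dropout_rate=0.0, seed=4)
    return cfg, init_encoder_params(cfg)


class TestEncodeTokens:
    def test_output_row_count_matches_input(self, setup):
        cfg, params = setup
        for n in (1, 5, 12):
            h = encode_tokens(list(range(2, 2 + n)), params, cfg)
            assert h.shape == (n, cfg.output_dim)

    def test_deterministic_in_eval_mode(self, setup):
        cfg, params = setup
        ids = [3, 4, 5, 6]
        h1 = encode_tokens(ids, params, cfg)
        h2 = encode_tokens(ids, params, cfg)
        assert np.array_equal(h1, h2)

    def test_backward_direction_carries_context(self, setup):
        """Changing the last token must change the first token's state."""
        cfg, params = setup
        base = encode_tokens([3, 4, 5, 6], params, cfg)
        perturbed = encode_tokens([3, 4, 5, 7], params, cfg)
        assert np.abs(base[0] - perturbed[0]).max() > 1e-8

    def test_out_of_vocab_id_rejected(self, setup):
        cfg, params = setup
        with pytest.raises(IndexError):
            encode_tokens([cfg.vocab_size], params, cfg)

    def test_padding_does_not_leak_into_real_positions(self, setup):
        cfg, params = setup
        ids = np.array([[3, 4, 5, 0, 0]])
        mask = np.array([[1.0, 1, 1, 0, 0]])
        h_padded, _ = encode_batch(ids, mask, params, cfg)
        h_exact = encode_tokens([3, 4, 5], params, cfg)
        assert np.allclose(h_padded[0, :3], h_exact, atol=1e-12)

    def test_dropout_only_in_train_mode(self, setup):
        cfg0, params = setup
        cfg = EncoderConfig(vocab_size=30, embed_dim=8, hidden_dim=8, dropout_rate=0.5, seed=4)
        ids = np.array([[3, 4, 5]])
        mask = np.ones((1, 3))
        h_eval, _ = encode_batch(ids, mask, params, cfg)
        h_train, _ = encode_batch(
            ids, mask, params, cfg, train=True, dropout_rng=np.random.default_rng(0)
        )
        assert not np.allclose(h_eval, h_train)


class TestCharComposition:
    def test_char_encoder_runs_and_differentiates_words(self):
        cfg = EncoderConfig(
            vocab_size=10, embed_dim=8, hidden_dim=8, use_char=True,
            char_dim=4, dropout_rate=0.0, seed=1,
        )
        params = init_encoder_params(cfg)
        h1 = encode_tokens([2, 3], params, cfg, char_ids=[[1, 2, 3], [4, 5]])
        h2 = encode_tokens([2, 3], params, cfg, char_ids=[[1, 2, 4], [4, 5]])
        assert h1.shape == (2, cfg.output_dim)
        assert np.abs(h1 - h2).max() > 1e-9


class TestSelfAttention:
    def test_single_position_returns_value_projection(self, setup):
        cfg = EncoderConfig(
            vocab_size=30, embed_dim=8, hidden_dim=8, use_attention=True,
            dropout_rate=0.0, seed=4,
        )
        params = init_encoder_params(cfg)
        h = np.random.default_rng(0).normal(size=(1, cfg.output_dim))
        out, attn = self_attention(h, params)
        assert attn == pytest.approx(np.ones((1, 1)))
        assert np.allclose(out, h @ params["attn_wv"], atol=1e-12)

    def test_attention_rows_sum_to_one(self):
        cfg = EncoderConfig(
            vocab_size=30, embed_dim=8, hidden_dim=8, use_attention=True,
            dropout_rate=0.0, seed=4,
        )
        params = init_encoder_params(cfg)
        h = np.random.default_rng(1).normal(size=(7, cfg.output_dim))
        out, attn = self_attention(h, params)
        assert out.shape == h.shape
        assert np.abs(attn.sum(axis=1) - 1.0).max() < 1e-12

    def test_matches_dense_reference_evaluation(self):
        cfg = EncoderConfig(
            vocab_size=30, embed_dim=8, hidden_dim=8, use_attention=True,
            dropout_rate=0.0, seed=4,
        )
        params = init_encoder_params(cfg)
        rng = np.random.default_rng(2)
        h = rng.normal(size=(5, cfg.output_dim))
        out, _ = self_attention(h, params)
        # independent dense evaluation of the attention formula
        q, k, v = h @ params["attn_wq"], h @ params["attn_wk"], h @ params["attn_wv"]
        s = q @ k.T / np.sqrt(h.shape[1])
        e = np.exp(s - s.max(axis=1, keepdims=True))
        a = e / e.sum(axis=1, keepdims=True)
        assert np.allclose(out, a @ v, atol=1e-12)

    def test_empty_input_rejected(self, setup):
        cfg, params = setup
        with pytest.raises(ValueError):
            self_attention(np.zeros((0, 16)), params)


class TestSubwordAlignment:
    def test_first_piece_keeps_label(self):
        subtoks, sublabs = align_subword_labels(
            ["depression"], ["B-ADR"], {"depression": ["de", "##press", "##ion"]}
        )
        assert subtoks == ["de", "##press", "##ion"]
        assert sublabs == ["B-ADR", IGN_LABEL, IGN_LABEL]

    def test_single_piece_word_unchanged(self):
        subtoks, sublabs = align_subword_labels(["ok", "tired"], ["O", "B-ADR"], {})
        assert subtoks == ["ok", "tired"]
        assert sublabs == ["O", "B-ADR"]

    def test_non_ignored_count_equals_word_count(self):
        words = ["a", "bcd", "ef"]
        splits = {"bcd": ["b", "##cd"], "ef": ["e", "##f"]}
        _, sublabs = align_subword_labels(words, ["O", "B-ADR", "I-ADR"], splits)
        assert sum(1 for l in sublabs if l != IGN_LABEL) == len(words)

    def test_empty_split_rejected(self):
        with pytest.raises(ValueError):
            align_subword_labels(["x"], ["O"], {"x": []})


class TestVocabulary:
    def test_unknown_maps_to_unk(self):
        v = Vocabulary(["sleep", "paralysis"])
        assert v.id_of("sleep") == 2
        assert v.id_of("zzz") == UNK_ID
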