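"""Encoder contracts: tokenization, attention math, pooling, persistence."""

import numpy as np
import pytest

from prser.autodiff import Tensor
from prser.encoder import (Encoder, EncoderConfig, POOLING_STRATEGIES,
                           SentenceEncoder, WhitespaceTokenizer, attention)

VOCAB_TEXTS = ["leaf spot wilt", "mildew rust blight", "rot canker scab"]


@pytest.fixture()
def small_encoder():
    tok = WhitespaceTokenizer.fit(VOCAB_TEXTS)
    cfg = EncoderConfig(vocab_size=len(tok), dim=8, heads=2, layers=2,
                        max_len=12, seed=42)
    return Encoder(cfg), tok


class TestTokenizer:
    def test_long_text_truncated_to_max_len(self):
        tok = WhitespaceTokenizer.fit(["a b c d e f g h"])
        seq = tok.tokenize("a b c d e f g h", max_len=4)
        assert len(seq.token_ids) == 4
        assert seq.attention_mask.sum() == 4

    def test_empty_text_is_cls_only(self):
        tok = WhitespaceTokenizer.fit(VOCAB_TEXTS)
        seq = tok.tokenize("", max_len=6)
        assert seq.attention_mask.sum() == 1
        assert seq.token_ids[0] == tok.stoi["[CLS]"]

    def test_short_text_padded_with_zero_ids(self):
        tok = WhitespaceTokenizer.fit(VOCAB_TEXTS)
        seq = tok.tokenize("leaf spot", max_len=6)
        assert seq.attention_mask.sum() == 3  # [CLS] + 2 tokens
        assert list(seq.token_ids[3:]) == [0, 0, 0]

    def test_unknown_token_maps_to_unk(self):
        tok = WhitespaceTokenizer.fit(VOCAB_TEXTS)
        seq = tok.tokenize("neverseen", max_len=4)
        assert seq.token_ids[1] == tok.stoi["[UNK]"]

    def test_oov_buckets_hash_consistently_and_spread(self):
        tok = WhitespaceTokenizer.fit(VOCAB_TEXTS, oov_buckets=16)
        a1 = tok.tokenize("strange", 4).token_ids[1]
        a2 = tok.tokenize("strange", 4).token_ids[1]
        b = tok.tokenize("different", 4).token_ids[1]
        assert a1 == a2 >= len(tok.itos)
        assert b != a1

    def test_vocab_file_round_trip(self, tmp_path):
        tok = WhitespaceTokenizer.fit(VOCAB_TEXTS, oov_buckets=8)
        tok.save(tmp_path / "vocab.txt")
        back = WhitespaceTokenizer.load(tmp_path / "vocab.txt")
        assert back.itos == tok.itos
        assert back.oov_buckets == 8
        text = "leaf unknowntoken"
        np.testing.assert_array_equal(back.tokenize(text, 8).token_ids,
                                      tok.tokenize(text, 8).token_ids)


class TestAttention:
    def test_single_token_returns_v(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(1, 3))
        out = attention(rng.normal(size=(1, 3)), rng.normal(size=(1, 3)), v)
        np.testing.assert_allclose(out, v, atol=1e-12)

    def test_two_token_hand_value(self):
        # d_k=1, Q=K=V=[[1],[0]]: softmax rows [e/(e+1), 1/(e+1)] and [.5,.5]
        q = np.array([[1.0], [0.0]])
        out = attention(q, q, q)
        np.testing.assert_allclose(out, [[np.e / (np.e + 1)], [0.5]], atol=1e-4)
        np.testing.assert_allclose(out, [[0.7311], [0.5]], atol=1e-4)

    def test_rows_are_convex_combinations(self):
        rng = np.random.default_rng(1)
        Q, K = rng.normal(size=(5, 4)), rng.normal(size=(5, 4))
        V = rng.normal(size=(5, 2))
        out = attention(Q, K, V)
        assert out.shape == (5, 2)
        assert np.all(out.min(axis=0) >= V.min(axis=0) - 1e-12)
        assert np.all(out.max(axis=0) <= V.max(axis=0) + 1e-12)

    def test_all_zero_mask_rejected(self):
        x = np.ones((2, 3))
        with pytest.raises(ValueError):
            attention(x, x, x, mask=np.zeros(2))

    def test_masked_key_ignored(self):
        rng = np.random.default_rng(2)
        Q, K = rng.normal(size=(3, 4)), rng.normal(size=(3, 4))
        V = rng.normal(size=(3, 2))
        masked = attention(Q, K, V, mask=np.array([1.0, 1.0, 0.0]))
        V2 = V.copy()
        V2[2] = 999.0  # masked row must not leak into the output
        np.testing.assert_allclose(masked, attention(Q, K, V2,
                                                     mask=np.array([1.0, 1.0, 0.0])))


def _np_block_oracle(enc: Encoder, layer: int, x: np.ndarray,
                     mask: np.ndarray) -> np.ndarray:
    """Independent step-by-step recomputation of one encoder block."""
    cfg = enc.config
    p = {k: v.data for k, v in enc.params.items()}
    pre = f"l{layer}_"
    B, T, d = x.shape

    def ln(v, g, b):
        mu = v.mean(-1, keepdims=True)
        var = v.var(-1, keepdims=True)
        return g * (v - mu) / np.sqrt(var + 1e-12) + b

    heads_out = []
    for h in range(cfg.heads):
        sl = slice(h * cfg.d_k, (h + 1) * cfg.d_k)
        outs = []
        for bi in range(B):
            q = x[bi] @ p[pre + "Wq"][:, sl] + p[pre + "bq"][sl]
            k = x[bi] @ p[pre + "Wk"][:, sl] + p[pre + "bk"][sl]
            v = x[bi] @ p[pre + "Wv"][:, sl] + p[pre + "bv"][sl]
            outs.append(attention(q, k, v, mask=mask[bi]))
        heads_out.append(np.stack(outs))
    concat = np.concatenate(heads_out, axis=-1)
    attn = concat @ p[pre + "Wo"] + p[pre + "bo"]
    x1 = ln(x + attn, p[pre + "ln1_g"], p[pre + "ln1_b"])
    from scipy.special import erf
    hmid = x1 @ p[pre + "W1"] + p[pre + "b1"]
    act = hmid * 0.5 * (1 + erf(hmid / np.sqrt(2)))
    ffn = act @ p[pre + "W2"] + p[pre + "b2"]
    return ln(x1 + ffn, p[pre + "ln2_g"], p[pre + "ln2_b"])


class TestEncoder:
    def test_multi_head_block_matches_independent_recomputation(self, small_encoder):
        enc, tok = small_encoder
        ids = np.array([[2, 4, 5, 0], [2, 6, 0, 0]])
        mask = np.array([[1, 1, 1, 0], [1, 1, 0, 0]], dtype=float)
        outputs = enc.forward(ids, mask)
        expected = _np_block_oracle(enc, 0, outputs[0].data, mask)
        got = outputs[1].data
        live = mask.astype(bool)
        np.testing.assert_allclose(got[live], expected[live], atol=1e-8)

    def test_layer_output_count(self, small_encoder):
        enc, _ = small_encoder
        outs = enc.forward(np.array([[2, 4]]), np.array([[1, 1]]))
        assert len(outs) == enc.config.layers + 1

    def test_deterministic_inference(self, small_encoder):
        enc, tok = small_encoder
        ids = np.array([[2, 4, 5]])
        mask = np.array([[1, 1, 1]])
        a = enc.forward(ids, mask)[-1].data
        b = enc.forward(ids, mask)[-1].data
        assert np.array_equal(a, b)

    def test_out_of_vocab_id_rejected(self, small_encoder):
        enc, _ = small_encoder
        with pytest.raises(ValueError):
            enc.forward(np.array([[enc.config.vocab_size]]), np.array([[1]]))

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            EncoderConfig(vocab_size=10, dim=10, heads=3)
        with pytest.raises(ValueError):
            EncoderConfig(vocab_size=10, max_len=1)

    @pytest.mark.parametrize("strategy", POOLING_STRATEGIES)
    def test_padding_invariance_of_every_pooling(self, strategy, small_encoder):
        enc, tok = small_encoder
        short = tok.tokenize("leaf spot wilt", max_len=4)
        padded = tok.tokenize("leaf spot wilt", max_len=12)
        e_short = enc.pool(enc.forward(short.token_ids, short.attention_mask),
                           strategy, short.attention_mask).data
        e_padded = enc.pool(enc.forward(padded.token_ids, padded.attention_mask),
                            strategy, padded.attention_mask).data
        np.testing.assert_allclose(e_short, e_padded, atol=1e-6)

    @pytest.mark.parametrize("strategy", POOLING_STRATEGIES)
    def test_pooled_vectors_finite_with_expected_dim(self, strategy, small_encoder):
        enc, tok = small_encoder
        seq = tok.tokenize("mildew rust", max_len=6)
        v = enc.pool(enc.forward(seq.token_ids, seq.attention_mask),
                     strategy, seq.attention_mask).data
        assert np.all(np.isfinite(v))
        want = enc.config.pooler_width if strategy == "pooler" else enc.config.dim
        assert v.shape == (1, want)

    def test_mean_pooling_ignores_padding_rows(self, small_encoder):
        enc, _ = small_encoder
        rows = np.zeros((1, 3, 4))
        rows[0, 0] = [1, 3, 1, 3]
        rows[0, 1] = [3, 1, 3, 1]
        rows[0, 2] = [9, 9, 9, 9]  # masked: must not shift the mean
        mask = np.array([[1, 1, 0]])
        fake = [Tensor(rows), Tensor(rows)]
        out = enc.pool(fake, "mean", mask).data
        np.testing.assert_allclose(out, [[2, 2, 2, 2]])

    def test_pooler_is_tanh_of_dense_cls(self, small_encoder):
        enc, _ = small_encoder
        d = enc.config.dim
        enc.params["pooler_W"] = Tensor(np.eye(d), requires_grad=True)
        enc.params["pooler_b"] = Tensor(np.zeros(d), requires_grad=True)
        rows = np.random.default_rng(3).normal(size=(1, 2, d))
        fake = [Tensor(rows), Tensor(rows)]
        out = enc.pool(fake, "pooler", np.array([[1, 1]])).data
        np.testing.assert_allclose(out, np.tanh(rows[:, 0, :]), atol=1e-12)

    def test_unknown_strategy_rejected(self, small_encoder):
        enc, _ = small_encoder
        with pytest.raises(ValueError):
            enc.pool([Tensor(np.zeros((1, 2, 8)))] * 2, "median", np.ones((1, 2)))


class TestPersistence:
    def test_checkpoint_round_trip_bitwise(self, tmp_path, small_encoder):
        enc, tok = small_encoder
        enc.save(tmp_path / "enc.zip")
        back = Encoder.load(tmp_path / "enc.zip")
        assert back.config == enc.config
        for key, val in enc.params.items():
            assert np.array_equal(back.params[key].data, val.data)

    def test_sentence_encoder_round_trip(self, tmp_path, small_encoder):
        enc, tok = small_encoder
        sent = SentenceEncoder(enc, tok, "mean")
        sent.save(tmp_path / "model")
        back = SentenceEncoder.load(tmp_path / "model")
        texts = ["leaf spot", "rot canker scab"]
        np.testing.assert_array_equal(back(texts), sent(texts))
        assert back.fingerprint() == sent.fingerprint()
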