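"""Trainable bi-encoder: token/position embeddings, a stack of multi-head
self-attention blocks, and the pooling operators that reduce per-token
outputs to one sentence vector.

The attention core is ``Softmax(QK^T / sqrt(d_k)) V`` with padded key
positions excluded from the softmax; each block wraps it with the standard
residual connection, layer normalization and a two-layer feed-forward
sublayer of the BERT family. The encoder is deliberately small enough to
train from scratch on one CPU; external pretrained encoders plug in through
the ``embed(texts) -> matrix`` callable contract instead.
"""

from __future__ import annotations

import hashlib
import io
import json
import zipfile
from dataclasses import dataclass, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .autodiff import Tensor, layer_norm, softmax as t_softmax
from .corpus import FIELD_SEPARATOR

PAD, UNK, CLS = "[PAD]", "[UNK]", "[CLS]"
SPECIAL_TOKENS = (PAD, UNK, CLS, FIELD_SEPARATOR)
POOLING_STRATEGIES = ("cls", "mean", "first_last_avg", "pooler", "max")

LN_EPS = 1e-12


@dataclass(frozen=True)
class EncoderConfig:
    vocab_size: int
    dim: int = 64
    heads: int = 4
    layers: int = 2
    max_len: int = 80
    pooler_dim: int | None = None
    ffn_dim: int | None = None
    seed: int = 0
    #: index of the "first" layer used by first-last-avg pooling:
    #: 1 = first encoder layer (default), 0 = embedding-layer output.
    first_layer_index: int = 1

    def __post_init__(self):
        if self.dim % self.heads != 0:
            raise ValueError("dim must be divisible by heads (dim = heads * d_k)")
        if self.max_len < 2:
            raise ValueError("max_len must leave room for [CLS] plus content")
        if self.layers < 1:
            raise ValueError("need at least one encoder layer")

    @property
    def d_k(self) -> int:
        return self.dim // self.heads

    @property
    def pooler_width(self) -> int:
        return self.pooler_dim or self.dim

    @property
    def ffn_width(self) -> int:
        return self.ffn_dim or 2 * self.dim


@dataclass
class TokenSequence:
    token_ids: np.ndarray  # (max_len,) int64
    attention_mask: np.ndarray  # (max_len,) int64, 1 on [CLS]+content


class WhitespaceTokenizer:
    """Whitespace tokenizer with a fitted vocabulary.

    Reserved ids: [PAD]=0, [UNK]=1, [CLS]=2, [FSEP]=3. With
    ``oov_buckets == 0`` every unknown token maps to the single [UNK] id.
    With ``oov_buckets > 0`` unknown tokens are feature-hashed into that
    many reserved tail ids instead: identical unseen tokens then share an
    id while distinct ones (mostly) do not, which lets a from-scratch
    encoder carry token-identity signal into open-set queries whose
    vocabulary never appeared in training. Pretrained encoders bring their
    own tokenization and ignore this class entirely.
    """

    def __init__(self, vocab: Sequence[str] | None = None, oov_buckets: int = 0):
        self.itos: list[str] = list(SPECIAL_TOKENS)
        if vocab:
            for tok in vocab:
                if tok not in SPECIAL_TOKENS:
                    self.itos.append(tok)
        self.stoi = {t: i for i, t in enumerate(self.itos)}
        self.oov_buckets = int(oov_buckets)

    @classmethod
    def fit(cls, texts: Sequence[str], oov_buckets: int = 0) -> "WhitespaceTokenizer":
        seen: dict[str, None] = {}
        for text in texts:
            for tok in text.split():
                seen.setdefault(tok, None)
        return cls(list(seen), oov_buckets=oov_buckets)

    def __len__(self) -> int:
        return len(self.itos) + self.oov_buckets

    def _oov_id(self, token: str) -> int:
        if self.oov_buckets == 0:
            return self.stoi[UNK]
        digest = hashlib.md5(token.encode("utf-8")).digest()
        bucket = int.from_bytes(digest[:8], "little") % self.oov_buckets
        return len(self.itos) + bucket

    def tokenize(self, text: str, max_len: int) -> TokenSequence:
        ids = [self.stoi[CLS]]
        for tok in text.split():
            ids.append(self.stoi.get(tok) if tok in self.stoi else self._oov_id(tok))
        ids = ids[:max_len]  # truncate, [CLS] kept
        mask = [1] * len(ids)
        pad = max_len - len(ids)
        ids += [self.stoi[PAD]] * pad
        mask += [0] * pad
        return TokenSequence(np.asarray(ids, dtype=np.int64),
                             np.asarray(mask, dtype=np.int64))

    def save(self, path: str | Path) -> None:
        lines = [f"#oov_buckets={self.oov_buckets}"] + self.itos
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "WhitespaceTokenizer":
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        buckets = 0
        if lines and lines[0].startswith("#oov_buckets="):
            buckets = int(lines[0].split("=", 1)[1])
            lines = lines[1:]
        tk = cls(oov_buckets=buckets)
        for tok in lines:
            if tok and tok not in tk.stoi:
                tk.itos.append(tok)
                tk.stoi[tok] = len(tk.itos) - 1
        return tk


# ---------------------------------------------------------------------------
# functional attention (also the unit-test surface)

def attention(Q: np.ndarray, K: np.ndarray, V: np.ndarray,
              mask: np.ndarray | None = None) -> np.ndarray:
    """Scaled dot-product attention on plain arrays.

    Masked (padding) key positions are excluded from the softmax; every
    output row is a convex combination of V rows.
    """
    Q, K, V = (np.asarray(a, dtype=np.float64) for a in (Q, K, V))
    if Q.shape[-1] != K.shape[-1] or K.shape[-2] != V.shape[-2]:
        raise ValueError("inconsistent Q/K/V shapes")
    d_k = Q.shape[-1]
    scores = Q @ np.swapaxes(K, -1, -2) / np.sqrt(d_k)
    if mask is not None:
        mask = np.asarray(mask, dtype=np.float64)
        if not np.any(mask > 0):
            raise ValueError("all key positions masked: nothing to attend to")
        scores = scores + (mask - 1.0) * 1e30
    scores -= scores.max(axis=-1, keepdims=True)
    e = np.exp(scores)
    if mask is not None:
        e = e * mask
    return (e / e.sum(axis=-1, keepdims=True)) @ V


# ---------------------------------------------------------------------------
# model

def _layer_norm(x: Tensor, g: Tensor, b: Tensor) -> Tensor:
    return layer_norm(x, g, b, eps=LN_EPS)


class Encoder:
    """Small BERT-style text encoder with named Tensor parameters."""

    def __init__(self, config: EncoderConfig, params: dict[str, Tensor] | None = None):
        self.config = config
        self.params = params if params is not None else self._init_params(config)

    @staticmethod
    def _init_params(cfg: EncoderConfig) -> dict[str, Tensor]:
        rng = np.random.default_rng(cfg.seed)

        def normal(*shape):
            return Tensor(rng.normal(0.0, 0.02, size=shape), requires_grad=True)

        def zeros(*shape):
            return Tensor(np.zeros(shape), requires_grad=True)

        def ones(*shape):
            return Tensor(np.ones(shape), requires_grad=True)

        p: dict[str, Tensor] = {
            "tok_emb": normal(cfg.vocab_size, cfg.dim),
            "pos_emb": normal(cfg.max_len, cfg.dim),
            # single-sentence inputs: one shared segment embedding
            "seg_emb": normal(1, cfg.dim),
            "ln_emb_g": ones(cfg.dim),
            "ln_emb_b": zeros(cfg.dim),
            "pooler_W": normal(cfg.dim, cfg.pooler_width),
            "pooler_b": zeros(cfg.pooler_width),
        }
        for layer in range(cfg.layers):
            pre = f"l{layer}_"
            p[pre + "Wq"] = normal(cfg.dim, cfg.dim)
            p[pre + "bq"] = zeros(cfg.dim)
            p[pre + "Wk"] = normal(cfg.dim, cfg.dim)
            p[pre + "bk"] = zeros(cfg.dim)
            p[pre + "Wv"] = normal(cfg.dim, cfg.dim)
            p[pre + "bv"] = zeros(cfg.dim)
            p[pre + "Wo"] = normal(cfg.dim, cfg.dim)
            p[pre + "bo"] = zeros(cfg.dim)
            p[pre + "ln1_g"] = ones(cfg.dim)
            p[pre + "ln1_b"] = zeros(cfg.dim)
            p[pre + "W1"] = normal(cfg.dim, cfg.ffn_width)
            p[pre + "b1"] = zeros(cfg.ffn_width)
            p[pre + "W2"] = normal(cfg.ffn_width, cfg.dim)
            p[pre + "b2"] = zeros(cfg.dim)
            p[pre + "ln2_g"] = ones(cfg.dim)
            p[pre + "ln2_b"] = zeros(cfg.dim)
        return p

    def parameters(self) -> dict[str, Tensor]:
        return self.params

    # -- forward ----------------------------------------------------------
    def _split_heads(self, x: Tensor, batch: int, seqlen: int) -> Tensor:
        cfg = self.config
        return x.reshape(batch, seqlen, cfg.heads, cfg.d_k).swapaxes(1, 2)

    def _block(self, layer: int, x: Tensor, mask: np.ndarray) -> Tensor:
        cfg, p = self.config, self.params
        pre = f"l{layer}_"
        B, T, _ = x.shape
        q = self._split_heads(x @ p[pre + "Wq"] + p[pre + "bq"], B, T)
        k = self._split_heads(x @ p[pre + "Wk"] + p[pre + "bk"], B, T)
        v = self._split_heads(x @ p[pre + "Wv"] + p[pre + "bv"], B, T)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(cfg.d_k))
        attn_mask = mask[:, None, None, :]  # broadcast over heads and queries
        weights = t_softmax(scores, axis=-1, mask=attn_mask)
        heads = (weights @ v).swapaxes(1, 2).reshape(B, T, cfg.dim)
        attn_out = heads @ p[pre + "Wo"] + p[pre + "bo"]
        x = _layer_norm(x + attn_out, p[pre + "ln1_g"], p[pre + "ln1_b"])
        ffn = ((x @ p[pre + "W1"] + p[pre + "b1"]).gelu()) @ p[pre + "W2"] + p[pre + "b2"]
        return _layer_norm(x + ffn, p[pre + "ln2_g"], p[pre + "ln2_b"])

    def forward(self, token_ids: np.ndarray, attention_mask: np.ndarray) -> list[Tensor]:
        """Return L+1 per-layer token matrices (index 0 = embedding output)."""
        cfg, p = self.config, self.params
        ids = np.atleast_2d(np.asarray(token_ids, dtype=np.int64))
        mask = np.atleast_2d(np.asarray(attention_mask, dtype=np.float64))
        if ids.max() >= cfg.vocab_size:
            raise ValueError("token id outside vocabulary")
        B, T = ids.shape
        if T > cfg.max_len:
            raise ValueError("sequence longer than max_len")
        x = p["tok_emb"][ids] + p["pos_emb"][np.arange(T)] + p["seg_emb"]
        x = _layer_norm(x, p["ln_emb_g"], p["ln_emb_b"])
        outputs = [x]
        for layer in range(cfg.layers):
            x = self._block(layer, x, mask)
            outputs.append(x)
        return outputs

    # -- pooling ----------------------------------------------------------
    def pool(self, outputs: list[Tensor], strategy: str,
             attention_mask: np.ndarray) -> Tensor:
        """Reduce per-token outputs to one sentence vector per sequence.

        cls: last-layer [CLS] row. mean: mask-weighted token average.
        first_last_avg: token average of (first layer + last layer)/2.
        pooler: Tanh(dense([CLS])). max: mask-aware elementwise maximum.
        """
        cfg = self.config
        mask = np.atleast_2d(np.asarray(attention_mask, dtype=np.float64))
        last = outputs[-1]
        if strategy == "cls":
            return last[:, 0, :]
        if strategy == "pooler":
            return (last[:, 0, :] @ self.params["pooler_W"]
                    + self.params["pooler_b"]).tanh()
        if strategy == "mean":
            m = Tensor(mask[:, :, None])
            return (last * m).sum(axis=1) / Tensor(mask.sum(axis=1, keepdims=True))
        if strategy == "first_last_avg":
            first = outputs[min(cfg.first_layer_index, len(outputs) - 1)]
            avg = (first + last) * 0.5
            m = Tensor(mask[:, :, None])
            return (avg * m).sum(axis=1) / Tensor(mask.sum(axis=1, keepdims=True))
        if strategy == "max":
            neg = Tensor((mask[:, :, None] - 1.0) * 1e30)
            return (last + neg).amax(axis=1)
        raise ValueError(f"unknown pooling strategy {strategy!r}")

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        buf = io.BytesIO()
        np.savez(buf, **{k: v.data for k, v in self.params.items()})
        with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
            zf.writestr("config.json", json.dumps(asdict(self.config), sort_keys=True))
            zf.writestr("params.npz", buf.getvalue())

    @classmethod
    def load(cls, path: str | Path) -> "Encoder":
        with zipfile.ZipFile(path) as zf:
            cfg = EncoderConfig(**json.loads(zf.read("config.json")))
            with zf.open("params.npz") as fh:
                npz = np.load(io.BytesIO(fh.read()))
                params = {k: Tensor(npz[k], requires_grad=True) for k in npz.files}
        return cls(cfg, params)

    def fingerprint(self) -> str:
        import hashlib

        h = hashlib.sha256()
        h.update(json.dumps(asdict(self.config), sort_keys=True).encode())
        for key in sorted(self.params):
            h.update(key.encode())
            h.update(np.ascontiguousarray(self.params[key].data).tobytes())
        return h.hexdigest()[:16]


class SentenceEncoder:
    """Tokenizer + encoder + pooling bundled behind the plug-in contract:
    a callable mapping a list of strings to a matrix of embeddings."""

    def __init__(self, encoder: Encoder, tokenizer: WhitespaceTokenizer,
                 pooling: str = "cls"):
        if pooling not in POOLING_STRATEGIES:
            raise ValueError(f"unknown pooling strategy {pooling!r}")
        self.encoder = encoder
        self.tokenizer = tokenizer
        self.pooling = pooling

    def _batch_arrays(self, texts: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        max_len = self.encoder.config.max_len
        seqs = [self.tokenizer.tokenize(t, max_len) for t in texts]
        ids = np.stack([s.token_ids for s in seqs])
        mask = np.stack([s.attention_mask for s in seqs])
        # trailing all-padding columns carry no information (padding
        # invariance is a tested property) — trim them for speed
        keep = max(int(mask.sum(axis=1).max()), 1)
        return ids[:, :keep], mask[:, :keep]

    def embed_tensor(self, texts: Sequence[str]) -> Tensor:
        ids, mask = self._batch_arrays(texts)
        outputs = self.encoder.forward(ids, mask)
        return self.encoder.pool(outputs, self.pooling, mask)

    def __call__(self, texts: Sequence[str]) -> np.ndarray:
        return self.embed_tensor(texts).data

    def fingerprint(self) -> str:
        return self.encoder.fingerprint() + f":{self.pooling}"

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.encoder.save(directory / "encoder.zip")
        self.tokenizer.save(directory / "vocab.txt")
        (directory / "pooling.json").write_text(
            json.dumps({"pooling": self.pooling}), encoding="utf-8")

    @classmethod
    def load(cls, directory: str | Path) -> "SentenceEncoder":
        directory = Path(directory)
        enc = Encoder.load(directory / "encoder.zip")
        tok = WhitespaceTokenizer.load(directory / "vocab.txt")
        pooling = json.loads((directory / "pooling.json").read_text())["pooling"]
        return cls(enc, tok, pooling)
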