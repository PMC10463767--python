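"""Contrastive training loop for the siamese sentence encoder.

Every mini-batch sends both sides of its text pairs through the shared
encoder (identical weights — the twin-tower arrangement), pools, and
applies the configured objective:

* ``cosent`` (default): CoSENT ranking loss over the batch's pair cosines;
  a batch with only one label class contributes zero loss and is logged.
* ``sbert_softmax``: classification over concat(u, v, |u - v|) with a
  trainable head; the head is train-time only — inference is always cosine.

Optimization is AdamW (decoupled weight decay). Training is fully
deterministic under a fixed seed: parameter init, per-epoch shuffling
(seed + epoch) and updates all run through seeded NumPy generators on one
thread.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import yaml

from .autodiff import Tensor
from .corpus import TextPair
from .encoder import Encoder, EncoderConfig, SentenceEncoder, WhitespaceTokenizer
from .losses import (DEFAULT_COSENT_SCALE, DEFAULT_SIMCSE_TAU, cosent_loss,
                     pairwise_cosine, sbert_objective)
from . import evaluation

logger = logging.getLogger(__name__)


@dataclass
class LossConfig:
    kind: str = "cosent"  # {cosent, sbert_softmax}; simcse_sup needs triad data
    cosent_scale: float = DEFAULT_COSENT_SCALE
    tau: float = DEFAULT_SIMCSE_TAU
    num_labels: int = 2

    def __post_init__(self):
        if self.cosent_scale <= 0 or self.tau <= 0:
            raise ValueError("loss scale and temperature must be positive")
        if self.num_labels < 2:
            raise ValueError("need at least two labels")


@dataclass
class TrainConfig:
    # 2e-5 suits fine-tuning a pretrained encoder; the small from-scratch
    # encoder needs a larger step
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 15
    weight_decay: float = 0.01
    seed: int = 0
    pooling: str = "cls"
    loss: LossConfig = field(default_factory=LossConfig)
    checkpoint_every: int = 0  # 0 = only best + final

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (a contrastive batch "
                             "needs room for both labels)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if isinstance(self.loss, dict):
            self.loss = LossConfig(**self.loss)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrainConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True),
                              encoding="utf-8")


class AdamW:
    """Adam with decoupled weight decay over a named parameter dict."""

    def __init__(self, params: dict[str, Tensor], lr: float,
                 weight_decay: float = 0.01, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}
        # bias vectors and norm gains conventionally skip weight decay
        self.no_decay = {k for k in params if params[k].data.ndim == 1}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for key, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
            update = (self.m[key] / bc1) / (np.sqrt(self.v[key] / bc2) + self.eps)
            if self.weight_decay and key not in self.no_decay:
                update = update + self.weight_decay * p.data
            p.data = p.data - self.lr * update


@dataclass
class EpochStats:
    epoch: int
    mean_loss: float
    pearson: float | None
    spearman: float | None


def write_history(history: Sequence[EpochStats], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["epoch", "mean_loss", "pearson", "spearman"])
        for h in history:
            writer.writerow([
                h.epoch, f"{h.mean_loss:.10g}",
                "" if h.pearson is None else f"{h.pearson:.10g}",
                "" if h.spearman is None else f"{h.spearman:.10g}",
            ])


def evaluate_epoch(embed: Callable[[Sequence[str]], np.ndarray],
                   held_out_pairs: Sequence[TextPair],
                   batch_size: int = 64) -> tuple[float | None, float | None]:
    """Pearson/Spearman between held-out pair cosines and their 0/1 labels.

    Undefined correlations (constant cosines or constant labels) come back
    as None, never as a silent zero.
    """
    if not held_out_pairs:
        raise ValueError("held-out pair list is empty")
    cosines = np.concatenate([
        _batch_cosines(embed, held_out_pairs[i:i + batch_size])
        for i in range(0, len(held_out_pairs), batch_size)
    ])
    labels = np.array([p.label for p in held_out_pairs], dtype=float)
    pearson = evaluation.pearson(cosines, labels)
    spearman = evaluation.spearman(cosines, labels)
    return pearson, spearman


def _batch_cosines(embed, pairs: Sequence[TextPair]) -> np.ndarray:
    a = embed([p.text_a for p in pairs])
    b = embed([p.text_b for p in pairs])
    return np.asarray(pairwise_cosine(a, b))


def train(
    pairs: Sequence[TextPair],
    encoder: Encoder,
    tokenizer: WhitespaceTokenizer,
    config: TrainConfig,
    held_out_pairs: Sequence[TextPair] | None = None,
    checkpoint_dir: str | Path | None = None,
) -> tuple[SentenceEncoder, list[EpochStats]]:
    """Train the encoder on labeled text pairs; return the trained
    sentence encoder (best epoch by held-out Spearman when available,
    else final) and the per-epoch history."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no training pairs")
    labels_seen = {p.label for p in pairs}
    if labels_seen != {0, 1}:
        raise ValueError("training pairs must contain both labels")

    sent = SentenceEncoder(encoder, tokenizer, config.pooling)
    params = dict(encoder.parameters())
    head: Tensor | None = None
    if config.loss.kind == "sbert_softmax":
        dim = (encoder.config.pooler_width if config.pooling == "pooler"
               else encoder.config.dim)
        rng = np.random.default_rng(config.seed + 1)
        head = Tensor(rng.normal(0.0, 0.02, size=(3 * dim, config.loss.num_labels)),
                      requires_grad=True)
        params["sbert_head"] = head
    elif config.loss.kind != "cosent":
        raise ValueError(
            f"unsupported training loss {config.loss.kind!r}: pair-format "
            "data supports 'cosent' and 'sbert_softmax'")

    opt = AdamW(params, lr=config.learning_rate, weight_decay=config.weight_decay)
    history: list[EpochStats] = []
    # model selection: held-out Spearman, ties broken by lower training
    # loss (binary pair labels make Spearman saturate early, so a pure
    # first-best rule would keep an undertrained checkpoint)
    best_score: tuple[float, float] = (-np.inf, -np.inf)
    best_params: dict[str, np.ndarray] | None = None
    ckpt_dir = Path(checkpoint_dir) if checkpoint_dir else None
    if ckpt_dir:
        ckpt_dir.mkdir(parents=True, exist_ok=True)

    n = len(pairs)
    for epoch in range(1, config.epochs + 1):
        rng = np.random.default_rng(config.seed + epoch)
        order = rng.permutation(n)
        losses: list[float] = []
        for start in range(0, n, config.batch_size):
            batch = [pairs[i] for i in order[start:start + config.batch_size]]
            loss = _batch_loss(sent, batch, config, head)
            if loss is None:
                logger.info("epoch %d: single-class batch skipped (0 loss)", epoch)
                losses.append(0.0)
                continue
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        pearson = spearman = None
        if held_out_pairs:
            pearson, spearman = evaluate_epoch(sent, held_out_pairs)
        stats = EpochStats(epoch, float(np.mean(losses)), pearson, spearman)
        history.append(stats)
        logger.info("epoch %d mean_loss=%.5f pearson=%s spearman=%s",
                    epoch, stats.mean_loss, pearson, spearman)
        primary = spearman if spearman is not None else -np.inf
        score = (primary, -stats.mean_loss)
        if score > best_score:
            best_score = score
            best_params = {k: v.data.copy() for k, v in encoder.parameters().items()}
        if ckpt_dir and config.checkpoint_every and epoch % config.checkpoint_every == 0:
            encoder.save(ckpt_dir / f"epoch{epoch:03d}.zip")

    if ckpt_dir:
        encoder.save(ckpt_dir / "final.zip")
    if best_params is not None:
        for k, v in encoder.parameters().items():
            v.data = best_params[k]
    if ckpt_dir:
        encoder.save(ckpt_dir / "best.zip")
        sent.save(ckpt_dir / "best_sentence_encoder")
    return sent, history


def _batch_loss(sent: SentenceEncoder, batch: Sequence[TextPair],
                config: TrainConfig, head: Tensor | None) -> Tensor | None:
    labels = np.array([p.label for p in batch])
    if config.loss.kind == "cosent" and len(set(labels.tolist())) < 2:
        return None
    texts = [p.text_a for p in batch] + [p.text_b for p in batch]
    emb = sent.embed_tensor(texts)
    k = len(batch)
    a, b = emb[np.arange(k)], emb[np.arange(k, 2 * k)]
    if config.loss.kind == "cosent":
        cosines = pairwise_cosine(a, b)
        return cosent_loss(cosines, labels, config.loss.cosent_scale)
    _, ce = sbert_objective(a, b, head, labels)
    return ce
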