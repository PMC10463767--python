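"""End-to-end study runner: corpus generation through evaluation.

Binds the whole pipeline at the scaled-down problem sizes this package
trains at (see docs/methods.md for the sizes and why): generate a
synthetic PEMR corpus, split it 8:1:1 into experimental / query /
reference sets, split the experimental set 7:3 into training and
held-out pair sources, train the bi-encoder contrastively, then run the
closed-set, open-set and field-ablation recommendation protocols.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

from .corpus import FIELD_GROUPS, SplitSpec, build_pairs, split_dataset
from .encoder import Encoder, EncoderConfig, SentenceEncoder, WhitespaceTokenizer
from .evaluation import EvalReport, run_protocol
from .synthetic import GeneratorConfig, generate_corpus, generate_open_set
from .training import EpochStats, LossConfig, TrainConfig, evaluate_epoch, train


@dataclass
class StudyConfig:
    seed: int = 0
    generator: GeneratorConfig | None = None   # defaults to GeneratorConfig(seed=seed)
    loss_kind: str = "cosent"
    pooling: str = "cls"
    epochs: int = 15
    dim: int = 64
    layers: int = 2
    heads: int = 4
    max_len: int = 80
    learning_rate: float = 1e-3
    # desk-scale training budget: cap positive pairs before 1:1 balancing
    max_positives: int | None = 150
    held_out_max_positives: int | None = 64
    oov_buckets: int = 64
    open_set_classes: int = 4
    open_set_per_class: int = 40
    ns: tuple[int, ...] = (1, 3, 5)


@dataclass
class StudyResult:
    config: StudyConfig
    history: list[EpochStats]
    pearson: float | None
    spearman: float | None
    closed_report: EvalReport
    open_report: EvalReport | None
    n_train_pairs: int = 0
    n_held_pairs: int = 0
    ablation_reports: dict[tuple[str, ...], EvalReport] = field(default_factory=dict)
    sentence_encoder: SentenceEncoder | None = None


def run_study(
    cfg: StudyConfig,
    with_open_set: bool = True,
    ablation_groups: Sequence[Sequence[str]] = (),
    keep_encoder: bool = False,
) -> StudyResult:
    gen_cfg = cfg.generator or GeneratorConfig(seed=cfg.seed)
    records, truth = generate_corpus(gen_cfg)
    experimental, queries, reference = split_dataset(
        records, SplitSpec((0.8, 0.1, 0.1), seed=cfg.seed))
    train_recs, held_recs = split_dataset(
        experimental, SplitSpec((0.7, 0.3), seed=cfg.seed + 1))

    train_pairs = build_pairs(train_recs, seed=cfg.seed,
                              max_positives=cfg.max_positives)
    held_pairs = build_pairs(held_recs, seed=cfg.seed + 1,
                             max_positives=cfg.held_out_max_positives)

    texts = [p.text_a for p in train_pairs] + [p.text_b for p in train_pairs]
    tokenizer = WhitespaceTokenizer.fit(texts, oov_buckets=cfg.oov_buckets)
    encoder = Encoder(EncoderConfig(
        vocab_size=len(tokenizer), dim=cfg.dim, heads=cfg.heads,
        layers=cfg.layers, max_len=cfg.max_len, seed=cfg.seed))
    train_cfg = TrainConfig(
        seed=cfg.seed, epochs=cfg.epochs, pooling=cfg.pooling,
        learning_rate=cfg.learning_rate,
        loss=LossConfig(kind=cfg.loss_kind))
    sent, history = train(train_pairs, encoder, tokenizer, train_cfg,
                          held_out_pairs=held_pairs)
    pearson, spearman = evaluate_epoch(sent, held_pairs)

    train_rx = {r.prescription for r in train_recs}
    closed = run_protocol(sent, queries, reference, ns=cfg.ns,
                          train_prescriptions=train_rx)

    open_report = None
    if with_open_set:
        open_gen = replace(gen_cfg, n_classes=cfg.open_set_classes,
                           records_per_class=cfg.open_set_per_class)
        open_records, _ = generate_open_set(open_gen, truth)
        open_q, open_r = split_dataset(
            open_records, SplitSpec((0.5, 0.5), seed=cfg.seed + 2))
        open_report = run_protocol(sent, open_q, open_r, ns=cfg.ns,
                                   train_prescriptions=train_rx)

    ablations: dict[tuple[str, ...], EvalReport] = {}
    for groups in ablation_groups:
        key = tuple(g for g in FIELD_GROUPS if g in set(groups))
        ablations[key] = run_protocol(sent, queries, reference, groups=key,
                                      ns=cfg.ns, train_prescriptions=train_rx)

    return StudyResult(
        config=cfg, history=history, pearson=pearson, spearman=spearman,
        n_train_pairs=len(train_pairs), n_held_pairs=len(held_pairs),
        closed_report=closed, open_report=open_report,
        ablation_reports=ablations,
        sentence_encoder=sent if keep_encoder else None,
    )
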