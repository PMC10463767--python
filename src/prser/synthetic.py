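"""Seeded generator of PEMR-like corpora with known latent class structure.

Each latent disease class owns a core vocabulary per signal-carrying field
group and maps to one prescription (bijective by default). Record text in
signal groups is drawn from the class core vocabulary with a controllable
probability of replacement by tokens from a shared cross-class pool;
non-signal groups draw entirely from the shared pool. This gives every
downstream module a corpus whose separability is known by construction:
with disjoint cores and low noise a bag-of-tokens nearest-neighbour
classifier must recover the classes, before any learned encoder is tested.

A many-diseases-one-prescription mode exists to exercise the pair-labeling
rule: pairs are labeled by prescription, not by latent disease.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

from .corpus import FIELD_GROUPS, GROUP_FIELDS, PlantRecord


@dataclass(frozen=True)
class GeneratorConfig:
    n_classes: int = 8
    records_per_class: int = 60
    vocab_core: int = 20      # core tokens per class per signal group
    vocab_shared: int = 50    # tokens shared across all classes
    tokens_per_field: int = 6
    noise_rate: float = 0.1   # P(core token replaced by a shared token)
    signal_groups: tuple[str, ...] = FIELD_GROUPS
    #: latent classes per prescription; >1 makes several diseases share one
    #: prescription (pair labels follow the prescription, not the disease)
    classes_per_prescription: int = 1
    class_prefix: str = "disease"
    prescription_prefix: str = "rx"
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least two latent classes")
        if not (0.0 <= self.noise_rate < 1.0):
            raise ValueError("noise_rate must lie in [0, 1)")
        if not self.signal_groups:
            raise ValueError("at least one field group must carry signal")
        unknown = set(self.signal_groups) - set(FIELD_GROUPS)
        if unknown:
            raise ValueError(f"unknown signal groups: {sorted(unknown)}")
        if self.classes_per_prescription < 1:
            raise ValueError("classes_per_prescription must be >= 1")


def _shared_pool(cfg: GeneratorConfig) -> list[str]:
    return [f"shared_t{i}" for i in range(max(cfg.vocab_shared, 1))]


def _core_pool(cfg: GeneratorConfig, cls: str, group: str) -> list[str]:
    return [f"{cls}_{group[:3]}_t{i}" for i in range(cfg.vocab_core)]


def class_names(cfg: GeneratorConfig) -> list[str]:
    return [f"{cfg.class_prefix}{i:02d}" for i in range(cfg.n_classes)]


def prescription_for(cfg: GeneratorConfig, class_index: int) -> str:
    return f"{cfg.prescription_prefix}{class_index // cfg.classes_per_prescription:02d}"


def _field_text(rng: np.random.Generator, cfg: GeneratorConfig,
                core: list[str] | None, shared: list[str]) -> str:
    toks = []
    for _ in range(cfg.tokens_per_field):
        if core is not None and rng.random() >= cfg.noise_rate:
            toks.append(core[rng.integers(len(core))])
        else:
            toks.append(shared[rng.integers(len(shared))])
    return " ".join(toks)


def generate_corpus(
    cfg: GeneratorConfig, id_prefix: str = "syn"
) -> tuple[list[PlantRecord], dict[str, str]]:
    """Generate a corpus and its record_id -> latent-class truth map."""
    rng = np.random.default_rng(cfg.seed)
    shared = _shared_pool(cfg)
    classes = class_names(cfg)
    cores = {
        (cls, g): _core_pool(cfg, cls, g)
        for cls in classes for g in cfg.signal_groups
    }
    records: list[PlantRecord] = []
    truth: dict[str, str] = {}
    counter = 0
    for ci, cls in enumerate(classes):
        rx = prescription_for(cfg, ci)
        for _ in range(cfg.records_per_class):
            rid = f"{id_prefix}-{counter:05d}"
            counter += 1
            groups: dict[str, dict[str, str]] = {}
            for gname in FIELD_GROUPS:
                core = cores.get((cls, gname))
                groups[gname] = {
                    fname: _field_text(rng, cfg, core, shared)
                    for fname in GROUP_FIELDS[gname]
                }
            records.append(PlantRecord(record_id=rid, prescription=rx, **groups))
            truth[rid] = cls
    return records, truth


def generate_open_set(
    cfg: GeneratorConfig, base_truth: Mapping[str, str], id_prefix: str = "open"
) -> tuple[list[PlantRecord], dict[str, str]]:
    """Corpus of classes/prescriptions disjoint from a base corpus.

    The shared token pool is reused, so surface style transfers while the
    labels do not — the open-set retrieval setting.
    """
    base_classes = set(base_truth.values())
    open_cfg = replace(
        cfg,
        class_prefix=cfg.class_prefix + "_open",
        prescription_prefix=cfg.prescription_prefix + "_open",
        seed=cfg.seed + 104729,  # distinct stream, still derived from cfg.seed
    )
    if set(class_names(open_cfg)) & base_classes:
        raise ValueError("open-set class names collide with base corpus")
    return generate_corpus(open_cfg, id_prefix=id_prefix)


# ---------------------------------------------------------------------------
# independent recoverability oracle (bag of tokens, no learned encoder)

def bag_of_tokens_nn_accuracy(
    train_records: Iterable[PlantRecord], train_truth: Mapping[str, str],
    test_records: Iterable[PlantRecord], test_truth: Mapping[str, str],
) -> float:
    """1-NN accuracy on token-overlap (Jaccard) — a generator sanity oracle."""

    def toks(rec: PlantRecord) -> frozenset[str]:
        out: set[str] = set()
        for g in FIELD_GROUPS:
            for text in rec.group(g).values():
                out.update(text.split())
        return frozenset(out)

    train = [(toks(r), train_truth[r.record_id]) for r in train_records]
    if not train:
        raise ValueError("empty training reference")
    hits = total = 0
    for rec in test_records:
        q = toks(rec)
        best, best_cls = -1.0, None
        for t, cls in train:
            sim = len(q & t) / len(q | t) if (q or t) else 0.0
            if sim > best:
                best, best_cls = sim, cls
        hits += int(best_cls == test_truth[rec.record_id])
        total += 1
    return hits / total
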