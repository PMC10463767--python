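"""Evaluation metrics and protocols.

Pearson / Spearman between pair cosines and binary same-prescription
labels (against a 0/1 label the Pearson formula is the point-biserial
coefficient — same value), Top-N recommendation accuracy
(hits / number of queries, counting the first N *distinct* prescriptions),
and the closed-set / open-set / field-ablation protocols.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats

from .corpus import FIELD_GROUPS, PlantRecord, serialize_record
from .retrieval import Recommendation, ReferenceIndex, build_index, recommend


def pearson(x, y) -> float | None:
    """Sample Pearson correlation; None (with a warning) when undefined."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-d sequences")
    if len(x) < 2:
        raise ValueError("need at least two observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("correlation undefined: constant input", stacklevel=2)
        return None
    return float(stats.pearsonr(x, y).statistic)


def spearman(x, y) -> float | None:
    """Spearman rank correlation (average ranks on ties); None if undefined."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-d sequences")
    if len(x) < 2:
        raise ValueError("need at least two observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("correlation undefined: constant input", stacklevel=2)
        return None
    return float(stats.spearmanr(x, y).statistic)


def topn_accuracy(recommendations: Sequence[Recommendation],
                  truths: Sequence[str], n: int) -> float:
    """Fraction of queries whose true prescription is in the first n
    distinct recommended prescriptions."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(recommendations) != len(truths):
        raise ValueError("recommendations and truths must align")
    if not recommendations:
        raise ValueError("empty query set")
    hits = sum(
        truth in [item.prescription for item in rec.ranked[:n]]
        for rec, truth in zip(recommendations, truths)
    )
    return hits / len(recommendations)


@dataclass
class EvalReport:
    protocol: str                      # closed_set | open_set
    input_groups: tuple[str, ...]
    n_queries: int
    topn_accuracy: dict[int, float]
    pearson: float | None = None
    spearman: float | None = None
    undefined_reason: str | None = None
    missing_truth_queries: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = asdict(self)
        payload["topn_accuracy"] = {str(k): v for k, v in
                                    sorted(self.topn_accuracy.items())}
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text


def run_protocol(
    embed: Callable[[Sequence[str]], np.ndarray],
    query_records: Sequence[PlantRecord],
    reference_records: Sequence[PlantRecord],
    groups: Sequence[str] = FIELD_GROUPS,
    ns: Sequence[int] = (1, 3, 5),
    train_prescriptions: set[str] | None = None,
    fingerprint: str = "",
    per_query_csv: str | Path | None = None,
) -> EvalReport:
    """Top-N recommendation test of queries against a reference set.

    Both sides are serialized with the same ``groups`` subset (the
    field-ablation protocol varies that subset). A query whose true
    prescription is absent from the reference is an automatic miss — the
    open-set protocol depends on counting these honestly. The protocol
    label is ``open_set`` iff the query prescriptions are disjoint from
    ``train_prescriptions`` (when supplied).
    """
    if not query_records or not reference_records:
        raise ValueError("query and reference sets must be non-empty")
    index = build_index(reference_records, embed, groups=groups,
                        fingerprint=fingerprint)
    max_n = max(ns)
    ref_rx = set(index.prescriptions)
    recs: list[Recommendation] = []
    truths: list[str] = []
    missing: list[str] = []
    for q in query_records:
        text = serialize_record(q, groups)
        recs.append(recommend(text, index, embed, n=max_n,
                              query_id=q.record_id, fingerprint=fingerprint))
        truths.append(q.prescription)
        if q.prescription not in ref_rx:
            missing.append(q.record_id)
    acc = {int(n): topn_accuracy(recs, truths, n) for n in ns}
    protocol = "closed_set"
    if train_prescriptions is not None:
        query_rx = {q.prescription for q in query_records}
        protocol = "open_set" if query_rx.isdisjoint(train_prescriptions) else "closed_set"
    if per_query_csv is not None:
        _write_rank_audit(recs, truths, per_query_csv)
    return EvalReport(
        protocol=protocol,
        input_groups=tuple(g for g in FIELD_GROUPS if g in set(groups)),
        n_queries=len(recs),
        topn_accuracy=acc,
        missing_truth_queries=missing,
    )


def _write_rank_audit(recs: Sequence[Recommendation], truths: Sequence[str],
                      path: str | Path) -> None:
    import csv

    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["query_id", "truth", "rank_of_truth", "top1", "top1_score"])
        for rec, truth in zip(recs, truths):
            rank = ""
            for i, item in enumerate(rec.ranked, start=1):
                if item.prescription == truth:
                    rank = i
                    break
            top = rec.ranked[0]
            writer.writerow([rec.query_id, truth, rank,
                             top.prescription, f"{top.score:.8f}"])
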