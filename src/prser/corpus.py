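"""Plant electronic medical record (PEMR) data model and dataset construction.

A PEMR groups its free-text fields into three blocks mirroring the disease
triangle (environment, host plant, symptoms) plus a prescription label.
This module normalizes raw records, serializes them to single strings for
the encoder, splits corpora with stratified sampling, and builds the
labeled text pairs that drive contrastive training: a pair is positive
iff the two records share a (normalized) prescription.
"""

from __future__ import annotations

import csv
import json
import math
import re
import unicodedata
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

FIELD_GROUPS = ("environment", "plant", "symptom")
GROUP_FIELDS = {
    "environment": ("onset_date", "location", "field_distribution"),
    "plant": ("species", "growth_stage", "affected_part"),
    "symptom": ("severity", "main_symptoms", "detail"),
}
#: reserved separator token between serialized fields; registered in the
#: tokenizer vocabulary so ablation subsets stay unambiguous.
FIELD_SEPARATOR = "[FSEP]"

_WS = re.compile(r"\s+")


class RecordInvalidError(ValueError):
    """A raw record failed validation; carries the offending record_id."""

    def __init__(self, record_id: str, reason: str):
        super().__init__(f"record {record_id!r}: {reason}")
        self.record_id = record_id
        self.reason = reason


@dataclass
class PlantRecord:
    """One plant EMR: three field groups plus the prescription label."""

    record_id: str
    environment: dict[str, str] = field(default_factory=dict)
    plant: dict[str, str] = field(default_factory=dict)
    symptom: dict[str, str] = field(default_factory=dict)
    prescription: str = ""

    def group(self, name: str) -> dict[str, str]:
        if name not in FIELD_GROUPS:
            raise KeyError(f"unknown field group {name!r}")
        return getattr(self, name)

    def to_json(self) -> str:
        return json.dumps(asdict(self), ensure_ascii=False, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "PlantRecord":
        return cls(
            record_id=str(d["record_id"]),
            environment=dict(d.get("environment", {})),
            plant=dict(d.get("plant", {})),
            symptom=dict(d.get("symptom", {})),
            prescription=str(d.get("prescription", "")),
        )


@dataclass(frozen=True)
class TextPair:
    """Two serialized record texts with a same-prescription label."""

    text_a: str
    text_b: str
    label: int

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError("pair label must be 0 or 1")


@dataclass(frozen=True)
class SplitSpec:
    ratios: tuple[float, ...]
    stratify_key: str = "prescription"
    seed: int = 0

    def __post_init__(self):
        if any(r <= 0 for r in self.ratios):
            raise ValueError("all split ratios must be positive")
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")


# ---------------------------------------------------------------------------
# normalization

def _clean_text(text: str) -> str:
    """NFKC (full/half-width) normalization, trim, collapse whitespace."""
    return _WS.sub(" ", unicodedata.normalize("NFKC", str(text))).strip()


def _alias_key(name: str) -> str:
    return _clean_text(name).casefold()


def normalize_record(raw: dict, alias_map: dict[str, str] | None = None) -> PlantRecord:
    """Clean one raw record and canonicalize its prescription name.

    Raises :class:`RecordInvalidError` if the prescription is missing/empty
    after alias resolution, or if the symptom group is entirely empty.
    """
    record_id = str(raw.get("record_id", ""))
    if "prescription" not in raw:
        raise RecordInvalidError(record_id, "missing prescription field")
    groups = {}
    for gname in FIELD_GROUPS:
        src = raw.get(gname, {}) or {}
        groups[gname] = {
            fname: _clean_text(src.get(fname, "")) for fname in GROUP_FIELDS[gname]
        }
    rx = _clean_text(raw["prescription"])
    if alias_map:
        rx = alias_map.get(_alias_key(rx), rx)
    if not rx:
        raise RecordInvalidError(record_id, "empty prescription after normalization")
    rec = PlantRecord(record_id=record_id, prescription=rx, **groups)
    if not any(rec.symptom.values()):
        raise RecordInvalidError(record_id, "symptom group entirely empty")
    return rec


def dedupe_key(record: PlantRecord) -> str:
    """Conservative duplicate key: full serialized text + prescription."""
    return serialize_record(record, FIELD_GROUPS) + "␞" + record.prescription


def normalize_corpus(
    raws: Iterable[dict], alias_map: dict[str, str] | None = None
) -> tuple[list[PlantRecord], list[RecordInvalidError], list[str]]:
    """Normalize, validate, and de-duplicate a stream of raw records.

    Returns (kept records, rejections, duplicate record_ids). Duplicates
    (identical full text + prescription to an earlier record) are excluded.
    """
    kept: list[PlantRecord] = []
    rejected: list[RecordInvalidError] = []
    duplicates: list[str] = []
    seen_keys: set[str] = set()
    seen_ids: set[str] = set()
    for raw in raws:
        try:
            rec = normalize_record(raw, alias_map)
        except RecordInvalidError as err:
            rejected.append(err)
            continue
        if rec.record_id in seen_ids:
            rejected.append(RecordInvalidError(rec.record_id, "duplicate record_id"))
            continue
        key = dedupe_key(rec)
        if key in seen_keys:
            duplicates.append(rec.record_id)
            continue
        seen_keys.add(key)
        seen_ids.add(rec.record_id)
        kept.append(rec)
    return kept, rejected, duplicates


# ---------------------------------------------------------------------------
# serialization

def serialize_record(
    record: PlantRecord,
    groups: Sequence[str] = FIELD_GROUPS,
    separator: str = FIELD_SEPARATOR,
) -> str:
    """Concatenate the selected field groups into one deterministic string.

    Groups always appear in the fixed order environment -> plant -> symptom;
    fields within a group follow the declared field order and are joined by
    the separator token. Empty fields are kept as empty slots between
    separators so field positions stay aligned across records.
    """
    chosen = set(groups)
    if not chosen:
        raise ValueError("groups must be a non-empty subset of field groups")
    unknown = chosen - set(FIELD_GROUPS)
    if unknown:
        raise ValueError(f"unknown field groups: {sorted(unknown)}")
    parts: list[str] = []
    for gname in FIELD_GROUPS:
        if gname not in chosen:
            continue
        grp = record.group(gname)
        parts.extend(grp.get(fname, "") for fname in GROUP_FIELDS[gname])
    return f" {separator} ".join(parts)


# ---------------------------------------------------------------------------
# splitting

def _largest_remainder(n: int, ratios: Sequence[float]) -> list[int]:
    exact = [n * r for r in ratios]
    sizes = [math.floor(e) for e in exact]
    short = n - sum(sizes)
    # distribute leftovers by descending fractional part; ties to the
    # larger ratio, then lower index, for determinism
    order = sorted(
        range(len(ratios)),
        key=lambda i: (-(exact[i] - sizes[i]), -ratios[i], i),
    )
    for i in order[:short]:
        sizes[i] += 1
    return sizes


def split_dataset(records: Sequence[PlantRecord], spec: SplitSpec) -> list[list[PlantRecord]]:
    """Stratified split into len(spec.ratios) disjoint parts.

    Within every stratum (grouped by ``spec.stratify_key``) counts follow
    largest-remainder rounding of the ratios. A stratum smaller than the
    number of parts goes entirely to the largest-ratio part, with a warning
    — this keeps rare prescriptions available for training.
    """
    k = len(spec.ratios)
    strata: dict[str, list[PlantRecord]] = {}
    for rec in records:
        if spec.stratify_key == "prescription":
            key = rec.prescription
        else:
            key = None
            for gname in FIELD_GROUPS:
                if spec.stratify_key in GROUP_FIELDS[gname]:
                    key = rec.group(gname).get(spec.stratify_key)
                    break
            if key is None:
                raise KeyError(f"unknown stratify key {spec.stratify_key!r}")
        if not key:
            raise ValueError(f"record {rec.record_id!r} has empty stratify value")
        strata.setdefault(key, []).append(rec)

    rng = np.random.default_rng(spec.seed)
    parts: list[list[PlantRecord]] = [[] for _ in range(k)]
    biggest = int(np.argmax(spec.ratios))
    for key in sorted(strata):
        members = strata[key]
        perm = rng.permutation(len(members))
        shuffled = [members[i] for i in perm]
        if len(members) < k:
            warnings.warn(
                f"stratum {key!r} has {len(members)} record(s) < {k} parts; "
                f"assigning all to part {biggest}",
                stacklevel=2,
            )
            parts[biggest].extend(shuffled)
            continue
        sizes = _largest_remainder(len(members), spec.ratios)
        start = 0
        for i, size in enumerate(sizes):
            parts[i].extend(shuffled[start:start + size])
            start += size
    return parts


# ---------------------------------------------------------------------------
# pair construction

def build_pairs(
    records: Sequence[PlantRecord],
    groups: Sequence[str] = FIELD_GROUPS,
    balance_ratio: float = 1.0,
    seed: int = 0,
    max_positives: int | None = None,
) -> list[TextPair]:
    """All unordered record pairs, labeled by same-prescription, balanced.

    Negatives are down-sampled (seeded, without replacement) to
    ``round(balance_ratio * n_pos)`` when enough exist. ``max_positives``
    optionally caps positives first (seeded down-sampling) so very dense
    corpora stay trainable at desk scale; negatives balance against the
    capped count.
    """
    if len(records) < 2:
        return []
    if balance_ratio <= 0:
        raise ValueError("balance_ratio must be positive")
    texts = [serialize_record(r, groups) for r in records]
    pos_idx: list[tuple[int, int]] = []
    neg_idx: list[tuple[int, int]] = []
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            if records[i].prescription == records[j].prescription:
                pos_idx.append((i, j))
            else:
                neg_idx.append((i, j))
    rng = np.random.default_rng(seed)
    if max_positives is not None and len(pos_idx) > max_positives:
        sel = rng.choice(len(pos_idx), size=max_positives, replace=False)
        pos_idx = [pos_idx[i] for i in np.sort(sel)]
    if not pos_idx:
        warnings.warn("no positive pairs; returning negatives unbalanced", stacklevel=2)
        chosen_neg = neg_idx
    else:
        want = round(balance_ratio * len(pos_idx))
        if len(neg_idx) > want:
            sel = rng.choice(len(neg_idx), size=want, replace=False)
            chosen_neg = [neg_idx[i] for i in np.sort(sel)]
        else:
            chosen_neg = neg_idx
    pairs = [TextPair(texts[i], texts[j], 1) for i, j in pos_idx]
    pairs += [TextPair(texts[i], texts[j], 0) for i, j in chosen_neg]
    perm = rng.permutation(len(pairs))
    return [pairs[i] for i in perm]


# ---------------------------------------------------------------------------
# file formats

def write_records(records: Iterable[PlantRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(rec.to_json() + "\n")


def read_records(path: str | Path) -> list[PlantRecord]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(PlantRecord.from_dict(json.loads(line)))
    return out


def write_pairs(pairs: Iterable[TextPair], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["text_a", "text_b", "label"])
        for p in pairs:
            writer.writerow([p.text_a, p.text_b, p.label])


def read_pairs(path: str | Path) -> list[TextPair]:
    out = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header[:3] != ["text_a", "text_b", "label"]:
            raise ValueError(f"unexpected pair file header: {header}")
        for row in reader:
            out.append(TextPair(row[0], row[1], int(row[2])))
    return out


def read_alias_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV ``variant<TAB>canonical`` -> casefolded lookup table."""
    table: dict[str, str] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) != 2:
                raise ValueError(f"alias map rows need 2 columns, got {row}")
            table[_alias_key(row[0])] = _clean_text(row[1])
    return table
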