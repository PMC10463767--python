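"""Reference-set embedding and cosine Top-N prescription recommendation.

The reference index stores one L2-normalized embedding per reference
record, so cosine similarity is a plain dot product and retrieval is exact
exhaustive search (reference sets here are at most tens of thousands of
rows). A recommendation ranks *distinct* prescriptions: reference rows are
sorted by similarity and each prescription keeps its best-scoring row.
Score ties break toward the earlier reference row for determinism.
"""

from __future__ import annotations

import io
import json
import warnings
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .corpus import FIELD_GROUPS, PlantRecord, serialize_record


@dataclass
class ReferenceIndex:
    embeddings: np.ndarray          # (n, d) float, unit rows
    prescriptions: list[str]
    record_ids: list[str]
    fingerprint: str = ""
    groups: tuple[str, ...] = FIELD_GROUPS

    def __post_init__(self):
        n = self.embeddings.shape[0]
        if not (n == len(self.prescriptions) == len(self.record_ids)):
            raise ValueError("embeddings, prescriptions, record_ids must align")
        norms = np.linalg.norm(self.embeddings, axis=1)
        if n and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("index rows must be unit-normalized")

    def __len__(self) -> int:
        return self.embeddings.shape[0]


@dataclass(frozen=True)
class RankedItem:
    prescription: str
    score: float
    supporting_record_id: str


@dataclass
class Recommendation:
    query_id: str
    ranked: list[RankedItem]
    truncated: bool = False  # n exceeded the number of distinct prescriptions

    def to_json(self) -> str:
        return json.dumps({
            "query_id": self.query_id,
            "ranked": [
                {"prescription": r.prescription, "score": r.score,
                 "supporting_record_id": r.supporting_record_id}
                for r in self.ranked
            ],
        }, ensure_ascii=False, indent=2)


def _normalize_rows(mat: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(mat, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("cannot normalize a zero embedding row")
    return mat / norms


def build_index(
    records: Sequence[PlantRecord],
    embed: Callable[[Sequence[str]], np.ndarray],
    groups: Sequence[str] = FIELD_GROUPS,
    fingerprint: str = "",
    batch_size: int = 64,
) -> ReferenceIndex:
    """Serialize, encode and L2-normalize every reference record."""
    if not records:
        raise ValueError("reference record list is empty")
    texts = [serialize_record(r, groups) for r in records]
    chunks = [np.asarray(embed(texts[i:i + batch_size]))
              for i in range(0, len(texts), batch_size)]
    mat = _normalize_rows(np.vstack(chunks).astype(np.float64))
    return ReferenceIndex(
        embeddings=mat,
        prescriptions=[r.prescription for r in records],
        record_ids=[r.record_id for r in records],
        fingerprint=fingerprint,
        groups=tuple(g for g in FIELD_GROUPS if g in set(groups)),
    )


def recommend(
    query_text: str,
    index: ReferenceIndex,
    embed: Callable[[Sequence[str]], np.ndarray],
    n: int = 5,
    query_id: str = "query",
    fingerprint: str | None = None,
) -> Recommendation:
    """Rank distinct prescriptions by cosine against the reference index."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(index) == 0:
        raise ValueError("empty reference index")
    if fingerprint is not None and index.fingerprint and fingerprint != index.fingerprint:
        raise ValueError("encoder fingerprint does not match the index")
    q = np.asarray(embed([query_text]), dtype=np.float64).reshape(-1)
    qnorm = np.linalg.norm(q)
    if qnorm == 0:
        raise ValueError("query embedded to the zero vector")
    scores = index.embeddings @ (q / qnorm)
    order = np.argsort(-scores, kind="stable")  # ties -> earlier row
    ranked: list[RankedItem] = []
    seen: set[str] = set()
    for row in order:
        rx = index.prescriptions[row]
        if rx in seen:
            continue
        seen.add(rx)
        ranked.append(RankedItem(rx, float(scores[row]), index.record_ids[row]))
        if len(ranked) == n:
            break
    truncated = len(ranked) < n
    if truncated:
        warnings.warn(
            f"requested top-{n} but only {len(ranked)} distinct prescriptions exist",
            stacklevel=2)
    return Recommendation(query_id=query_id, ranked=ranked, truncated=truncated)


# ---------------------------------------------------------------------------
# index archive: TSV metadata + raw little-endian float32 matrix + JSON shape

def save_index(index: ReferenceIndex, path: str | Path) -> None:
    meta_lines = ["record_id\tprescription"]
    meta_lines += [f"{rid}\t{rx}" for rid, rx in
                   zip(index.record_ids, index.prescriptions)]
    mat32 = np.ascontiguousarray(index.embeddings, dtype="<f4")
    header = {
        "shape": list(index.embeddings.shape),
        "dtype": "<f4",
        "order": "C",
        "fingerprint": index.fingerprint,
        "groups": list(index.groups),
    }
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("meta.tsv", "\n".join(meta_lines) + "\n")
        zf.writestr("shape.json", json.dumps(header, sort_keys=True))
        zf.writestr("embeddings.f32", mat32.tobytes())


def load_index(path: str | Path) -> ReferenceIndex:
    with zipfile.ZipFile(path) as zf:
        header = json.loads(zf.read("shape.json"))
        raw = zf.read("embeddings.f32")
        mat = np.frombuffer(raw, dtype=header["dtype"]).reshape(header["shape"])
        lines = zf.read("meta.tsv").decode("utf-8").splitlines()
    if lines[0] != "record_id\tprescription":
        raise ValueError("unexpected index metadata header")
    rids, rxs = [], []
    for line in lines[1:]:
        rid, rx = line.split("\t")
        rids.append(rid)
        rxs.append(rx)
    # no renormalization: float32 keeps unit norm within tolerance, and
    # save(load(p)) must reproduce the stored matrix bit-exactly
    return ReferenceIndex(
        embeddings=mat.astype(np.float64), prescriptions=rxs, record_ids=rids,
        fingerprint=header.get("fingerprint", ""),
        groups=tuple(header.get("groups", FIELD_GROUPS)),
    )
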