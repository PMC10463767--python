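"""Record normalization, serialization, splitting, and pair construction."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from prser import corpus
from prser.corpus import (FIELD_GROUPS, GROUP_FIELDS, FIELD_SEPARATOR,
                          RecordInvalidError, SplitSpec, TextPair,
                          build_pairs, normalize_corpus, normalize_record,
                          read_pairs, read_records, serialize_record,
                          split_dataset, write_pairs, write_records)
from conftest import make_record


def raw_record(record_id="r1", prescription="Mancozeb", symptoms="leaf spots"):
    return {
        "record_id": record_id,
        "environment": {"onset_date": " 2023-06-01 ", "location": "field A"},
        "plant": {"species": "tomato"},
        "symptom": {"main_symptoms": symptoms},
        "prescription": prescription,
    }


class TestNormalization:
    def test_alias_lookup_after_trim_and_casefold(self):
        alias = {"mancozeb 80%wp": "mancozeb"}
        rec = normalize_record(raw_record(prescription=" Mancozeb  80%WP"), alias)
        assert rec.prescription == "mancozeb"

    def test_fullwidth_text_normalized_and_whitespace_collapsed(self):
        rec = normalize_record(raw_record(symptoms="ｌｅａｆ　　ｓｐｏｔ"))
        assert rec.symptom["main_symptoms"] == "leaf spot"

    def test_empty_prescription_rejected(self):
        with pytest.raises(RecordInvalidError) as err:
            normalize_record(raw_record(prescription="   "))
        assert err.value.record_id == "r1"

    def test_missing_prescription_rejected(self):
        raw = raw_record()
        del raw["prescription"]
        with pytest.raises(RecordInvalidError):
            normalize_record(raw)

    def test_empty_symptom_group_rejected(self):
        raw = raw_record(symptoms="")
        with pytest.raises(RecordInvalidError):
            normalize_record(raw)

    def test_duplicate_records_excluded_once(self):
        raws = [raw_record("a"), raw_record("b"), raw_record("c", symptoms="wilt")]
        kept, rejected, dups = normalize_corpus(raws)
        assert [r.record_id for r in kept] == ["a", "c"]
        assert dups == ["b"]
        assert not rejected


class TestSerialization:
    def test_symptom_only_projection(self):
        rec = make_record()
        text = serialize_record(rec, ["symptom"])
        expected = FIELD_SEPARATOR.join(
            f" {rec.symptom[f]} " for f in GROUP_FIELDS["symptom"]).strip()
        assert text == expected
        assert "tomato" not in text

    def test_deterministic(self):
        rec = make_record()
        assert serialize_record(rec, FIELD_GROUPS) == serialize_record(rec, FIELD_GROUPS)

    def test_all_groups_matches_hand_built_concatenation(self):
        rec = make_record()
        fields = []
        for g in ("environment", "plant", "symptom"):
            fields.extend(rec.group(g)[f] for f in GROUP_FIELDS[g])
        assert serialize_record(rec) == f" {FIELD_SEPARATOR} ".join(fields)
        assert len(fields) == 9

    def test_empty_groups_rejected(self):
        with pytest.raises(ValueError):
            serialize_record(make_record(), [])


def _records_with_labels(labels):
    return [make_record(record_id=f"r{i}", prescription=lab)
            for i, lab in enumerate(labels)]


class TestSplit:
    def test_single_stratum_8_1_1(self):
        recs = _records_with_labels(["a"] * 10)
        parts = split_dataset(recs, SplitSpec((0.8, 0.1, 0.1), seed=0))
        assert [len(p) for p in parts] == [8, 1, 1]

    def test_even_split_5_5(self):
        recs = _records_with_labels(["a"] * 20)
        parts = split_dataset(recs, SplitSpec((0.5, 0.5), seed=0))
        assert [len(p) for p in parts] == [10, 10]

    def test_largest_remainder_on_two_strata(self):
        recs = _records_with_labels(["a"] * 7 + ["b"] * 3)
        parts = split_dataset(recs, SplitSpec((0.7, 0.3), seed=0))
        per_stratum = [
            (sum(r.prescription == "a" for r in p),
             sum(r.prescription == "b" for r in p)) for p in parts]
        assert per_stratum == [(5, 2), (2, 1)]

    def test_partition_is_disjoint_and_complete(self):
        recs = _records_with_labels(["a"] * 11 + ["b"] * 7 + ["c"] * 5)
        parts = split_dataset(recs, SplitSpec((0.6, 0.2, 0.2), seed=3))
        ids = [frozenset(r.record_id for r in p) for p in parts]
        assert sum(len(s) for s in ids) == len(recs)
        assert frozenset().union(*ids) == {r.record_id for r in recs}

    def test_tiny_stratum_goes_to_largest_part_with_warning(self):
        recs = _records_with_labels(["a"] * 6 + ["rare"])
        with pytest.warns(UserWarning, match="rare"):
            parts = split_dataset(recs, SplitSpec((0.5, 0.3, 0.2), seed=0))
        assert any(r.prescription == "rare" for r in parts[0])

    def test_same_seed_reproduces_identical_split(self):
        recs = _records_with_labels(list("aabbccdd") * 3)
        spec = SplitSpec((0.5, 0.25, 0.25), seed=9)
        p1 = split_dataset(recs, spec)
        p2 = split_dataset(recs, spec)
        assert [[r.record_id for r in p] for p in p1] == \
               [[r.record_id for r in p] for p in p2]

    def test_invalid_ratios_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec((0.5, 0.4))
        with pytest.raises(ValueError):
            SplitSpec((1.2, -0.2))


class TestPairs:
    def test_single_record_yields_no_pairs(self):
        assert build_pairs(_records_with_labels(["a"])) == []

    def test_two_two_balance(self):
        # 4 records, labels A,A,B,B: C(4,2)=6 candidates, 2 pos, 4 neg
        recs = _records_with_labels(["A", "A", "B", "B"])
        pairs = build_pairs(recs, balance_ratio=1.0, seed=0)
        assert len(pairs) == 4
        assert sum(p.label for p in pairs) == 2

    def test_three_records_one_pos_one_neg(self):
        recs = _records_with_labels(["A", "A", "B"])
        pairs = build_pairs(recs, balance_ratio=1.0, seed=1)
        assert sum(p.label for p in pairs) == 1
        assert sum(1 - p.label for p in pairs) == 1

    def test_no_positives_returns_all_negatives_with_warning(self):
        recs = _records_with_labels(["A", "B", "C"])
        with pytest.warns(UserWarning):
            pairs = build_pairs(recs, seed=0)
        assert len(pairs) == 3
        assert all(p.label == 0 for p in pairs)

    def test_labels_match_independent_recomputation(self):
        rng = np.random.default_rng(5)
        labels = rng.choice(list("abc"), size=12).tolist()
        recs = [make_record(record_id=f"r{i}", prescription=lab,
                            symptom={"severity": "mild", "main_symptoms": f"spot {i}",
                                     "detail": f"lesion variant {i}"})
                for i, lab in enumerate(labels)]
        text_to_rx = {serialize_record(r): r.prescription for r in recs}
        assert len(text_to_rx) == len(recs)  # oracle needs unique texts
        for p in build_pairs(recs, balance_ratio=2.0, seed=7):
            assert p.label == int(text_to_rx[p.text_a] == text_to_rx[p.text_b])
            assert p.text_a != p.text_b

    @given(n_a=st.integers(2, 6), n_b=st.integers(0, 6), seed=st.integers(0, 10))
    @settings(max_examples=25, deadline=None)
    def test_pair_counts_match_combinatorics(self, n_a, n_b, seed):
        recs = _records_with_labels(["a"] * n_a + ["b"] * n_b)
        n = len(recs)
        pairs = build_pairs(recs, balance_ratio=1.0, seed=seed)
        n_pos = sum(p.label for p in pairs)
        expected_pos = n_a * (n_a - 1) // 2 + n_b * (n_b - 1) // 2
        assert n_pos == expected_pos
        assert len(pairs) <= n * (n - 1) // 2
        n_neg_candidates = n_a * n_b
        assert len(pairs) - n_pos == min(n_neg_candidates, expected_pos)

    def test_max_positives_caps_and_rebalances(self):
        recs = _records_with_labels(["a"] * 8 + ["b"] * 8)
        pairs = build_pairs(recs, balance_ratio=1.0, seed=0, max_positives=10)
        assert sum(p.label for p in pairs) == 10
        assert len(pairs) == 20

    def test_same_seed_identical_pair_files(self, tmp_path):
        recs = _records_with_labels(list("aabbcc") * 2)
        for name in ("one", "two"):
            write_pairs(build_pairs(recs, seed=11), tmp_path / name)
        assert (tmp_path / "one").read_bytes() == (tmp_path / "two").read_bytes()

    def test_different_seed_same_counts(self):
        recs = _records_with_labels(list("aabbcc") * 2)
        p1 = build_pairs(recs, seed=1)
        p2 = build_pairs(recs, seed=2)
        assert len(p1) == len(p2)
        assert sum(p.label for p in p1) == sum(p.label for p in p2)
        assert p1 != p2


class TestRoundTrips:
    def test_jsonl_round_trip(self, tmp_path):
        recs = [make_record("x1"), make_record("x2", prescription="rx-b")]
        path = tmp_path / "records.jsonl"
        write_records(recs, path)
        assert read_records(path) == recs

    def test_pairs_tsv_round_trip(self, tmp_path):
        pairs = [TextPair("a b", "c d", 1), TextPair("e", "f", 0)]
        path = tmp_path / "pairs.tsv"
        write_pairs(pairs, path)
        assert read_pairs(path) == pairs

    def test_alias_map_parsing(self, tmp_path):
        path = tmp_path / "alias.tsv"
        path.write_text("# comment\nMancozeb 80%WP\tmancozeb\n", encoding="utf-8")
        table = corpus.read_alias_map(path)
        assert table == {"mancozeb 80%wp": "mancozeb"}
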