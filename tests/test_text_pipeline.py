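"""Cleaning, vocabulary, encoding, splitting, and file-format round trips."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from icdcoder.text_pipeline import (
    FIELD_SEP,
    LabeledNote,
    PAD_INDEX,
    PAD_TOKEN,
    RawRecord,
    UNK_INDEX,
    UNK_TOKEN,
    Vocabulary,
    build_vocabulary,
    clean_text,
    decode,
    drop_null_and_duplicates,
    encode,
    read_code_catalog,
    read_notes_jsonl,
    read_notes_tsv,
    read_stopwords,
    record_to_note,
    split_dataset,
    write_code_catalog,
    write_notes_jsonl,
    write_notes_tsv,
)
from icdcoder.text_pipeline import LabelSpace


class TestCleanText:
    @pytest.mark.parametrize(
        "raw, stop, expected",
        [
            (
                "He had coronary artery disease. Also, he got fever.",
                {"he", "had", "also"},
                ["coronary", "artery", "disease", "got", "fever"],
            ),
            ("", frozenset(), []),
            ("fever 發燒 39C !!", frozenset(), ["fever", "39c"]),
            ("中文只有", frozenset(), []),
            ("a,b;c", frozenset(), ["a", "b", "c"]),
        ],
    )
    def test_examples(self, raw, stop, expected):
        assert clean_text(raw, stop) == expected

    def test_output_is_latin_lowercase(self):
        toks = clean_text("Mixed 病歷 CASE with UPPER 39C and 中文!", frozenset())
        for t in toks:
            assert t == t.lower()
            assert all(c.isascii() and (c.isalpha() or c.isdigit()) for c in t)

    @given(st.text(max_size=80))
    @settings(max_examples=200, deadline=None)
    def test_idempotent(self, raw):
        once = clean_text(raw)
        again = clean_text(" ".join(once))
        assert once == again

    def test_duplicate_tokens_within_note_kept(self):
        assert clean_text("pain pain pain", frozenset()) == ["pain"] * 3


class TestDropNullAndDuplicates:
    def test_duplicates_and_nulls(self):
        r1 = RawRecord("1", [("dx", "fever")], ["A"])
        r1_copy = RawRecord("1b", [("dx", "fever")], ["A"])
        r2 = RawRecord("2", [("dx", "cough")], ["B"])
        r_empty = RawRecord("3", [("dx", "   ")], ["C"])
        out = drop_null_and_duplicates([r1, r1_copy, r2, r_empty])
        assert [r.note_id for r in out] == ["1", "2"]

    def test_same_text_different_codes_kept(self):
        r1 = RawRecord("1", [("dx", "fever")], ["A"])
        r2 = RawRecord("2", [("dx", "fever")], ["B"])
        assert len(drop_null_and_duplicates([r1, r2])) == 2

    def test_identity_on_clean_input(self):
        recs = [RawRecord(str(i), [("dx", f"text {i}")], []) for i in range(10)]
        assert drop_null_and_duplicates(recs) == recs


class TestVocabulary:
    def test_frequency_threshold(self):
        notes = [LabeledNote("1", ["a", "b", "a"]), LabeledNote("2", ["b", "c"])]
        v = build_vocabulary(notes, min_count=2)
        assert v.to_dict() == {PAD_TOKEN: 0, UNK_TOKEN: 1, "a": 2, "b": 3}

    def test_empty_corpus(self):
        v = build_vocabulary([], min_count=2)
        assert v.to_dict() == {PAD_TOKEN: 0, UNK_TOKEN: 1}

    def test_min_count_one_keeps_everything(self):
        notes = [LabeledNote("1", ["x", "y"]), LabeledNote("2", ["z"])]
        v = build_vocabulary(notes, min_count=1)
        assert set(v.to_dict()) == {PAD_TOKEN, UNK_TOKEN, "x", "y", "z"}

    def test_matches_brute_force_counter(self):
        from collections import Counter

        rng = np.random.default_rng(3)
        notes = [
            LabeledNote(str(i), list(rng.choice(list("abcdefg"), size=8)))
            for i in range(30)
        ]
        counts = Counter(t for n in notes for t in n.tokens)
        for mc in (1, 3, 10):
            v = build_vocabulary(notes, min_count=mc)
            expected = {t for t, c in counts.items() if c >= mc}
            assert set(v.to_dict()) - {PAD_TOKEN, UNK_TOKEN} == expected

    def test_order_independence_up_to_permutation(self):
        notes = [LabeledNote("1", ["a", "b"]), LabeledNote("2", ["c", "a"])]
        v1 = build_vocabulary(notes, min_count=1)
        v2 = build_vocabulary(notes[::-1], min_count=1)
        assert set(v1.to_dict()) == set(v2.to_dict())


class TestEncode:
    def test_lookup_pad(self, tiny_vocab):
        idx, n = encode(["a", "b"], tiny_vocab, max_len=4)
        assert idx.tolist() == [tiny_vocab["a"], tiny_vocab["b"], PAD_INDEX, PAD_INDEX]
        assert n == 2

    def test_unknown_token(self, tiny_vocab):
        idx, n = encode(["zzz"], tiny_vocab, max_len=2)
        assert idx.tolist() == [UNK_INDEX, PAD_INDEX]
        assert n == 1

    def test_truncation(self, tiny_vocab):
        idx, n = encode(["a"] * 6, tiny_vocab, max_len=4)
        assert n == 4 and len(idx) == 4

    def test_decode_round_trip(self, tiny_vocab):
        tokens = ["a", "zzz", "c", "b"]
        idx, n = encode(tokens, tiny_vocab, max_len=8)
        assert decode(idx, tiny_vocab, n) == ["a", UNK_TOKEN, "c", "b"]


class TestSplit:
    def test_sizes_and_partition(self):
        notes = [LabeledNote(str(i), ["t"]) for i in range(100)]
        s = split_dataset(notes, ratio=0.9, seed=1)
        assert len(s.train) == 90 and len(s.valid) == 10
        ids = {n.note_id for n in s.train} | {n.note_id for n in s.valid}
        assert ids == {str(i) for i in range(100)}

    def test_determinism(self):
        notes = [LabeledNote(str(i), ["t"]) for i in range(37)]
        a = split_dataset(notes, 0.9, seed=9)
        b = split_dataset(notes, 0.9, seed=9)
        assert [n.note_id for n in a.train] == [n.note_id for n in b.train]
        assert [n.note_id for n in a.valid] == [n.note_id for n in b.valid]

    def test_random_instances_property(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(2, 200))
            ratio = float(rng.uniform(0.1, 0.95))
            seed = int(rng.integers(0, 2**31))
            notes = [LabeledNote(str(i), ["t"]) for i in range(n)]
            s = split_dataset(notes, ratio, seed)
            assert len(s.train) == int(np.floor(ratio * n))
            assert len(s.train) + len(s.valid) == n
            train_ids = {x.note_id for x in s.train}
            valid_ids = {x.note_id for x in s.valid}
            assert not train_ids & valid_ids

    def test_too_small_errors(self):
        with pytest.raises(ValueError, match="cannot split"):
            split_dataset([LabeledNote("1", ["t"])], 0.9, 0)


class TestRecordToNote:
    def test_fields_joined_with_separator(self):
        rec = RawRecord("1", [("progress", "stable gait"), ("dx", "fever")], ["A"])
        note = record_to_note(rec, frozenset())
        assert note.tokens == ["stable", "gait", FIELD_SEP, "fever"]

    def test_empty_fields_skipped(self):
        rec = RawRecord("1", [("a", "!!"), ("b", "fever")], [])
        assert record_to_note(rec, frozenset()).tokens == ["fever"]


class TestFileFormats:
    def _records(self):
        return [
            RawRecord("n1", [("dx", "fever and chills"), ("course", "stable")], ["A1", "B2"]),
            RawRecord("n2", [("dx", "fracture 骨折"), ("course", "")], []),
        ]

    def test_tsv_round_trip(self, tmp_path):
        path = tmp_path / "notes.tsv"
        write_notes_tsv(self._records(), path)
        back = read_notes_tsv(path)
        assert back == self._records()

    def test_jsonl_round_trip(self, tmp_path):
        path = tmp_path / "notes.jsonl"
        write_notes_jsonl(self._records(), path)
        assert read_notes_jsonl(path) == self._records()

    def test_code_catalog_round_trip(self, tmp_path):
        space = LabelSpace({"A1": "first disease", "B2": "second disease"})
        path = tmp_path / "codes.tsv"
        write_code_catalog(space, path)
        back = read_code_catalog(path)
        assert back.codes == space.codes
        assert back.definitions == space.definitions

    def test_stopword_file(self, tmp_path):
        path = tmp_path / "stop.txt"
        path.write_text("the\nand\n\nof\n")
        assert read_stopwords(path) == {"the", "and", "of"}

    def test_catalog_malformed_line(self, tmp_path):
        path = tmp_path / "codes.tsv"
        path.write_text("A1 no tab here\n")
        with pytest.raises(ValueError, match="line 1"):
            read_code_catalog(path)
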