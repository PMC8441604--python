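"""Deterministic text preprocessing for clinical discharge notes.

Cleaning follows the conventions of hospital coding pipelines built on
English-language electronic health records: text is lowercased, any
codepoint outside basic Latin letters and digits (Chinese annotations,
punctuation, symbols) is treated as a separator, stopwords are dropped,
and rare tokens are removed when the vocabulary is built.  Records that
are empty after cleaning, or exact duplicates of an earlier record, are
discarded at the corpus level.
"""

from __future__ import annotations

import json
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS

PAD_TOKEN = "<pad>"
UNK_TOKEN = "<unk>"
PAD_INDEX = 0
UNK_INDEX = 1

#: separator token inserted between concatenated text fields
FIELD_SEP = "fieldsep"

DEFAULT_STOPWORDS: frozenset[str] = frozenset(ENGLISH_STOP_WORDS)


@dataclass
class RawRecord:
    """One unprocessed note: id, ordered (field name, raw text) pairs, gold codes."""

    note_id: str
    fields: list[tuple[str, str]]
    gold_codes: list[str] = field(default_factory=list)

    def concat_text(self) -> str:
        return " ".join(text for _, text in self.fields)


@dataclass
class LabeledNote:
    """A cleaned, tokenized note with its gold ICD code set."""

    note_id: str
    tokens: list[str]
    gold_codes: set[str] = field(default_factory=set)


class Vocabulary:
    """Token-to-index mapping with reserved PAD (0) and UNK (1) slots.

    Non-reserved tokens are indexed in first-appearance order and must
    occur at least ``min_count`` times in the corpus the vocabulary was
    built from.
    """

    def __init__(self, tokens: Iterable[str] = (), min_count: int = 1):
        self.min_count = min_count
        self._index: dict[str, int] = {PAD_TOKEN: PAD_INDEX, UNK_TOKEN: UNK_INDEX}
        for tok in tokens:
            if tok not in self._index:
                self._index[tok] = len(self._index)

    def __len__(self) -> int:
        return len(self._index)

    def __contains__(self, token: str) -> bool:
        return token in self._index

    def __getitem__(self, token: str) -> int:
        return self._index.get(token, UNK_INDEX)

    def tokens(self) -> list[str]:
        """All tokens including reserved ones, in index order."""
        return sorted(self._index, key=self._index.get)

    def to_dict(self) -> dict[str, int]:
        return dict(self._index)

    @classmethod
    def from_dict(cls, d: dict[str, int], min_count: int = 1) -> "Vocabulary":
        v = cls(min_count=min_count)
        for tok, idx in sorted(d.items(), key=lambda kv: kv[1]):
            if tok not in v._index:
                v._index[tok] = idx
        return v


class LabelSpace:
    """Bijective code <-> index mapping with per-code definition text."""

    def __init__(self, code_to_definition: dict[str, str]):
        self.codes: list[str] = list(code_to_definition)
        self.code_to_index: dict[str, int] = {c: i for i, c in enumerate(self.codes)}
        self.definitions: dict[str, str] = dict(code_to_definition)

    def __len__(self) -> int:
        return len(self.codes)

    def __contains__(self, code: str) -> bool:
        return code in self.code_to_index

    def index(self, code: str) -> int:
        return self.code_to_index[code]

    def code(self, index: int) -> str:
        return self.codes[index]

    def definition(self, code: str) -> str:
        return self.definitions[code]

    def binarize(self, codes: Iterable[str]) -> np.ndarray:
        """Multi-hot vector of length L; unknown codes are ignored."""
        y = np.zeros(len(self.codes), dtype=np.float32)
        for c in codes:
            if c in self.code_to_index:
                y[self.code_to_index[c]] = 1.0
        return y


@dataclass
class SplitResult:
    train: list[LabeledNote]
    valid: list[LabeledNote]
    seed: int


def _is_latin_or_digit(ch: str) -> bool:
    return ("a" <= ch <= "z") or ("A" <= ch <= "Z") or ("0" <= ch <= "9")


def clean_text(raw: str, stopwords: frozenset[str] | set[str] | None = None) -> list[str]:
    """Clean one raw text into a token list.

    Non-Latin codepoints (e.g. Chinese characters) and punctuation are
    replaced by spaces, the text is lowercased and whitespace-tokenized,
    and stopwords are removed.  Token order is preserved and repeated
    tokens within a note are kept.  Degenerate input yields ``[]``.
    """
    if stopwords is None:
        stopwords = DEFAULT_STOPWORDS
    # NFKC first so full-width Latin forms survive the character filter
    raw = unicodedata.normalize("NFKC", raw)
    chars = [ch if _is_latin_or_digit(ch) else " " for ch in raw]
    tokens = "".join(chars).lower().split()
    return [t for t in tokens if t not in stopwords]


def drop_null_and_duplicates(records: Sequence[RawRecord]) -> list[RawRecord]:
    """Remove records whose text is entirely empty/whitespace and exact
    duplicates (same concatenated text and same code multiset), keeping
    the first occurrence. Order is otherwise preserved."""
    seen: set[tuple[str, tuple[str, ...]]] = set()
    out: list[RawRecord] = []
    for rec in records:
        text = rec.concat_text()
        if not text.strip():
            continue
        key = (text, tuple(sorted(rec.gold_codes)))
        if key in seen:
            continue
        seen.add(key)
        out.append(rec)
    return out


def record_to_note(
    rec: RawRecord, stopwords: frozenset[str] | set[str] | None = None
) -> LabeledNote:
    """Clean and concatenate a record's fields into one LabeledNote.

    Fields are joined in their declared order with a separator token so
    the classifier can tell, e.g., progress text from discharge
    diagnosis text.
    """
    parts: list[list[str]] = []
    for _, text in rec.fields:
        toks = clean_text(text, stopwords)
        if toks:
            parts.append(toks)
    tokens: list[str] = []
    for i, toks in enumerate(parts):
        if i > 0:
            tokens.append(FIELD_SEP)
        tokens.extend(toks)
    return LabeledNote(rec.note_id, tokens, set(rec.gold_codes))


def build_vocabulary(notes: Sequence[LabeledNote], min_count: int = 2) -> Vocabulary:
    """Index every token with corpus frequency >= min_count, in
    first-appearance order, after the reserved PAD/UNK slots."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts: dict[str, int] = {}
    order: list[str] = []
    for note in notes:
        for tok in note.tokens:
            if tok not in counts:
                order.append(tok)
                counts[tok] = 0
            counts[tok] += 1
    kept = (t for t in order if counts[t] >= min_count)
    return Vocabulary(kept, min_count=min_count)


def encode(
    tokens: Sequence[str], vocab: Vocabulary, max_len: int = 256
) -> tuple[np.ndarray, int]:
    """Map tokens to indices, truncate/right-pad to ``max_len``.

    Returns ``(indices, true_length)`` where ``true_length`` is the
    pre-padding length (capped at max_len).
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    idx = [vocab[t] for t in tokens[:max_len]]
    length = len(idx)
    idx.extend([PAD_INDEX] * (max_len - length))
    return np.asarray(idx, dtype=np.int64), length


def decode(indices: Sequence[int], vocab: Vocabulary, length: int | None = None) -> list[str]:
    """Inverse of :func:`encode` on the unpadded prefix (UNK stays UNK)."""
    toks = vocab.tokens()
    if length is None:
        length = len(indices)
    return [toks[i] for i in list(indices)[:length]]


def split_dataset(
    notes: Sequence[LabeledNote], ratio: float = 0.9, seed: int = 0
) -> SplitResult:
    """Seeded uniform random train/validation split.

    The first ``floor(ratio * n)`` notes of a seeded permutation go to
    train, the remainder to validation; same seed, same split.
    """
    n = len(notes)
    if n < 2:
        raise ValueError("cannot split: need at least 2 notes")
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(np.floor(ratio * n))
    train = [notes[i] for i in perm[:n_train]]
    valid = [notes[i] for i in perm[n_train:]]
    return SplitResult(train=train, valid=valid, seed=seed)


# ---------------------------------------------------------------------------
# File formats: note TSV / JSON-lines, code catalog TSV, stopword lists.

CODES_COLUMN = "codes"
NOTE_ID_COLUMN = "note_id"


def read_notes_tsv(path: str | Path, sep: str = "\t") -> list[RawRecord]:
    """Read records from delimited text with columns ``note_id``, one
    column per text field, and ``codes`` (semicolon-separated)."""
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    return _records_from_frame(df)


def write_notes_tsv(records: Sequence[RawRecord], path: str | Path, sep: str = "\t") -> None:
    rows = []
    for rec in records:
        row = {NOTE_ID_COLUMN: rec.note_id}
        for name, text in rec.fields:
            row[name] = text
        row[CODES_COLUMN] = ";".join(rec.gold_codes)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def read_notes_jsonl(path: str | Path) -> list[RawRecord]:
    """Read records from JSON-lines with keys note_id, codes, and one
    key per text field."""
    records = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            records.append(_record_from_mapping(obj))
    return records


def write_notes_jsonl(records: Sequence[RawRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            obj = {NOTE_ID_COLUMN: rec.note_id}
            for name, text in rec.fields:
                obj[name] = text
            obj[CODES_COLUMN] = rec.gold_codes
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


def _records_from_frame(df: pd.DataFrame) -> list[RawRecord]:
    if NOTE_ID_COLUMN not in df.columns:
        raise ValueError(f"missing required column {NOTE_ID_COLUMN!r}")
    field_cols = [c for c in df.columns if c not in (NOTE_ID_COLUMN, CODES_COLUMN)]
    records = []
    for _, row in df.iterrows():
        codes_raw = str(row.get(CODES_COLUMN, "") or "")
        codes = [c for c in codes_raw.split(";") if c]
        fields = [(c, str(row[c])) for c in field_cols]
        records.append(RawRecord(str(row[NOTE_ID_COLUMN]), fields, codes))
    return records


def _record_from_mapping(obj: dict) -> RawRecord:
    note_id = str(obj[NOTE_ID_COLUMN])
    codes = obj.get(CODES_COLUMN, [])
    if isinstance(codes, str):
        codes = [c for c in codes.split(";") if c]
    fields = [
        (k, str(v)) for k, v in obj.items() if k not in (NOTE_ID_COLUMN, CODES_COLUMN)
    ]
    return RawRecord(note_id, fields, list(codes))


def read_code_catalog(path: str | Path) -> LabelSpace:
    """Read a ``code<TAB>definition`` catalog into a LabelSpace."""
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t", 1)
            if len(parts) != 2:
                raise ValueError(f"line {lineno}: expected code<TAB>definition")
            mapping[parts[0]] = parts[1]
    return LabelSpace(mapping)


def write_code_catalog(space: LabelSpace, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for code in space.codes:
            fh.write(f"{code}\t{space.definition(code)}\n")


def read_stopwords(path: str | Path) -> frozenset[str]:
    """Read a stopword file: one token per line, UTF-8."""
    with open(path, encoding="utf-8") as fh:
        return frozenset(line.strip() for line in fh if line.strip())
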