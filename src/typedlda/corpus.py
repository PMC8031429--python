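"""Typed bag-of-words corpora.

A *typed corpus* is a document collection in which every token belongs to one
of a small set of note types (e.g. ``physician`` vs ``nursing`` notes of the
same hospital admission).  Each type carries its own vocabulary, while all
notes that share a group identifier (an admission) are pooled into a single
document assumed to have one topic composition.

This module provides the preprocessing pipeline (tokenisation, stopword
removal, document-frequency filtering), grouping of raw notes into documents,
the three corpus representations used to compare multi-type modelling against
flattened baselines, and a plain-text on-disk format (Matrix Market counts +
TSV vocabularies + JSONL manifest).
"""

from __future__ import annotations

import json
import logging
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from ._stopwords import ENGLISH_STOPWORDS

logger = logging.getLogger(__name__)

__all__ = [
    "CorpusMode",
    "RawNote",
    "TokenizedNote",
    "TokenStreams",
    "TypedCorpus",
    "tokenize_and_filter",
    "group_into_documents",
    "build_corpus_variant",
    "read_raw_notes",
    "read_outcomes",
]

_TOKEN_RE = re.compile(r"[a-z0-9]+")
_MIN_TOKEN_LEN = 2


class CorpusMode(str, Enum):
    """How note types are represented in the document-term counts.

    ``multi_type``
        Each type keeps its own vocabulary and count matrix (the full model).
    ``single_same_word``
        Types are flattened; identical word strings from different types are
        merged and their counts summed.
    ``single_diff_word``
        Types are flattened but each (type, word) pair stays a distinct
        vocabulary entry named ``"<type>-<word>"``.
    """

    MULTI_TYPE = "multi_type"
    SINGLE_SAME_WORD = "single_same_word"
    SINGLE_DIFF_WORD = "single_diff_word"


@dataclass(frozen=True)
class RawNote:
    """A single free-text note before preprocessing."""

    group_id: str
    note_type: str
    text: str


@dataclass(frozen=True)
class TokenizedNote:
    """A note reduced to a bag of retained tokens."""

    group_id: str
    note_type: str
    counts: Mapping[str, int]


@dataclass
class TokenStreams:
    """Output of :func:`tokenize_and_filter`: filtered notes + vocabularies."""

    notes: List[TokenizedNote]
    vocab: Dict[str, List[str]]  # note type -> sorted retained word list

    @property
    def type_labels(self) -> List[str]:
        return list(self.vocab.keys())


def _tokenize(text: str) -> List[str]:
    """Lowercase, split on non-alphanumeric runs, drop very short tokens."""
    return [t for t in _TOKEN_RE.findall(text.lower()) if len(t) >= _MIN_TOKEN_LEN]


def tokenize_and_filter(
    notes: Iterable[RawNote],
    min_doc_count: int = 5,
    max_doc_fraction: float = 0.15,
    stopwords: Optional[Set[str]] = None,
    note_types: Optional[Sequence[str]] = None,
    per_type_df: bool = False,
) -> TokenStreams:
    """Tokenise notes and apply the document-frequency vocabulary filter.

    A word is retained iff its note-level document frequency (number of
    distinct notes containing it, counted *before* grouping into admissions)
    is at least ``min_doc_count`` and at most ``max_doc_fraction`` times the
    number of notes.  The defaults (5, 0.15) drop words seen in fewer than 5
    notes or in more than 15% of notes.  By default the frequency universe is
    all notes of all types pooled; ``per_type_df=True`` counts within each
    note type separately.

    Parameters
    ----------
    notes
        The raw notes.  An empty collection yields an empty result.
    stopwords
        Words removed before frequency counting; defaults to the bundled
        English list.
    note_types
        Declared closed set of admissible types.  A note with a type outside
        this set raises ``ValueError``; if omitted, types are inferred.
    """
    if min_doc_count < 1:
        raise ValueError("min_doc_count must be >= 1")
    if not (0.0 < max_doc_fraction <= 1.0):
        raise ValueError("max_doc_fraction must lie in (0, 1]")
    stopwords = ENGLISH_STOPWORDS if stopwords is None else set(stopwords)

    notes = list(notes)
    if note_types is not None:
        declared = set(note_types)
        for note in notes:
            if note.note_type not in declared:
                raise ValueError(
                    f"note with group_id={note.group_id!r} has unknown "
                    f"note_type={note.note_type!r}; declared types: {sorted(declared)}"
                )

    tokenized: List[tuple[str, str, Counter]] = []
    for note in notes:
        counts = Counter(t for t in _tokenize(note.text) if t not in stopwords)
        tokenized.append((note.group_id, note.note_type, counts))

    # note-level document frequencies
    df_pooled: Counter = Counter()
    df_by_type: Dict[str, Counter] = defaultdict(Counter)
    n_notes_by_type: Counter = Counter()
    for _, ntype, counts in tokenized:
        n_notes_by_type[ntype] += 1
        for word in counts:
            df_pooled[word] += 1
            df_by_type[ntype][word] += 1
    n_notes = len(tokenized)

    def _passes(word: str, ntype: str) -> bool:
        if per_type_df:
            df = df_by_type[ntype][word]
            ceiling = max_doc_fraction * n_notes_by_type[ntype]
        else:
            df = df_pooled[word]
            ceiling = max_doc_fraction * n_notes
        return df >= min_doc_count and df <= ceiling

    type_order = list(note_types) if note_types is not None else sorted(n_notes_by_type)
    vocab_sets: Dict[str, Set[str]] = {t: set() for t in type_order}
    out_notes: List[TokenizedNote] = []
    for gid, ntype, counts in tokenized:
        kept = {w: c for w, c in counts.items() if _passes(w, ntype)}
        vocab_sets[ntype].update(kept)
        out_notes.append(TokenizedNote(gid, ntype, kept))

    vocab = {t: sorted(vocab_sets[t]) for t in type_order}
    return TokenStreams(notes=out_notes, vocab=vocab)


@dataclass
class TypedCorpus:
    """Sparse per-type document-term counts with per-type vocabularies.

    ``counts[t]`` is a ``D x W_t`` CSR matrix of non-negative integer token
    counts for note type ``type_labels[t]``; row ``j`` of every matrix refers
    to the same document ``doc_ids[j]``.
    """

    type_labels: List[str]
    vocabs: List[List[str]]
    counts: List[sp.csr_matrix]
    doc_ids: List[str]
    mode: CorpusMode = CorpusMode.MULTI_TYPE

    # -- basic shape -------------------------------------------------------
    @property
    def num_docs(self) -> int:
        return len(self.doc_ids)

    @property
    def num_types(self) -> int:
        return len(self.type_labels)

    @property
    def vocab_sizes(self) -> List[int]:
        return [len(v) for v in self.vocabs]

    def doc_token_totals(self) -> np.ndarray:
        """``(D, T)`` array of token totals per document and type."""
        if self.num_docs == 0:
            return np.zeros((0, self.num_types))
        return np.stack(
            [np.asarray(m.sum(axis=1)).ravel() for m in self.counts], axis=1
        )

    @property
    def total_tokens(self) -> int:
        return int(sum(m.sum() for m in self.counts))

    def validate(self) -> None:
        if len(self.vocabs) != self.num_types or len(self.counts) != self.num_types:
            raise ValueError("type_labels, vocabs and counts must align")
        for label, vocab, m in zip(self.type_labels, self.vocabs, self.counts):
            if len(set(vocab)) != len(vocab):
                raise ValueError(f"duplicate vocabulary entries for type {label!r}")
            if m.shape != (self.num_docs, len(vocab)):
                raise ValueError(f"count matrix shape mismatch for type {label!r}")
            data = m.data
            if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
                raise ValueError(f"counts for type {label!r} must be non-negative integers")
        if self.num_docs and np.any(self.doc_token_totals().sum(axis=1) == 0):
            raise ValueError("every document must contain at least one token")

    def subset(self, rows: Sequence[int]) -> "TypedCorpus":
        """A new corpus containing the given document rows (in that order)."""
        rows = np.asarray(rows, dtype=int)
        return TypedCorpus(
            list(self.type_labels),
            [list(v) for v in self.vocabs],
            [sp.csr_matrix(m[rows]) for m in self.counts],
            [self.doc_ids[j] for j in rows],
            self.mode,
        )

    # -- serialization -----------------------------------------------------
    def save(self, out_dir: str | Path) -> None:
        """Write the corpus as MTX matrices + TSV vocabularies + manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        totals = self.doc_token_totals()
        for label, vocab, m in zip(self.type_labels, self.vocabs, self.counts):
            mmwrite(str(out / f"counts_{label}.mtx"), sp.coo_matrix(m))
            pd.DataFrame({"index": range(len(vocab)), "word": vocab}).to_csv(
                out / f"vocab_{label}.tsv", sep="\t", index=False
            )
        with open(out / "manifest.jsonl", "w") as fh:
            for j, gid in enumerate(self.doc_ids):
                rec = {
                    "group_id": gid,
                    "row": j,
                    "token_totals": {
                        label: int(totals[j, t])
                        for t, label in enumerate(self.type_labels)
                    },
                }
                fh.write(json.dumps(rec) + "\n")
        meta = {"type_labels": self.type_labels, "mode": self.mode.value}
        (out / "metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True))

    @classmethod
    def load(cls, in_dir: str | Path) -> "TypedCorpus":
        src = Path(in_dir)
        meta = json.loads((src / "metadata.json").read_text())
        labels = meta["type_labels"]
        vocabs, counts = [], []
        for label in labels:
            vocab = pd.read_csv(
                src / f"vocab_{label}.tsv", sep="\t", keep_default_na=False
            )["word"].astype(str).tolist()
            m = sp.csr_matrix(mmread(str(src / f"counts_{label}.mtx")))
            vocabs.append(vocab)
            counts.append(m.astype(np.int64))
        doc_ids: List[str] = []
        with open(src / "manifest.jsonl") as fh:
            for line in fh:
                doc_ids.append(json.loads(line)["group_id"])
        corpus = cls(labels, vocabs, counts, doc_ids, CorpusMode(meta["mode"]))
        # mmread of an all-zero column can shrink shape; re-assert
        for t, vocab in enumerate(vocabs):
            m = corpus.counts[t]
            if m.shape != (len(doc_ids), len(vocab)):
                corpus.counts[t] = sp.csr_matrix(m, shape=(len(doc_ids), len(vocab)))
        return corpus


def group_into_documents(streams: TokenStreams) -> TypedCorpus:
    """Aggregate tokenised notes into one document per group identifier.

    All notes sharing a ``group_id`` are summed into one document, each note
    type into its own count slice; a group missing a type simply has zero
    counts there.  Documents left empty by the vocabulary filter are dropped
    with a warning.
    """
    labels = streams.type_labels
    word_index = {t: {w: i for i, w in enumerate(streams.vocab[t])} for t in labels}

    agg: Dict[str, Dict[str, Counter]] = defaultdict(lambda: {t: Counter() for t in labels})
    order: List[str] = []
    for note in streams.notes:
        if note.group_id not in agg:
            order.append(note.group_id)
        agg[note.group_id][note.note_type].update(note.counts)

    doc_ids = [g for g in order if any(agg[g][t] for t in labels)]
    n_dropped = len(order) - len(doc_ids)
    if n_dropped:
        logger.warning("dropping %d documents with no retained tokens", n_dropped)

    matrices = []
    for t in labels:
        rows, cols, vals = [], [], []
        for j, gid in enumerate(doc_ids):
            for word, c in agg[gid][t].items():
                rows.append(j)
                cols.append(word_index[t][word])
                vals.append(c)
        matrices.append(
            sp.csr_matrix(
                (vals, (rows, cols)),
                shape=(len(doc_ids), len(streams.vocab[t])),
                dtype=np.int64,
            )
        )
    return TypedCorpus(list(labels), [list(streams.vocab[t]) for t in labels],
                       matrices, doc_ids)


def _escape_word(word: str) -> str:
    # a literal hyphen in the original word is doubled so that the
    # "<type>-<word>" composite stays unambiguous
    return word.replace("-", "--")


def build_corpus_variant(corpus: TypedCorpus, mode: CorpusMode | str) -> TypedCorpus:
    """Re-represent a corpus in one of the three type-handling modes.

    Total token count is invariant across modes.  With a single input type
    all three modes return an identical copy.
    """
    mode = CorpusMode(mode)
    if mode is CorpusMode.MULTI_TYPE or corpus.num_types == 1:
        out = TypedCorpus(
            list(corpus.type_labels),
            [list(v) for v in corpus.vocabs],
            [m.copy() for m in corpus.counts],
            list(corpus.doc_ids),
            mode,
        )
        return out

    if mode is CorpusMode.SINGLE_SAME_WORD:
        merged = sorted(set().union(*[set(v) for v in corpus.vocabs]))
        index = {w: i for i, w in enumerate(merged)}
        total = sp.csr_matrix((corpus.num_docs, len(merged)), dtype=np.int64)
        for vocab, m in zip(corpus.vocabs, corpus.counts):
            cols = np.array([index[w] for w in vocab], dtype=np.int64)
            proj = sp.csr_matrix(
                (np.ones(len(vocab), dtype=np.int64), (np.arange(len(vocab)), cols)),
                shape=(len(vocab), len(merged)),
            )
            total = total + m @ proj
        return TypedCorpus(["all"], [merged], [sp.csr_matrix(total)],
                           list(corpus.doc_ids), mode)

    # SINGLE_DIFF_WORD: each (type, word) pair becomes its own entry
    vocab = [
        f"{label}-{_escape_word(w)}"
        for label, words in zip(corpus.type_labels, corpus.vocabs)
        for w in words
    ]
    stacked = sp.hstack([m for m in corpus.counts], format="csr").astype(np.int64)
    return TypedCorpus(["all"], [vocab], [stacked], list(corpus.doc_ids), mode)


def read_raw_notes(path: str | Path) -> List[RawNote]:
    """Read raw notes from JSONL with fields group_id, note_type, text."""
    notes = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            try:
                notes.append(RawNote(str(rec["group_id"]), str(rec["note_type"]),
                                     str(rec["text"])))
            except KeyError as exc:
                raise ValueError(f"line {i + 1}: missing field {exc}") from exc
    return notes


def read_outcomes(path: str | Path) -> pd.Series:
    """Read per-document outcomes from a two-column TSV (group_id, label)."""
    df = pd.read_csv(path, sep="\t", dtype={"group_id": str})
    if "group_id" not in df.columns or "label" not in df.columns:
        raise ValueError("outcome TSV must have columns 'group_id' and 'label'")
    return df.set_index("group_id")["label"]
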