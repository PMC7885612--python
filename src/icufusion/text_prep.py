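"""Clinical-note text preparation.

Notes are segmented into named sections on "HEADER:" boundaries (History of
Present Illness, Past Medical History, Allergies, ...), tokenized into
lowercased word tokens with stop-word flags, and flattened into one padded
token sequence per stay.  History notes of chronic patients come first —
they are the initial information of the text stream — followed by the
observation-window notes in chart-time order.  Section spans survive the
flattening so attention mass can later be aggregated per section.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .ingest import NoteBundle
from .resources import section_lexicon, stop_words

PAD_ID = 0
UNK_ID = 1
OTHER_SECTION = "OTHER"

_WORD_RE = re.compile(r"[a-z0-9]+")


@dataclass(frozen=True)
class NoteSection:
    """A half-open token span [start, end) belonging to one named section."""

    name: str
    start: int
    end: int


@dataclass
class TokenSequence:
    """A fixed-length padded token sequence with section annotations."""

    ids: np.ndarray                    # (max_len,) int64, PAD_ID beyond content
    tokens: list[str]                  # the content_length surface tokens
    content_length: int
    stopword_mask: np.ndarray          # (max_len,) bool; True = stop word
    sections: list[NoteSection]

    @property
    def max_len(self) -> int:
        return int(self.ids.shape[0])

    def content_mask(self) -> np.ndarray:
        mask = np.zeros(self.max_len, dtype=bool)
        mask[: self.content_length] = True
        return mask


@lru_cache(maxsize=1)
def _header_re() -> re.Pattern:
    surfaces = sorted(section_lexicon().keys(), key=len, reverse=True)
    alt = "|".join(re.escape(s) for s in surfaces)
    return re.compile(rf"(?<![A-Za-z])({alt})\s*:", re.IGNORECASE)


def segment_sections(text: str) -> list[tuple[str, tuple[int, int]]]:
    """Partition ``text`` into contiguous (section_name, char_span) pieces.

    Every character lands in exactly one span; text before the first header
    (or all of it, if headerless) is the catch-all "OTHER" section.
    """
    lex = section_lexicon()
    matches = list(_header_re().finditer(text))
    spans: list[tuple[str, tuple[int, int]]] = []
    if not matches:
        return [(OTHER_SECTION, (0, len(text)))] if text else []
    if matches[0].start() > 0:
        spans.append((OTHER_SECTION, (0, matches[0].start())))
    for i, m in enumerate(matches):
        end = matches[i + 1].start() if i + 1 < len(matches) else len(text)
        spans.append((lex[m.group(1).lower()], (m.start(), end)))
    return spans


def tokenize(text: str) -> tuple[list[str], list[bool]]:
    """Lowercased alphanumeric word tokens plus per-token stop-word flags."""
    sw = stop_words()
    tokens = _WORD_RE.findall(text.lower())
    return tokens, [t in sw for t in tokens]


class Vocabulary:
    """Token-to-id map with reserved pad (0) and unknown (1) ids."""

    def __init__(self, tokens: list[str]):
        self.itos = ["<pad>", "<unk>", *tokens]
        self.stoi = {t: i for i, t in enumerate(self.itos)}

    def __len__(self) -> int:
        return len(self.itos)

    def __contains__(self, token: str) -> bool:
        return token in self.stoi

    @classmethod
    def build(cls, documents: "list[list[str]]", min_count: int = 1) -> "Vocabulary":
        counts: dict[str, int] = {}
        for doc in documents:
            for tok in doc:
                counts[tok] = counts.get(tok, 0) + 1
        kept = [t for t, c in counts.items() if c >= min_count]
        kept.sort(key=lambda t: (-counts[t], t))  # frequency order, ties lexical
        return cls(kept)

    def encode(self, tokens: list[str]) -> np.ndarray:
        return np.array([self.stoi.get(t, UNK_ID) for t in tokens], dtype=np.int64)

    def to_dict(self) -> dict:
        return {"tokens": self.itos[2:]}

    @classmethod
    def from_dict(cls, d: dict) -> "Vocabulary":
        return cls(list(d["tokens"]))


def flatten_bundle(bundle: NoteBundle) -> tuple[list[str], list[bool], list[NoteSection]]:
    """Segment+tokenize every note of a bundle into one token stream.

    History notes precede window notes; within each group the chart-time
    order from the bundle is kept.  Empty sections are dropped, so the
    returned spans partition [0, len(tokens)) exactly.
    """
    tokens: list[str] = []
    flags: list[bool] = []
    sections: list[NoteSection] = []
    for note in [*bundle.history_notes, *bundle.window_notes]:
        for name, (lo, hi) in segment_sections(note.text):
            toks, fl = tokenize(note.text[lo:hi])
            if not toks:
                continue
            start = len(tokens)
            tokens.extend(toks)
            flags.extend(fl)
            sections.append(NoteSection(name, start, start + len(toks)))
    return tokens, flags, sections


def pad_or_truncate(
    tokens: list[str],
    max_len: int,
    stop_flags: list[bool] | None = None,
    sections: list[NoteSection] | None = None,
    vocab: Vocabulary | None = None,
    side: str = "head",
) -> TokenSequence:
    """Fit a token stream to exactly ``max_len`` positions.

    Overflow keeps the head of the stream by default (preserving the
    history-first prefix) or the tail when ``side='tail'``; shortfall is
    zero-padded.  Section spans are shifted/clipped to [0, content_length).
    """
    if max_len <= 0:
        raise ValueError("max_len must be positive")
    stop_flags = stop_flags if stop_flags is not None else [False] * len(tokens)
    sections = sections if sections is not None else (
        [NoteSection(OTHER_SECTION, 0, len(tokens))] if tokens else [])

    offset = 0
    if len(tokens) > max_len:
        if side == "head":
            tokens, stop_flags = tokens[:max_len], stop_flags[:max_len]
        else:
            offset = len(tokens) - max_len
            tokens, stop_flags = tokens[offset:], stop_flags[offset:]
    n = len(tokens)

    clipped: list[NoteSection] = []
    for s in sections:
        lo = min(max(s.start - offset, 0), n)
        hi = min(max(s.end - offset, 0), n)
        if hi > lo:
            clipped.append(NoteSection(s.name, lo, hi))

    ids = np.full(max_len, PAD_ID, dtype=np.int64)
    if n:
        ids[:n] = vocab.encode(tokens) if vocab is not None else UNK_ID
    mask = np.zeros(max_len, dtype=bool)
    mask[:n] = stop_flags
    return TokenSequence(ids=ids, tokens=tokens, content_length=n,
                         stopword_mask=mask, sections=clipped)


def assemble_bundle_text(
    bundle: NoteBundle,
    vocab: Vocabulary | None = None,
    max_len: int = 1000,
    side: str = "head",
) -> TokenSequence:
    """Full note pipeline for one stay: flatten -> segment -> tokenize -> pad."""
    tokens, flags, sections = flatten_bundle(bundle)
    return pad_or_truncate(tokens, max_len, flags, sections, vocab, side)
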