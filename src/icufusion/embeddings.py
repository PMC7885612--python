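"""Word-embedding I/O in the word2vec *text* format.

Format: a header line ``"<vocab_size> <dim>"`` followed by one line per word,
``"word v1 v2 ... vdim"``.  Pretrained biomedical vectors (e.g. trained on
PubMed) can be loaded here; by default the model trains embeddings from
scratch on the corpus.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .text_prep import Vocabulary


def load_word2vec_text(path: str | Path) -> tuple[list[str], np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"embedding file not found: {path}")
    with open(path) as f:
        header = f.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: malformed word2vec header {header!r}")
        n, dim = int(header[0]), int(header[1])
        words: list[str] = []
        vecs = np.zeros((n, dim))
        for i in range(n):
            parts = f.readline().rstrip("\n").split(" ")
            if len(parts) != dim + 1:
                raise ValueError(f"{path}: line {i + 2} has {len(parts) - 1} values, expected {dim}")
            words.append(parts[0])
            vecs[i] = [float(x) for x in parts[1:]]
    return words, vecs


def save_word2vec_text(path: str | Path, words: list[str], vectors: np.ndarray) -> None:
    vectors = np.asarray(vectors)
    with open(path, "w") as f:
        f.write(f"{len(words)} {vectors.shape[1]}\n")
        for w, v in zip(words, vectors):
            f.write(w + " " + " ".join(f"{x:.6f}" for x in v) + "\n")


def build_embedding_matrix(
    vocab: Vocabulary,
    word_to_vec: dict[str, np.ndarray],
    dim: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Initial embedding table: pretrained rows where known, small random
    noise otherwise; pad row zero."""
    mat = rng.normal(0.0, 0.1, size=(len(vocab), dim))
    mat[0] = 0.0
    hits = 0
    for tok, i in vocab.stoi.items():
        v = word_to_vec.get(tok)
        if v is not None and i >= 2:
            if len(v) != dim:
                raise ValueError(f"embedding dim mismatch for {tok!r}: {len(v)} != {dim}")
            mat[i] = v
            hits += 1
    return mat
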