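"""Word-vector and frequency-norm I/O, and reference-vocabulary construction.

Word vectors are read from the plain-text word2vec dialect (``.vec``): an
optional ``<n> <d>`` header followed by one line per word, the token and then
*d* decimal numbers.  Frequency norms (e.g. subtitle-corpus counts such as
SUBTLEX) come as delimited tables.  The reference vocabulary for neighborhood
computation is the restriction of the embedding space to the top-N most
frequent words that actually have vectors.

Word matching is exact string match after Unicode NFC normalization; there is
no case folding or diacritic stripping (orthography is meaningful), but a
``lowercase`` switch is available on the readers.
"""

from __future__ import annotations

import logging
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EmbeddingSpace",
    "FrequencyList",
    "EmbeddingFormatError",
    "read_word2vec_text",
    "write_word2vec_text",
    "read_frequency_list",
    "build_reference_vocabulary",
]


class EmbeddingFormatError(ValueError):
    """Raised when a vector or frequency file violates its format contract."""


def _nfc(word: str, lowercase: bool = False) -> str:
    w = unicodedata.normalize("NFC", word)
    return w.lower() if lowercase else w


@dataclass
class EmbeddingSpace:
    """An ordered vocabulary with one fixed-dimension real vector per word.

    Parameters
    ----------
    words
        Vocabulary in file (or construction) order; unique.
    vectors
        Array of shape ``(len(words), d)``, float64, all entries finite.
    """

    words: list[str]
    vectors: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.words):
            raise ValueError(
                f"vectors shape {self.vectors.shape} does not match "
                f"{len(self.words)} words"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("embedding vectors contain non-finite entries")
        self._index = {}
        for i, w in enumerate(self.words):
            if w in self._index:
                raise EmbeddingFormatError(f"duplicate word in vocabulary: {w!r}")
            self._index[w] = i

    @property
    def d(self) -> int:
        """Vector dimension."""
        return int(self.vectors.shape[1])

    def __len__(self) -> int:
        return len(self.words)

    def __contains__(self, word: str) -> bool:
        return _nfc(word) in self._index

    def vector(self, word: str) -> np.ndarray:
        """Return the vector for ``word`` (NFC-normalized exact match).

        Raises ``KeyError`` for out-of-vocabulary words: a text ``.vec`` file,
        unlike a full subword model, cannot synthesize vectors for unseen
        strings, so lookups must fail loudly rather than guess.
        """
        key = _nfc(word)
        try:
            return self.vectors[self._index[key]]
        except KeyError:
            raise KeyError(f"word not in embedding vocabulary: {word!r}") from None

    def subset(self, words: Iterable[str]) -> "EmbeddingSpace":
        """Restrict to ``words`` (which must all be present), keeping their order."""
        ws = [_nfc(w) for w in words]
        idx = [self._index[w] for w in ws]
        return EmbeddingSpace(ws, self.vectors[idx])


@dataclass
class FrequencyList:
    """(word, frequency) pairs ordered by descending frequency.

    Ties are broken lexicographically (ascending) so the ordering — and hence
    any top-N reference vocabulary cut from it — is reproducible.
    """

    words: list[str]
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=np.float64)
        if len(self.words) != len(self.frequencies):
            raise ValueError("words and frequencies length mismatch")
        if np.any(self.frequencies < 0):
            raise ValueError("negative frequency")
        order = np.lexsort((np.asarray(self.words, dtype=object), -self.frequencies))
        self.words = [self.words[i] for i in order]
        self.frequencies = self.frequencies[order]

    def __len__(self) -> int:
        return len(self.words)

    def top(self, n: int) -> list[str]:
        return self.words[:n]


def read_word2vec_text(path: str | Path, lowercase: bool = False) -> EmbeddingSpace:
    """Read a word2vec text-format vector file, with or without header.

    The header, if present, is a first line with exactly two integer tokens
    ``<n> <d>``; both are checked against the content.
    """
    path = Path(path)
    words: list[str] = []
    seen: set[str] = set()
    rows: list[np.ndarray] = []
    expected_n = expected_d = None
    d = None
    with path.open("r", encoding="utf-8") as fh:
        first = fh.readline()
        if not first:
            raise EmbeddingFormatError(f"{path}: empty file")
        toks = first.rstrip("\n").split()
        if len(toks) == 2:
            try:
                expected_n, expected_d = int(toks[0]), int(toks[1])
            except ValueError:
                expected_n = expected_d = None
        if expected_n is None:
            _parse_vec_line(first, 1, words, seen, rows, d, path, lowercase)
            d = rows[0].size
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            _parse_vec_line(line, lineno, words, seen, rows, d, path, lowercase)
            if d is None:
                d = rows[0].size
                if expected_d is not None and d != expected_d:
                    raise EmbeddingFormatError(
                        f"{path}: header declares d={expected_d} but line "
                        f"{lineno} has {d} values"
                    )
    if not rows:
        raise EmbeddingFormatError(f"{path}: no vector rows")
    if expected_n is not None and len(rows) != expected_n:
        raise EmbeddingFormatError(
            f"{path}: header declares n={expected_n} but file has {len(rows)} rows"
        )
    space = EmbeddingSpace(words, np.vstack(rows))
    logger.info("read %d vectors of dimension %d from %s", len(space), space.d, path)
    return space


def _parse_vec_line(
    line: str,
    lineno: int,
    words: list[str],
    seen: set[str],
    rows: list[np.ndarray],
    d: int | None,
    path: Path,
    lowercase: bool,
) -> None:
    toks = line.rstrip("\n").split()
    if len(toks) < 2:
        raise EmbeddingFormatError(f"{path}: line {lineno}: no vector values")
    word = _nfc(toks[0], lowercase)
    try:
        vec = np.array([float(t) for t in toks[1:]], dtype=np.float64)
    except ValueError as exc:
        raise EmbeddingFormatError(
            f"{path}: line {lineno}: non-numeric vector entry ({exc})"
        ) from None
    if d is not None and vec.size != d:
        raise EmbeddingFormatError(
            f"{path}: line {lineno}: expected {d} values, found {vec.size}"
        )
    if word in seen:
        raise EmbeddingFormatError(f"{path}: line {lineno}: duplicate word {word!r}")
    words.append(word)
    seen.add(word)
    rows.append(vec)


def write_word2vec_text(
    space: EmbeddingSpace, path: str | Path, header: bool = True, fmt: str = "%.6f"
) -> None:
    """Write ``space`` in word2vec text format (deterministic formatting)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        if header:
            fh.write(f"{len(space)} {space.d}\n")
        for w, row in zip(space.words, space.vectors):
            fh.write(w + " " + " ".join(fmt % x for x in row) + "\n")


def read_frequency_list(
    path: str | Path,
    word_column: str = "word",
    freq_column: str = "frequency",
    sep: str | None = None,
    lowercase: bool = False,
) -> FrequencyList:
    """Read a delimited frequency table into a :class:`FrequencyList`.

    ``sep=None`` auto-detects the delimiter (TSV or CSV).  Duplicate word rows
    keep the highest frequency and log a warning.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    for col in (word_column, freq_column):
        if col not in df.columns:
            raise KeyError(
                f"{path}: column {col!r} not found (have {list(df.columns)})"
            )
    if df.empty:
        return FrequencyList([], np.empty(0))
    words = df[word_column].astype(str).map(lambda w: _nfc(w, lowercase))
    freqs = pd.to_numeric(df[freq_column])
    tbl = pd.DataFrame({"word": words, "freq": freqs})
    n_dup = int(tbl["word"].duplicated().sum())
    if n_dup:
        logger.warning("%s: %d duplicate word rows; keeping highest frequency", path, n_dup)
        tbl = tbl.groupby("word", as_index=False)["freq"].max()
    logger.info("read %d frequency entries from %s", len(tbl), path)
    return FrequencyList(tbl["word"].tolist(), tbl["freq"].to_numpy())


def build_reference_vocabulary(
    freq: FrequencyList,
    space: EmbeddingSpace,
    n_top: int,
    min_size: int | None = None,
) -> EmbeddingSpace:
    """Restrict ``space`` to the ``n_top`` most frequent words that have vectors.

    Words in the top-``n_top`` slice that lack vectors are skipped and counted,
    not back-filled from lower ranks: the result keeps the literal
    "top-N most frequent" semantics and may therefore be shorter than
    ``n_top``.  ``min_size`` (typically k+1 for a downstream k-nearest-neighbor
    count) makes an undersized result an error.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    top = freq.top(n_top)
    kept = [w for w in top if w in space]
    n_skipped = len(top) - len(kept)
    if n_skipped:
        logger.info(
            "reference vocabulary: %d of top-%d words lack vectors and were skipped",
            n_skipped,
            n_top,
        )
    if min_size is not None and len(kept) < min_size:
        raise ValueError(
            f"reference vocabulary has {len(kept)} words, fewer than the "
            f"required {min_size}; neighborhood density would be undefined"
        )
    return space.subset(kept)
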