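"""Semantic neighborhood density (SNeigh) from cosine similarities.

For each target word, SNeigh is the arithmetic mean of the cosine
similarities between the target's vector and its k closest neighbors
(default k = 5) within a frequency-defined reference vocabulary, excluding
the target word itself.  A higher value means a denser semantic
neighborhood; in lexical decision, words from denser neighborhoods tend to
be recognized faster.

The search is exhaustive (the reference is ~20,000 words, comfortably
enumerable) and fully deterministic: neighbors are ranked by cosine
descending with lexicographic tie-break on the word string.  Self-exclusion
is by exact string identity only — a *different* word whose vector happens
to coincide with the target's is a legitimate neighbor with cosine 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .embedding_io import EmbeddingSpace

__all__ = ["SNeighConfig", "cosine", "semantic_neighborhood_density", "compute_density_table"]


@dataclass(frozen=True)
class SNeighConfig:
    """Neighborhood-density parameters.

    k
        Number of nearest neighbors averaged (study value 5).
    n_top
        Size of the frequency-defined reference vocabulary (study value
        20,000); must exceed k.
    """

    k: int = 5
    n_top: int = 20_000

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.n_top <= self.k:
            raise ValueError("n_top must exceed k")


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two vectors, clamped to [-1, 1]."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity undefined for zero-norm vector")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


def _neighbor_search(
    target: str,
    target_vec: np.ndarray,
    ref_words: np.ndarray,
    ref_unit: np.ndarray,
    k: int,
) -> tuple[float, list[tuple[str, float]]]:
    """Top-k cosine neighbors of ``target_vec`` among pre-normalized reference rows."""
    t = np.asarray(target_vec, dtype=np.float64)
    nt = np.linalg.norm(t)
    if nt == 0.0:
        raise ValueError(f"zero-norm vector for target {target!r}")
    cos = np.clip(ref_unit @ (t / nt), -1.0, 1.0)
    eligible = ref_words != target
    if int(eligible.sum()) < k:
        raise ValueError(
            f"only {int(eligible.sum())} eligible reference words for "
            f"{target!r}; need at least k={k}"
        )
    words = ref_words[eligible]
    cos = cos[eligible]
    # primary key: cosine descending; secondary: word ascending (reproducible ties)
    order = np.lexsort((words, -cos))[:k]
    neighbors = [(str(words[i]), float(cos[i])) for i in order]
    sneigh = float(np.mean([c for _, c in neighbors]))
    return sneigh, neighbors


def semantic_neighborhood_density(
    target: str,
    target_vec: np.ndarray,
    reference: EmbeddingSpace,
    cfg: SNeighConfig = SNeighConfig(),
) -> tuple[float, list[tuple[str, float]]]:
    """SNeigh of one word: mean cosine to its k closest reference neighbors.

    Returns ``(sneigh, neighbors)`` where ``neighbors`` is the k
    ``(word, cosine)`` pairs in non-increasing cosine order.  The target
    itself (exact string match) is excluded from the candidate set; an error
    is raised if fewer than k eligible reference words remain.
    """
    ref_words = np.asarray(reference.words, dtype=object)
    norms = np.linalg.norm(reference.vectors, axis=1)
    if np.any(norms == 0.0):
        bad = [reference.words[i] for i in np.nonzero(norms == 0.0)[0][:5]]
        raise ValueError(f"zero-norm reference vectors (e.g. {bad})")
    ref_unit = reference.vectors / norms[:, None]
    return _neighbor_search(target, np.asarray(target_vec), ref_words, ref_unit, cfg.k)


def compute_density_table(
    stimuli: list[str],
    space: EmbeddingSpace,
    reference: EmbeddingSpace,
    cfg: SNeighConfig = SNeighConfig(),
) -> pd.DataFrame:
    """SNeigh for every stimulus word, as a tidy table.

    ``space`` supplies the stimulus vectors (stimuli are looked up in the full
    embedding file, independently of whether they fall inside the reference
    set); ``reference`` supplies the neighbor candidates.  Output columns:
    ``word``, ``sneigh``, then ``neighbor_i`` / ``cosine_i`` for i = 1..k.

    All unresolvable stimuli are reported in a single error.
    """
    missing = [w for w in stimuli if w not in space]
    if missing:
        raise KeyError(
            f"{len(missing)} stimulus words have no vector: {sorted(missing)}"
        )
    ref_words = np.asarray(reference.words, dtype=object)
    norms = np.linalg.norm(reference.vectors, axis=1)
    if np.any(norms == 0.0):
        raise ValueError("zero-norm reference vectors")
    ref_unit = reference.vectors / norms[:, None]

    rows = []
    for w in stimuli:
        sneigh, neighbors = _neighbor_search(w, space.vector(w), ref_words, ref_unit, cfg.k)
        row: dict[str, object] = {"word": w, "sneigh": sneigh}
        for i, (nw, nc) in enumerate(neighbors, start=1):
            row[f"neighbor_{i}"] = nw
            row[f"cosine_{i}"] = nc
        rows.append(row)
    return pd.DataFrame(rows)
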