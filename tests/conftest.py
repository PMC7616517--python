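from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from semdense.embedding_io import EmbeddingSpace
from semdense.synthetic import (
    DesignConfig,
    EmbeddingSimConfig,
    GenerativeConfig,
    simulate_study,
)


def random_space(rng: np.random.Generator, n: int, d: int) -> EmbeddingSpace:
    words = [f"t{i:03d}" for i in range(n)]
    return EmbeddingSpace(words, rng.normal(size=(n, d)))


@pytest.fixture(scope="session")
def small_study():
    """A small but fully structured simulated experiment (shared, read-only)."""
    cfg = GenerativeConfig(
        embedding=EmbeddingSimConfig(n_words=300, dim=16, n_clusters=6),
        design=DesignConfig(n_participants_per_group=6, n_words_per_type=8),
        seed=42,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def small_model_data(small_study):
    from semdense.preprocessing import clean_pipeline

    cleaned, _ = clean_pipeline(small_study.trials)
    return cleaned.merge(
        small_study.density[["word", "sneigh"]], left_on="stimulus", right_on="word"
    ).drop(columns=["word"])


@pytest.fixture(scope="session")
def small_fit(small_model_data):
    from semdense.lmm import fit_lmm

    return fit_lmm(small_model_data, with_emmeans=True)


def build_cascade_fixture() -> tuple[pd.DataFrame, dict]:
    """Hand-constructed trial table whose cleaning outcome is known exactly.

    Design (all arithmetic verifiable by hand):

    * 6 EB + 6 SC participants; 12 words (4 per type, one of them ``w_bad``)
      and 6 pseudowords, one presentation each -> 18 trials per participant.
    * Every participant errs on ``w_bad``.  EB1-5 err on one pseudoword each
      (error rate 2/18); EB6 errs on all 6 pseudowords plus words w01, w02
      (rate 9/18): the leave-one-out rule excludes exactly EB6 (others'
      rates are identical, SD 0, cutoff 2/18).  SC participants each also
      err on one distinct word w01..w06 (rate 2/18, identical) -> none
      excluded.
    * After EB6 is dropped, ``w_bad`` has accuracy 0 in both groups while
      every other word is well above each group's mean - 2.5 SD cutoff ->
      exactly one item excluded.
    * Of the remaining 11 x 11 = 121 word trials: 6 are inaccurate (the SC
      word errors), one accurate trial has RT 250 ms (< 300 floor), and EB2
      has a 10,000 ms outlier among otherwise constant 600 ms trials, which
      is the single trial beyond 3 SD of EB2's mean.  All other
      participants have zero RT spread, so the strict inequality keeps
      everything else.
    """
    eb = [f"EB{i}" for i in range(1, 7)]
    sc = [f"SC{i}" for i in range(1, 7)]
    words = [f"w{i:02d}" for i in range(1, 12)] + ["w_bad"]
    types = {w: ["abstract", "multimodal", "visual"][i % 3] for i, w in enumerate(words)}
    pseudos = [f"pw{i}" for i in range(1, 7)]

    rows = []
    for p in eb + sc:
        group = p[:2]
        for w in words:
            acc = 1
            if w == "w_bad":
                acc = 0
            if p == "EB6" and w in ("w01", "w02"):
                acc = 0
            if group == "SC" and w == f"w{int(p[2]):02d}":
                acc = 0  # SC_i errs on word w0i
            rt = 600.0
            if p == "EB1" and w == "w03":
                rt = 250.0  # fast-RT casualty (accurate trial)
            if p == "EB2" and w == "w05":
                rt = 10_000.0  # the single 3-SD outlier
            rows.append(
                dict(
                    participant=p,
                    group=group,
                    stimulus=w,
                    type=types[w],
                    lexicality="word",
                    presentation=1,
                    accuracy=acc,
                    rt=rt,
                    duration=700.0,
                )
            )
        for j, pw in enumerate(pseudos, start=1):
            acc = 1
            if p == "EB6":
                acc = 0
            elif group == "EB" and j == int(p[2]):
                acc = 0  # EB_i (i<=5) errs on pseudoword pw_i
            rows.append(
                dict(
                    participant=p,
                    group=group,
                    stimulus=pw,
                    type="none",
                    lexicality="pseudoword",
                    presentation=1,
                    accuracy=acc,
                    rt=800.0,
                    duration=700.0,
                )
            )
    trials = pd.DataFrame(rows)
    expected = {
        "excluded_participants": ["EB6"],
        "excluded_items": ["w_bad"],
        "n_participant_trials_removed": 18,
        "n_item_trials_removed": 11,
        "n_pseudoword_trials_dropped": 66,
        "n_inaccurate": 6,
        "n_fast": 1,
        "n_sd_trimmed": 1,
        "n_final": 113,
    }
    return trials, expected


@pytest.fixture
def cascade_fixture():
    return build_cascade_fixture()
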