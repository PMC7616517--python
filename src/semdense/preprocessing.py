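"""Trial cleaning for the auditory lexical decision data.

The cascade mirrors the study's order of operations:

1. participant exclusion — within each group, drop participants whose error
   rate over *all* trials (words and pseudowords) is more than 2.5 SD above
   the mean error rate of the *other* participants in the same group
   (leave-one-out, one-sided high);
2. item exclusion — drop word stimuli whose accuracy is more than 2.5 SD
   below the mean item accuracy in *both* groups separately;
3. trial filters on word trials only, in order: incorrect responses, RTs
   faster than 300 ms, then per-participant trimming of RTs beyond ±3 SD of
   that participant's mean (computed on the trials surviving the first two
   steps, on the raw millisecond scale);
4. natural-log transforms of RT and stimulus duration.

Each step reports counts and percentages; because published percentages can
be computed against different denominators, the report carries the
per-step remaining count, the word-trial total, and the all-trial total.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "REQUIRED_COLUMNS",
    "CleaningReport",
    "validate_trials",
    "exclude_participants_by_accuracy",
    "exclude_items_by_accuracy",
    "filter_trials",
    "log_transforms",
    "clean_pipeline",
]

REQUIRED_COLUMNS = (
    "participant",
    "group",
    "stimulus",
    "type",
    "lexicality",
    "presentation",
    "accuracy",
    "rt",
    "duration",
)

GROUPS = ("EB", "SC")
WORD_TYPES = ("abstract", "multimodal", "visual")


@dataclass
class CleaningReport:
    """Bookkeeping for one or more cleaning steps; JSON-serializable."""

    excluded_participants: list[dict] = field(default_factory=list)
    excluded_items: list[dict] = field(default_factory=list)
    steps: list[dict] = field(default_factory=list)
    n_all_trials_in: int = 0
    n_word_trials_in: int = 0

    def add_step(self, name: str, n_before: int, n_removed: int) -> None:
        self.steps.append(
            {
                "step": name,
                "n_before": int(n_before),
                "n_removed": int(n_removed),
                "n_after": int(n_before - n_removed),
                "pct_of_remaining": 100.0 * n_removed / n_before if n_before else 0.0,
                "pct_of_word_trials": (
                    100.0 * n_removed / self.n_word_trials_in
                    if self.n_word_trials_in
                    else 0.0
                ),
                "pct_of_all_trials": (
                    100.0 * n_removed / self.n_all_trials_in
                    if self.n_all_trials_in
                    else 0.0
                ),
            }
        )

    def step(self, name: str) -> dict:
        for s in self.steps:
            if s["step"] == name:
                return s
        raise KeyError(name)

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(asdict(self), indent=indent)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    def merged_with(self, other: "CleaningReport") -> "CleaningReport":
        return CleaningReport(
            excluded_participants=self.excluded_participants + other.excluded_participants,
            excluded_items=self.excluded_items + other.excluded_items,
            steps=self.steps + other.steps,
            n_all_trials_in=self.n_all_trials_in or other.n_all_trials_in,
            n_word_trials_in=self.n_word_trials_in or other.n_word_trials_in,
        )


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Check the trial-table contract; returns the (unmodified) table."""
    missing = [c for c in REQUIRED_COLUMNS if c not in trials.columns]
    if missing:
        raise KeyError(f"trial table missing columns: {missing}")
    if not trials["group"].isin(GROUPS).all():
        bad = sorted(set(trials["group"]) - set(GROUPS))
        raise ValueError(f"unknown group labels: {bad}")
    if not trials["lexicality"].isin(("word", "pseudoword")).all():
        raise ValueError("lexicality must be 'word' or 'pseudoword'")
    word_rows = trials[trials["lexicality"] == "word"]
    if not word_rows["type"].isin(WORD_TYPES).all():
        bad = sorted(set(word_rows["type"]) - set(WORD_TYPES))
        raise ValueError(f"unknown word types: {bad}")
    if not trials["accuracy"].isin((0, 1)).all():
        raise ValueError("accuracy must be coded 0/1")
    if (trials["rt"] <= 0).any():
        raise ValueError("non-positive RT")
    if (trials["duration"] <= 0).any():
        raise ValueError("non-positive stimulus duration")
    dup = trials.duplicated(["participant", "stimulus", "presentation"])
    if dup.any():
        raise ValueError(
            f"{int(dup.sum())} duplicate (participant, stimulus, presentation) rows"
        )
    return trials


def exclude_participants_by_accuracy(
    trials: pd.DataFrame, threshold_sd: float = 2.5
) -> tuple[pd.DataFrame, CleaningReport]:
    """Leave-one-out accuracy screening of participants within each group.

    A participant is excluded when their error rate over all their trials
    exceeds ``mean + threshold_sd * SD`` of the error rates of the *other*
    same-group participants (sample SD).  Groups need at least 3 participants
    for the SD to be meaningful.
    """
    report = CleaningReport(
        n_all_trials_in=len(trials),
        n_word_trials_in=int((trials["lexicality"] == "word").sum()),
    )
    err = 1.0 - trials.groupby("participant", observed=True)["accuracy"].mean()
    groups = trials.drop_duplicates("participant").set_index("participant")["group"]
    excluded: list[str] = []
    for g, members in groups.groupby(groups):
        parts = list(members.index)
        if len(parts) < 3:
            raise ValueError(
                f"group {g!r} has {len(parts)} participants; need >= 3 for "
                "leave-one-out SD screening"
            )
        for p in parts:
            others = err[[q for q in parts if q != p]]
            mu, sd = float(others.mean()), float(others.std(ddof=1))
            cutoff = mu + threshold_sd * sd
            if err[p] > cutoff:
                excluded.append(p)
                report.excluded_participants.append(
                    {
                        "participant": p,
                        "group": g,
                        "error_rate": float(err[p]),
                        "others_mean": mu,
                        "others_sd": sd,
                        "cutoff": cutoff,
                    }
                )
    out = trials[~trials["participant"].isin(excluded)].copy()
    report.add_step("participant_exclusion", len(trials), len(trials) - len(out))
    if excluded:
        logger.info("excluded participants: %s", excluded)
    return out, report


def exclude_items_by_accuracy(
    trials: pd.DataFrame,
    threshold_sd: float = 2.5,
    rule: Literal["both", "either"] = "both",
) -> tuple[pd.DataFrame, CleaningReport]:
    """Accuracy screening of word items, judged within each group.

    An item's accuracy is computed per group over word trials; the item is
    flagged in a group when its accuracy falls below
    ``mean - threshold_sd * SD`` of that group's item accuracies.  With the
    default ``rule="both"`` an item must be flagged in *both* groups to be
    excluded ("either" is a documented alternative).  Pseudoword trials are
    untouched.
    """
    report = CleaningReport(
        n_all_trials_in=len(trials),
        n_word_trials_in=int((trials["lexicality"] == "word").sum()),
    )
    words = trials[trials["lexicality"] == "word"]
    acc = (
        words.groupby(["group", "stimulus"], observed=True)["accuracy"]
        .mean()
        .unstack(level="group")
    )
    flagged_per_group = {}
    for g in acc.columns:
        col = acc[g].dropna()
        cutoff = float(col.mean() - threshold_sd * col.std(ddof=1))
        flagged_per_group[g] = set(col.index[col < cutoff])
    sets = list(flagged_per_group.values())
    excluded = set.intersection(*sets) if rule == "both" else set.union(*sets)
    for w in sorted(excluded):
        report.excluded_items.append(
            {
                "stimulus": w,
                "accuracy_by_group": {g: float(acc.loc[w, g]) for g in acc.columns},
            }
        )
    mask = (trials["lexicality"] == "word") & trials["stimulus"].isin(excluded)
    out = trials[~mask].copy()
    report.add_step("item_exclusion", len(trials), int(mask.sum()))
    if excluded:
        logger.info("excluded items: %s", sorted(excluded))
    return out, report


def filter_trials(
    trials: pd.DataFrame,
    rt_floor: float = 300.0,
    sd_window: float = 3.0,
) -> tuple[pd.DataFrame, CleaningReport]:
    """Word-trial filters, applied sequentially.

    (1) drop incorrect trials; (2) drop RT < ``rt_floor`` ms; (3) within each
    participant, drop trials with ``|rt - mean| > sd_window * SD`` where mean
    and SD are that participant's statistics over the trials surviving steps
    1-2 (raw millisecond scale; strict inequality, so an SD of zero removes
    nothing).  Participants left with fewer than 2 trials before step 3 are
    skipped by the SD filter with a warning.  Pseudoword trials are dropped
    here: the model analyses word trials only.
    """
    report = CleaningReport(
        n_all_trials_in=len(trials),
        n_word_trials_in=int((trials["lexicality"] == "word").sum()),
    )
    words = trials[trials["lexicality"] == "word"].copy()
    report.add_step("restrict_to_words", len(trials), len(trials) - len(words))

    correct = words[words["accuracy"] == 1]
    report.add_step("inaccurate", len(words), len(words) - len(correct))

    fast_ok = correct[correct["rt"] >= rt_floor]
    report.add_step("fast_rt", len(correct), len(correct) - len(fast_ok))

    keep = np.ones(len(fast_ok), dtype=bool)
    rt = fast_ok["rt"].to_numpy()
    for p, idx in fast_ok.groupby("participant", observed=True).indices.items():
        if len(idx) < 2:
            logger.warning(
                "participant %s has %d trials before SD trimming; skipped", p, len(idx)
            )
            continue
        mu = rt[idx].mean()
        sd = rt[idx].std(ddof=1)
        keep[idx] &= np.abs(rt[idx] - mu) <= sd_window * sd
    out = fast_ok[keep].copy()
    report.add_step("sd_trim", len(fast_ok), int((~keep).sum()))
    return out, report


def log_transforms(trials: pd.DataFrame) -> pd.DataFrame:
    """Add natural-log RT and duration columns (``log_rt``, ``log_duration``).

    Originals are preserved; applying the transform twice is rejected so a
    pipeline cannot silently double-log.
    """
    for col in ("log_rt", "log_duration"):
        if col in trials.columns:
            raise ValueError(f"column {col!r} already present; refusing to re-log")
    if (trials["rt"] <= 0).any() or (trials["duration"] <= 0).any():
        raise ValueError("log transform requires positive rt and duration")
    out = trials.copy()
    out["log_rt"] = np.log(out["rt"])
    out["log_duration"] = np.log(out["duration"])
    return out


def clean_pipeline(
    trials: pd.DataFrame,
    participant_sd: float = 2.5,
    item_sd: float = 2.5,
    rt_floor: float = 300.0,
    sd_window: float = 3.0,
    item_rule: Literal["both", "either"] = "both",
) -> tuple[pd.DataFrame, CleaningReport]:
    """Full cascade: participants -> items -> trial filters -> log transforms."""
    validate_trials(trials)
    t1, r1 = exclude_participants_by_accuracy(trials, participant_sd)
    t2, r2 = exclude_items_by_accuracy(t1, item_sd, rule=item_rule)
    t3, r3 = filter_trials(t2, rt_floor=rt_floor, sd_window=sd_window)
    out = log_transforms(t3)
    report = r1.merged_with(r2).merged_with(r3)
    return out, report
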