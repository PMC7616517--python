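import math

import numpy as np
import pandas as pd
import pytest

from semdense.preprocessing import (
    clean_pipeline,
    exclude_items_by_accuracy,
    exclude_participants_by_accuracy,
    filter_trials,
    log_transforms,
    validate_trials,
)

from _oracles import loo_high_outliers


def make_trials(
    participants,
    words,
    accuracy=None,
    rt=600.0,
    lexicality="word",
    group_of=None,
):
    """Minimal well-formed trial table: one presentation per (participant, word)."""
    rows = []
    types = ["abstract", "multimodal", "visual"]
    for p in participants:
        for j, w in enumerate(words):
            rows.append(
                dict(
                    participant=p,
                    group=(group_of(p) if group_of else ("EB" if p.startswith("EB") else "SC")),
                    stimulus=w,
                    type=types[j % 3] if lexicality == "word" else "none",
                    lexicality=lexicality,
                    presentation=1,
                    accuracy=1 if accuracy is None else accuracy(p, w),
                    rt=rt if np.isscalar(rt) else rt(p, w),
                    duration=650.0,
                )
            )
    return pd.DataFrame(rows)


class TestParticipantExclusion:
    def test_zero_spread_excludes_nobody(self):
        parts = [f"EB{i}" for i in range(4)] + [f"SC{i}" for i in range(4)]
        trials = make_trials(parts, [f"w{i}" for i in range(10)])
        out, report = exclude_participants_by_accuracy(trials)
        assert len(out) == len(trials)
        assert report.excluded_participants == []

    def test_gross_outlier_excluded_and_matches_loo_oracle(self):
        parts = [f"EB{i:02d}" for i in range(21)]
        words = [f"w{i:02d}" for i in range(50)]
        rng = np.random.default_rng(3)
        # ~2% error for everyone, 50% for EB00
        errs = {
            p: set(rng.choice(50, size=25 if p == "EB00" else 1, replace=False))
            for p in parts
        }
        trials = make_trials(
            parts + ["SC1", "SC2", "SC3"],
            words,
            accuracy=lambda p, w: 0 if int(w[1:]) in errs.get(p, set()) else 1,
        )
        out, report = exclude_participants_by_accuracy(trials)
        excluded = [e["participant"] for e in report.excluded_participants]
        rates = {p: len(errs[p]) / 50 for p in parts}
        assert excluded == loo_high_outliers(rates)
        assert "EB00" in excluded
        assert set(out["participant"]) == set(trials["participant"]) - set(excluded)

    def test_small_group_is_an_error(self):
        trials = make_trials(["EB1", "EB2", "SC1", "SC2", "SC3"], ["w1", "w2"])
        with pytest.raises(ValueError, match=">= 3"):
            exclude_participants_by_accuracy(trials)

    def test_error_rate_uses_all_trials_including_pseudowords(self):
        parts = ["EB1", "EB2", "EB3", "EB4", "SC1", "SC2", "SC3"]
        words = make_trials(parts, [f"w{i}" for i in range(6)])
        # EB4's errors live exclusively on pseudoword trials
        pseudos = make_trials(
            parts,
            [f"pw{i}" for i in range(6)],
            lexicality="pseudoword",
            accuracy=lambda p, w: 0 if p == "EB4" else 1,
        )
        trials = pd.concat([words, pseudos], ignore_index=True)
        _, report = exclude_participants_by_accuracy(trials)
        assert [e["participant"] for e in report.excluded_participants] == ["EB4"]


class TestItemExclusion:
    def test_equal_accuracy_excludes_nothing(self):
        parts = ["EB1", "EB2", "EB3", "SC1", "SC2", "SC3"]
        trials = make_trials(parts, [f"w{i}" for i in range(8)])
        out, report = exclude_items_by_accuracy(trials)
        assert report.excluded_items == []
        assert len(out) == len(trials)

    def test_chance_item_in_both_groups_excluded(self):
        parts = [f"EB{i}" for i in range(6)] + [f"SC{i}" for i in range(6)]
        words = [f"w{i:02d}" for i in range(20)]
        trials = make_trials(
            parts, words, accuracy=lambda p, w: 0 if w == "w07" else 1
        )
        out, report = exclude_items_by_accuracy(trials)
        assert [e["stimulus"] for e in report.excluded_items] == ["w07"]
        assert "w07" not in set(out["stimulus"])

    def test_and_rule_keeps_item_bad_in_one_group_only(self):
        parts = [f"EB{i}" for i in range(6)] + [f"SC{i}" for i in range(6)]
        words = [f"w{i:02d}" for i in range(20)]
        trials = make_trials(
            parts,
            words,
            accuracy=lambda p, w: 0 if (w == "w07" and p.startswith("EB")) else 1,
        )
        _, report_and = exclude_items_by_accuracy(trials, rule="both")
        assert report_and.excluded_items == []
        _, report_or = exclude_items_by_accuracy(trials, rule="either")
        assert [e["stimulus"] for e in report_or.excluded_items] == ["w07"]


class TestTrialFilters:
    def test_constant_rt_degenerate_sd_removes_nothing(self):
        parts = ["EB1", "EB2", "SC1"]
        trials = make_trials(parts, [f"w{i}" for i in range(20)], rt=500.0)
        out, report = filter_trials(trials)
        assert len(out) == len(trials)
        assert report.step("sd_trim")["n_removed"] == 0

    def test_single_outlier_removed_at_sd_step(self):
        rng = np.random.default_rng(12)
        words = [f"w{i:02d}" for i in range(20)]
        jitter = {w: float(rng.normal(600, 20)) for w in words}
        jitter["w13"] = 5000.0
        trials = make_trials(["EB1"], words, rt=lambda p, w: jitter[w])
        out, report = filter_trials(trials)
        assert report.step("sd_trim")["n_removed"] == 1
        assert 5000.0 not in set(out["rt"])
        # oracle: mean/SD over the 20 surviving-step-2 trials
        vals = np.array(list(jitter.values()))
        assert abs(5000 - vals.mean()) > 3 * vals.std(ddof=1)

    def test_fast_floor_and_accuracy_steps_in_order(self):
        words = [f"w{i}" for i in range(10)]
        trials = make_trials(
            ["EB1", "SC1"],
            words,
            accuracy=lambda p, w: 0 if w == "w0" else 1,
            rt=lambda p, w: 100.0 if w == "w1" else 600.0,
        )
        out, report = filter_trials(trials)
        assert report.step("inaccurate")["n_removed"] == 2
        assert report.step("fast_rt")["n_removed"] == 2
        # percentages use the pre-step remaining denominator
        assert report.step("inaccurate")["pct_of_remaining"] == pytest.approx(10.0)
        assert report.step("fast_rt")["pct_of_remaining"] == pytest.approx(100 * 2 / 18)

    def test_pseudowords_dropped_before_filters(self):
        words = make_trials(["EB1", "SC1"], ["w1", "w2"])
        pseudos = make_trials(["EB1", "SC1"], ["pw1"], lexicality="pseudoword")
        out, report = filter_trials(pd.concat([words, pseudos], ignore_index=True))
        assert set(out["lexicality"]) == {"word"}
        assert report.step("restrict_to_words")["n_removed"] == 2


class TestLogTransforms:
    def test_known_values(self):
        trials = make_trials(["EB1"], ["w1", "w2"])
        trials.loc[0, "rt"] = 1.0
        trials.loc[1, "rt"] = math.e * 1000
        out = log_transforms(trials)
        assert out.loc[0, "log_rt"] == pytest.approx(0.0)
        assert out.loc[1, "log_rt"] == pytest.approx(7.907755278982137, abs=1e-12)
        assert out.loc[0, "log_duration"] == pytest.approx(math.log(650.0))
        assert {"rt", "duration"} <= set(out.columns)  # originals preserved

    def test_double_application_rejected(self):
        out = log_transforms(make_trials(["EB1"], ["w1"]))
        with pytest.raises(ValueError, match="already present"):
            log_transforms(out)

    def test_nonpositive_rt_rejected(self):
        trials = make_trials(["EB1"], ["w1"])
        trials["rt"] = -5.0
        with pytest.raises(ValueError):
            log_transforms(trials)


class TestCascade:
    def test_frozen_fixture_counts_match_hand_computation(self, cascade_fixture):
        trials, expected = cascade_fixture
        validate_trials(trials)
        cleaned, report = clean_pipeline(trials)
        assert [e["participant"] for e in report.excluded_participants] == (
            expected["excluded_participants"]
        )
        assert [e["stimulus"] for e in report.excluded_items] == expected["excluded_items"]
        assert report.step("participant_exclusion")["n_removed"] == (
            expected["n_participant_trials_removed"]
        )
        assert report.step("item_exclusion")["n_removed"] == expected["n_item_trials_removed"]
        assert report.step("restrict_to_words")["n_removed"] == (
            expected["n_pseudoword_trials_dropped"]
        )
        assert report.step("inaccurate")["n_removed"] == expected["n_inaccurate"]
        assert report.step("fast_rt")["n_removed"] == expected["n_fast"]
        assert report.step("sd_trim")["n_removed"] == expected["n_sd_trimmed"]
        assert len(cleaned) == expected["n_final"]

    def test_cleaning_never_increases_rows_and_counts_are_consistent(self, cascade_fixture):
        trials, _ = cascade_fixture
        cleaned, report = clean_pipeline(trials)
        assert len(cleaned) <= len(trials)
        for step in report.steps:
            assert step["n_after"] == step["n_before"] - step["n_removed"]
            assert step["n_removed"] >= 0
        # chained bookkeeping reproduces the final size
        assert report.steps[-1]["n_after"] == len(cleaned)

    def test_duplicate_trial_rows_rejected(self):
        trials = make_trials(["EB1", "EB2", "EB3", "SC1", "SC2", "SC3"], ["w1"])
        dup = pd.concat([trials, trials.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            validate_trials(dup)
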