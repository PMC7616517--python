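import io
import math

import numpy as np
import pandas as pd
import pytest

from semdense.embedding_io import write_word2vec_text
from semdense.preprocessing import clean_pipeline
from semdense.sneigh import SNeighConfig, compute_density_table
from semdense.synthetic import (
    DesignConfig,
    EmbeddingSimConfig,
    ErrorModelConfig,
    GenerativeConfig,
    RTModelConfig,
    calibrate_residual_sd,
    generate_embedding_space,
    generate_stimuli,
    generate_trials,
    generative_fixed_effects,
    simulate_study,
)


def small_cfg(**kw):
    base = dict(
        embedding=EmbeddingSimConfig(n_words=200, dim=12, n_clusters=4),
        design=DesignConfig(n_participants_per_group=4, n_words_per_type=5),
        sneigh=SNeighConfig(k=5, n_top=200),
        seed=1,
    )
    base.update(kw)
    return GenerativeConfig(**base)


class TestEmbeddingGeneration:
    def test_same_seed_gives_byte_identical_vec_output(self, tmp_path):
        cfg = small_cfg()
        for name in ("a.vec", "b.vec"):
            space, _ = generate_embedding_space(cfg)
            write_word2vec_text(space, tmp_path / name)
        assert (tmp_path / "a.vec").read_bytes() == (tmp_path / "b.vec").read_bytes()

    def test_tight_clusters_are_denser_than_loose_ones(self):
        cfg = small_cfg(
            embedding=EmbeddingSimConfig(
                n_words=200, dim=12, n_clusters=2, cluster_spreads=(0.01, 1.0)
            )
        )
        space, _ = generate_embedding_space(cfg)
        density = compute_density_table(
            space.words, space, space, SNeighConfig(k=5, n_top=200)
        )
        cluster = np.arange(200) % 2  # round-robin assignment
        tight = density.loc[cluster == 0, "sneigh"].mean()
        loose = density.loc[cluster == 1, "sneigh"].mean()
        assert tight > loose

    def test_minimal_space_still_defines_density_everywhere(self):
        cfg = small_cfg(
            embedding=EmbeddingSimConfig(n_words=6, dim=3, n_clusters=1),
            sneigh=SNeighConfig(k=5, n_top=6),
        )
        space, _ = generate_embedding_space(cfg)
        density = compute_density_table(space.words, space, space, cfg.sneigh)
        assert len(density) == 6
        assert density["sneigh"].notna().all()

    def test_frequency_list_is_zipf_like_and_complete(self):
        space, freq = generate_embedding_space(small_cfg())
        assert set(freq.words) == set(space.words)
        assert (np.diff(freq.frequencies) <= 0).all()

    def test_degenerate_configs_rejected(self):
        with pytest.raises(ValueError, match="dim"):
            EmbeddingSimConfig(n_words=10, dim=1, n_clusters=2).validate()
        with pytest.raises(ValueError, match="n_words"):
            EmbeddingSimConfig(n_words=3, dim=4, n_clusters=3).validate()


@pytest.fixture(scope="module")
def study_parts():
    cfg = small_cfg()
    space, freq = generate_embedding_space(cfg)
    stimuli = generate_stimuli(cfg, space)
    density = compute_density_table(stimuli["word"].tolist(), space, space, cfg.sneigh)
    return cfg, stimuli, density


class TestTrialGeneration:
    def test_noise_free_limit_is_recomputable_by_hand(self, study_parts):
        cfg, stimuli, density = study_parts
        quiet = GenerativeConfig(
            embedding=cfg.embedding,
            design=cfg.design,
            rt_model=RTModelConfig(
                participant_intercept_sd=0.0,
                participant_slope_sd=0.0,
                intercept_slope_corr=0.0,
                stimulus_intercept_sd=0.0,
                residual_sd=0.0,
            ),
            error_model=ErrorModelConfig(p_error=0.0, include_pseudowords=False),
            sneigh=cfg.sneigh,
            seed=cfg.seed,
        )
        trials = generate_trials(quiet, density, stimuli)
        m = quiet.rt_model
        merged = trials.merge(density[["word", "sneigh"]], left_on="stimulus", right_on="word")
        g_eff = np.where(merged["group"] == "EB", m.group_effect, -m.group_effect)
        slope = np.where(merged["group"] == "EB", m.slope_eb, m.slope_sc)
        expected = (
            m.intercept
            + g_eff
            + slope * merged["sneigh"]
            + merged["type"].map(m.type_effects)
            + m.duration_slope * np.log(merged["duration"])
        )
        np.testing.assert_allclose(np.log(merged["rt"]), expected, atol=1e-12)

    def test_zero_error_probability_means_all_correct(self, study_parts):
        cfg, stimuli, density = study_parts
        cfg0 = small_cfg(error_model=ErrorModelConfig(p_error=0.0, pseudoword_p_error=0.0))
        trials = generate_trials(cfg0, density, stimuli)
        assert (trials["accuracy"] == 1).all()

    def test_mean_log_rt_matches_linear_predictor(self, study_parts):
        # fixed covariates: many participants with all random SDs at zero,
        # so only residual noise remains; the mean over ~1e5 trials must sit
        # on the linear predictor within Monte-Carlo error
        cfg, stimuli, density = study_parts
        big = GenerativeConfig(
            embedding=cfg.embedding,
            design=DesignConfig(n_participants_per_group=250, n_words_per_type=5),
            rt_model=RTModelConfig(
                participant_intercept_sd=0.0,
                participant_slope_sd=0.0,
                intercept_slope_corr=0.0,
                stimulus_intercept_sd=0.0,
                residual_sd=0.15,
            ),
            error_model=ErrorModelConfig(include_pseudowords=False),
            sneigh=cfg.sneigh,
            seed=3,
        )
        trials = generate_trials(big, density, stimuli)
        one = trials[(trials["stimulus"] == stimuli["word"].iloc[0]) & (trials["group"] == "EB")]
        m = big.rt_model
        s = float(density.set_index("word").loc[stimuli["word"].iloc[0], "sneigh"])
        pred = (
            m.intercept
            + m.group_effect
            + m.slope_eb * s
            + m.type_effects[stimuli["type"].iloc[0]]
            + m.duration_slope * math.log(stimuli["duration"].iloc[0])
        )
        mc_se = 0.15 / math.sqrt(len(one))
        assert np.log(one["rt"]).mean() == pytest.approx(pred, abs=4 * mc_se)

    def test_determinism_and_seed_sensitivity(self, study_parts):
        cfg, stimuli, density = study_parts
        a = generate_trials(cfg, density, stimuli, seed=5)
        b = generate_trials(cfg, density, stimuli, seed=5)
        c = generate_trials(cfg, density, stimuli, seed=6)
        pd.testing.assert_frame_equal(a, b)
        assert not np.allclose(a["rt"], c["rt"])

    def test_error_rate_within_binomial_band(self, study_parts):
        cfg, stimuli, density = study_parts
        big = small_cfg(design=DesignConfig(n_participants_per_group=100, n_words_per_type=5))
        trials = generate_trials(big, density, stimuli, seed=11)
        words = trials[trials["lexicality"] == "word"]
        p = 0.0175
        n = len(words)
        rate = 1.0 - words["accuracy"].mean()
        assert abs(rate - p) < 4 * math.sqrt(p * (1 - p) / n)

    def test_cleaning_removes_about_the_configured_error_fraction(self, study_parts):
        cfg, stimuli, density = study_parts
        big = small_cfg(design=DesignConfig(n_participants_per_group=30, n_words_per_type=5))
        trials = generate_trials(big, density, stimuli, seed=13)
        _, report = clean_pipeline(trials)
        frac = report.step("inaccurate")["pct_of_remaining"] / 100
        n = report.step("inaccurate")["n_before"]
        assert abs(frac - 0.0175) < 4 * math.sqrt(0.0175 * 0.9825 / n)


class TestCalibration:
    def test_residual_sd_hits_target_conditional_r2(self):
        cfg = small_cfg()
        space, _ = generate_embedding_space(cfg)
        stimuli = generate_stimuli(cfg, space)
        density = compute_density_table(stimuli["word"].tolist(), space, space, cfg.sneigh)
        sd = calibrate_residual_sd(cfg, density, stimuli)
        # plug-in check: with Ve = Vf + Vr the ratio (Vf+Vr)/(Vf+Vr+Ve) = 1/2
        m = cfg.rt_model
        tbl = stimuli.merge(density[["word", "sneigh"]], on="word")
        preds = []
        for group, g_eff, slope in (("EB", m.group_effect, m.slope_eb), ("SC", -m.group_effect, m.slope_sc)):
            preds.append(
                m.intercept
                + g_eff
                + slope * tbl["sneigh"].to_numpy()
                + tbl["type"].map(m.type_effects).to_numpy(dtype=float)
                + m.duration_slope * np.log(tbl["duration"].to_numpy())
            )
        var_f = float(np.var(np.concatenate(preds)))
        s = np.tile(tbl["sneigh"].to_numpy(), 2)
        cov = m.intercept_slope_corr * m.participant_intercept_sd * m.participant_slope_sd
        var_r = m.stimulus_intercept_sd**2 + float(
            np.mean(m.participant_intercept_sd**2 + 2 * cov * s + m.participant_slope_sd**2 * s**2)
        )
        implied = (var_f + var_r) / (var_f + var_r + sd**2)
        assert implied == pytest.approx(0.50, abs=1e-12)

    def test_generative_fixed_effects_are_sum_coded(self):
        eff = generative_fixed_effects(small_cfg())
        m = small_cfg().rt_model
        assert eff["sneigh"] == pytest.approx((m.slope_eb + m.slope_sc) / 2)
        assert eff["group1:sneigh"] == pytest.approx((m.slope_eb - m.slope_sc) / 2)
        assert eff["type1"] + eff["type2"] + (-eff["type1"] - eff["type2"]) == 0

    def test_config_round_trips_through_dict(self):
        cfg = small_cfg()
        assert GenerativeConfig.from_dict(cfg.to_dict()) == cfg


class TestSimulatedStudy:
    def test_full_study_is_deterministic_end_to_end(self):
        a = simulate_study(small_cfg())
        b = simulate_study(small_cfg())
        pd.testing.assert_frame_equal(a.trials, b.trials)
        pd.testing.assert_frame_equal(a.density, b.density)
        assert a.residual_sd == b.residual_sd

    def test_study_shapes_match_design(self):
        study = simulate_study(small_cfg())
        d = study.config.design
        n_words = 3 * d.n_words_per_type
        n_parts = 2 * d.n_participants_per_group
        words = study.trials[study.trials["lexicality"] == "word"]
        assert len(words) == n_parts * n_words * d.presentations
        assert study.trials["participant"].nunique() == n_parts
        assert len(study.density) == n_words
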