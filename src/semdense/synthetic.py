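"""Generative counterpart of the analysis: synthetic embeddings and trials.

The generator exists so that every stage of the pipeline — density
computation, cleaning, model fitting — can be exercised and validated
without downloading corpus vectors or behavioral data.  It emulates:

* an embedding space of Gaussian word clusters whose per-cluster spread
  differs, so k-nearest-neighbor density varies systematically across words
  (tight clusters -> high SNeigh), plus a Zipf-like frequency list that is
  independent of cluster structure;
* the study's trial design — two groups of participants, three word types,
  each word stimulus presented twice, log-normal audio durations — with log
  reaction times drawn from exactly the linear mixed model the analysis
  fits: fixed group, per-group SNeigh slopes, type and log-duration
  effects; correlated participant intercept/slope, stimulus intercept, and
  residual noise; plus a Bernoulli error model for accuracy flags and an
  optional pseudoword block so the cleaning denominators are realistic.

Default parameters are the study's published estimates where those exist
(slopes -0.37 EB / -0.25 SC; duration slope 0.25; participant intercept SD
0.13, slope SD 0.11, correlation -0.50; stimulus intercept SD 0.06; trial
error rate 1.75%; 21 participants per group, 40 words per type, 2
presentations).  The residual SD is not published; by default it is
calibrated so the implied conditional R² is 0.50, matching the reported
model fit.  Everything is deterministic given (config, seed).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .embedding_io import EmbeddingSpace, FrequencyList, build_reference_vocabulary
from .sneigh import SNeighConfig, compute_density_table

logger = logging.getLogger(__name__)

__all__ = [
    "EmbeddingSimConfig",
    "DesignConfig",
    "RTModelConfig",
    "ErrorModelConfig",
    "GenerativeConfig",
    "SimulatedStudy",
    "generate_embedding_space",
    "generate_stimuli",
    "calibrate_residual_sd",
    "generate_trials",
    "generative_fixed_effects",
    "simulate_study",
]


@dataclass(frozen=True)
class EmbeddingSimConfig:
    """Clustered Gaussian embedding space.

    Cluster centers are standard normal in ``dim`` dimensions (norm about
    sqrt(dim)); each word is its cluster center plus isotropic noise with the
    cluster's spread, so within-cluster cosines fall with spread and k-NN
    density varies across clusters.  ``cluster_spreads=None`` uses
    ``linspace(0.2, 2.0, n_clusters)``.
    """

    n_words: int = 2000
    dim: int = 50
    n_clusters: int = 10
    cluster_spreads: tuple[float, ...] | None = None
    zipf_exponent: float = 1.0

    def spreads(self) -> np.ndarray:
        if self.cluster_spreads is not None:
            s = np.asarray(self.cluster_spreads, dtype=float)
            if s.size != self.n_clusters:
                raise ValueError("cluster_spreads length must equal n_clusters")
            return s
        return np.linspace(0.2, 2.0, self.n_clusters)

    def validate(self) -> None:
        if self.dim < 2:
            raise ValueError("embedding dim must be >= 2")
        if not (self.n_words > self.n_clusters >= 1):
            raise ValueError("need n_words > n_clusters >= 1")
        if np.any(self.spreads() < 0):
            raise ValueError("cluster spreads must be non-negative")


@dataclass(frozen=True)
class DesignConfig:
    """Experimental design: who sees what, how often, and for how long."""

    n_participants_per_group: int = 21
    n_words_per_type: int = 40
    presentations: int = 2
    duration_mean_ms: float = 700.0
    duration_sdlog: float = 0.15

    def validate(self) -> None:
        if self.n_participants_per_group < 3:
            raise ValueError("need >= 3 participants per group (exclusion SD)")
        if self.n_words_per_type < 1 or self.presentations < 1:
            raise ValueError("need >= 1 word per type and >= 1 presentation")
        if self.duration_mean_ms <= 0:
            raise ValueError("durations must be positive")


@dataclass(frozen=True)
class RTModelConfig:
    """Parameters of the generative log-RT mixed model (log-ms scale).

    ``group_effect`` is the sum-coded EB deviation (SC gets its negative);
    ``type_effects`` must sum to zero.  ``residual_sd=None`` requests
    calibration to a conditional R² of ``target_conditional_r2``.
    """

    intercept: float = 7.0
    group_effect: float = -0.06
    slope_eb: float = -0.37
    slope_sc: float = -0.25
    type_effects: Mapping[str, float] = field(
        default_factory=lambda: {"abstract": 0.02, "multimodal": -0.01, "visual": -0.01}
    )
    duration_slope: float = 0.25
    participant_intercept_sd: float = 0.13
    participant_slope_sd: float = 0.11
    intercept_slope_corr: float = -0.50
    stimulus_intercept_sd: float = 0.06
    residual_sd: float | None = None
    target_conditional_r2: float = 0.50

    def validate(self) -> None:
        for name in ("participant_intercept_sd", "participant_slope_sd", "stimulus_intercept_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.residual_sd is not None and self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")
        if not -1.0 <= self.intercept_slope_corr <= 1.0:
            raise ValueError("intercept_slope_corr must lie in [-1, 1]")
        if abs(sum(self.type_effects.values())) > 1e-9:
            raise ValueError("type_effects must sum to zero (sum-coded deviations)")

    def slope(self, group: str) -> float:
        return {"EB": self.slope_eb, "SC": self.slope_sc}[group]


@dataclass(frozen=True)
class ErrorModelConfig:
    """Bernoulli trial-error model and the optional pseudoword block."""

    p_error: float = 0.0175
    include_pseudowords: bool = True
    pseudoword_intercept: float = 7.1
    pseudoword_sd: float = 0.18
    pseudoword_p_error: float = 0.0175

    def validate(self) -> None:
        for p in (self.p_error, self.pseudoword_p_error):
            if not 0.0 <= p <= 1.0:
                raise ValueError("error probabilities must lie in [0, 1]")
        if self.pseudoword_sd < 0:
            raise ValueError("pseudoword_sd must be >= 0")


@dataclass(frozen=True)
class GenerativeConfig:
    embedding: EmbeddingSimConfig = EmbeddingSimConfig()
    design: DesignConfig = DesignConfig()
    rt_model: RTModelConfig = RTModelConfig()
    error_model: ErrorModelConfig = ErrorModelConfig()
    sneigh: SNeighConfig = SNeighConfig(k=5, n_top=2000)
    seed: int = 0

    def validate(self) -> "GenerativeConfig":
        self.embedding.validate()
        self.design.validate()
        self.rt_model.validate()
        self.error_model.validate()
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["rt_model"]["type_effects"] = dict(self.rt_model.type_effects)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GenerativeConfig":
        kwargs: dict = {}
        for key, sub in (
            ("embedding", EmbeddingSimConfig),
            ("design", DesignConfig),
            ("rt_model", RTModelConfig),
            ("error_model", ErrorModelConfig),
            ("sneigh", SNeighConfig),
        ):
            if key in d:
                block = dict(d[key])
                if key == "embedding" and block.get("cluster_spreads") is not None:
                    block["cluster_spreads"] = tuple(block["cluster_spreads"])
                kwargs[key] = sub(**block)
        if "seed" in d:
            kwargs["seed"] = int(d["seed"])
        return cls(**kwargs).validate()


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), *map(int, stream)])


def generate_embedding_space(
    cfg: GenerativeConfig,
) -> tuple[EmbeddingSpace, FrequencyList]:
    """Clustered word vectors plus a Zipf-like frequency list.

    Cluster membership is round-robin so every cluster is populated;
    frequencies follow ``1/rank^a`` over a random permutation of the
    vocabulary, making frequency independent of cluster (and hence of
    density), as in a natural lexicon where the two are only loosely linked.
    """
    cfg.validate()
    e = cfg.embedding
    rng = _rng(cfg.seed, 101)
    centers = rng.normal(0.0, 1.0, size=(e.n_clusters, e.dim))
    spreads = e.spreads()
    cluster = np.arange(e.n_words) % e.n_clusters
    noise = rng.normal(0.0, 1.0, size=(e.n_words, e.dim))
    vectors = centers[cluster] + spreads[cluster][:, None] * noise
    width = max(5, len(str(e.n_words)))
    words = [f"w{i:0{width}d}" for i in range(e.n_words)]

    perm = rng.permutation(e.n_words)
    ranks = np.empty(e.n_words, dtype=float)
    ranks[perm] = np.arange(1, e.n_words + 1)
    freqs = 1e6 / ranks**e.zipf_exponent
    space = EmbeddingSpace(words, vectors)
    return space, FrequencyList(list(words), freqs)


def generate_stimuli(cfg: GenerativeConfig, space: EmbeddingSpace) -> pd.DataFrame:
    """Sample the stimulus set: word, type, and audio duration (ms)."""
    cfg.validate()
    n = 3 * cfg.design.n_words_per_type
    if n > len(space):
        raise ValueError(f"need {n} stimuli but the space has {len(space)} words")
    rng = _rng(cfg.seed, 102)
    chosen = rng.choice(len(space), size=n, replace=False)
    words = [space.words[i] for i in sorted(chosen)]
    types = np.repeat(["abstract", "multimodal", "visual"], cfg.design.n_words_per_type)
    rng.shuffle(types)
    durations = rng.lognormal(
        math.log(cfg.design.duration_mean_ms), cfg.design.duration_sdlog, size=n
    )
    return pd.DataFrame({"word": words, "type": types, "duration": durations})


def _participant_frame(cfg: GenerativeConfig) -> pd.DataFrame:
    npg = cfg.design.n_participants_per_group
    ids = [f"EB{i + 1:02d}" for i in range(npg)] + [f"SC{i + 1:02d}" for i in range(npg)]
    groups = ["EB"] * npg + ["SC"] * npg
    return pd.DataFrame({"participant": ids, "group": groups})


def calibrate_residual_sd(
    cfg: GenerativeConfig, density: pd.DataFrame, stimuli: pd.DataFrame
) -> float:
    """Residual SD that makes the implied conditional R² hit its target.

    The variance-partitioning identity gives conditional R² =
    (Vf + Vr) / (Vf + Vr + Ve); solving for Ve at target R² = c yields
    Ve = (Vf + Vr)(1 - c)/c.  Vf is the variance of the fixed-effect
    predictor over the design; Vr is the stimulus-intercept variance plus
    the participant term averaged over the observed SNeigh values.
    """
    m = cfg.rt_model
    c = m.target_conditional_r2
    if not 0.0 < c < 1.0:
        raise ValueError("target_conditional_r2 must lie strictly in (0, 1)")
    tbl = stimuli.merge(density[["word", "sneigh"]], on="word", validate="one_to_one")
    preds = []
    for group in ("EB", "SC"):
        g_eff = m.group_effect if group == "EB" else -m.group_effect
        preds.append(
            m.intercept
            + g_eff
            + m.slope(group) * tbl["sneigh"].to_numpy()
            + tbl["type"].map(m.type_effects).to_numpy(dtype=float)
            + m.duration_slope * np.log(tbl["duration"].to_numpy())
        )
    var_f = float(np.var(np.concatenate(preds)))
    s = np.tile(tbl["sneigh"].to_numpy(), 2)
    cov = m.intercept_slope_corr * m.participant_intercept_sd * m.participant_slope_sd
    var_r = m.stimulus_intercept_sd**2 + float(
        np.mean(
            m.participant_intercept_sd**2 + 2 * cov * s + m.participant_slope_sd**2 * s**2
        )
    )
    var_e = (var_f + var_r) * (1.0 - c) / c
    sd = math.sqrt(var_e)
    logger.info(
        "calibrated residual SD = %.4f (Vf=%.5f, Vr=%.5f, target conditional R²=%.2f)",
        sd,
        var_f,
        var_r,
        c,
    )
    return sd


def generate_trials(
    cfg: GenerativeConfig,
    density: pd.DataFrame,
    stimuli: pd.DataFrame,
    seed: int | None = None,
    residual_sd: float | None = None,
) -> pd.DataFrame:
    """Draw a full trial table from the generative mixed model.

    log RT = intercept + group effect + slope_group·SNeigh + type effect
    + duration slope·log(duration) + participant intercept
    + participant slope·SNeigh + stimulus intercept + residual, then
    exponentiated to milliseconds.  Accuracy flags are Bernoulli errors.
    ``seed`` defaults to the config seed; ``residual_sd`` overrides the
    config (pass the calibrated value to avoid recalibrating every call).
    """
    cfg.validate()
    m = cfg.rt_model
    seed = cfg.seed if seed is None else int(seed)
    if residual_sd is None:
        residual_sd = (
            m.residual_sd
            if m.residual_sd is not None
            else calibrate_residual_sd(cfg, density, stimuli)
        )

    tbl = stimuli.merge(density[["word", "sneigh"]], on="word", how="left", validate="one_to_one")
    if tbl["sneigh"].isna().any():
        missing = tbl.loc[tbl["sneigh"].isna(), "word"].tolist()
        raise ValueError(f"density table does not cover stimuli: {missing}")
    if (tbl["duration"] <= 0).any():
        raise ValueError("non-positive stimulus duration")

    parts = _participant_frame(cfg)
    n_p, n_w, n_pres = len(parts), len(tbl), cfg.design.presentations

    rng_p = _rng(seed, 201)
    z = rng_p.normal(size=(n_p, 2))
    rho = m.intercept_slope_corr
    b0_p = m.participant_intercept_sd * z[:, 0]
    b1_p = m.participant_slope_sd * (rho * z[:, 0] + math.sqrt(max(0.0, 1 - rho**2)) * z[:, 1])
    b0_w = _rng(seed, 202).normal(0.0, m.stimulus_intercept_sd, size=n_w)

    pi = np.repeat(np.arange(n_p), n_w * n_pres)
    wi = np.tile(np.repeat(np.arange(n_w), n_pres), n_p)
    pres = np.tile(np.arange(1, n_pres + 1), n_p * n_w)

    group = parts["group"].to_numpy()[pi]
    sneigh = tbl["sneigh"].to_numpy()[wi]
    duration = tbl["duration"].to_numpy()[wi]
    g_eff = np.where(group == "EB", m.group_effect, -m.group_effect)
    slope = np.where(group == "EB", m.slope_eb, m.slope_sc)
    type_eff = tbl["type"].map(m.type_effects).to_numpy(dtype=float)[wi]

    eps = _rng(seed, 203).normal(0.0, residual_sd, size=pi.size)
    log_rt = (
        m.intercept
        + g_eff
        + slope * sneigh
        + type_eff
        + m.duration_slope * np.log(duration)
        + b0_p[pi]
        + b1_p[pi] * sneigh
        + b0_w[wi]
        + eps
    )
    accuracy = (_rng(seed, 204).random(pi.size) >= cfg.error_model.p_error).astype(int)

    trials = pd.DataFrame(
        {
            "participant": parts["participant"].to_numpy()[pi],
            "group": group,
            "stimulus": tbl["word"].to_numpy()[wi],
            "type": tbl["type"].to_numpy()[wi],
            "lexicality": "word",
            "presentation": pres,
            "accuracy": accuracy,
            "rt": np.exp(log_rt),
            "duration": duration,
        }
    )

    if cfg.error_model.include_pseudowords:
        em = cfg.error_model
        rng_pw = _rng(seed, 205)
        pw_words = [f"pw{i:04d}" for i in range(n_w)]
        pw_dur = rng_pw.lognormal(
            math.log(cfg.design.duration_mean_ms), cfg.design.duration_sdlog, size=n_w
        )
        wi_pw = np.tile(np.repeat(np.arange(n_w), n_pres), n_p)
        pi_pw = np.repeat(np.arange(n_p), n_w * n_pres)
        pres_pw = np.tile(np.arange(1, n_pres + 1), n_p * n_w)
        log_rt_pw = (
            em.pseudoword_intercept
            + b0_p[pi_pw]
            + rng_pw.normal(0.0, em.pseudoword_sd, size=pi_pw.size)
        )
        acc_pw = (rng_pw.random(pi_pw.size) >= em.pseudoword_p_error).astype(int)
        pw = pd.DataFrame(
            {
                "participant": parts["participant"].to_numpy()[pi_pw],
                "group": parts["group"].to_numpy()[pi_pw],
                "stimulus": np.asarray(pw_words, dtype=object)[wi_pw],
                "type": "none",
                "lexicality": "pseudoword",
                "presentation": pres_pw,
                "accuracy": acc_pw,
                "rt": np.exp(log_rt_pw),
                "duration": pw_dur[wi_pw],
            }
        )
        trials = pd.concat([trials, pw], ignore_index=True)

    return trials


def generative_fixed_effects(cfg: GenerativeConfig) -> pd.Series:
    """The generative values of the sum-coded fixed-effect coefficients.

    Because the fitted model family is exactly the generative one (raw,
    uncentered covariates; sum-to-zero factors with EB and abstract first),
    each fitted coefficient has a closed-form generative counterpart.
    """
    m = cfg.rt_model
    te = dict(m.type_effects)
    return pd.Series(
        {
            "(Intercept)": m.intercept,
            "group1": m.group_effect,
            "sneigh": (m.slope_eb + m.slope_sc) / 2.0,
            "type1": te["abstract"],
            "type2": te["multimodal"],
            "log_duration": m.duration_slope,
            "group1:sneigh": (m.slope_eb - m.slope_sc) / 2.0,
            "group1:type1": 0.0,
            "group1:type2": 0.0,
        },
        name="generative",
    )


@dataclass
class RecoveryReport:
    """Parameter-recovery results across simulation replicates.

    ``per_replicate`` has one row per replicate (slope estimates and SEs,
    interaction F and p, convergence flags); ``summary`` aggregates bias,
    RMSE, Monte-Carlo SE, Wald-CI coverage, and the interaction rejection
    rate at ``alpha``.
    """

    per_replicate: pd.DataFrame
    summary: dict
    config: dict
    n_replicates: int
    seed: int

    def to_json(self, path=None, indent: int = 2) -> str:
        import json

        payload = {
            "summary": self.summary,
            "config": self.config,
            "n_replicates": self.n_replicates,
            "seed": self.seed,
            "per_replicate": self.per_replicate.to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=indent)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text


def recovery_experiment(
    cfg: GenerativeConfig,
    n_replicates: int,
    seed: int = 0,
    clean: bool = True,
    alpha: float = 0.05,
    spec=None,
) -> RecoveryReport:
    """Simulate, clean, and refit ``n_replicates`` experiments; summarize recovery.

    The embedding space, stimuli, and densities are generated once (they are
    design constants); trials are redrawn per replicate.  All replicates are
    fitted in a single R session.  Non-convergent or errored replicates are
    recorded, not fatal; summary statistics use the replicates that produced
    estimates.
    """
    from . import lmm as _lmm
    from .preprocessing import clean_pipeline, log_transforms

    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    cfg = replace(cfg, seed=int(seed)).validate()
    spec = spec or _lmm.ModelSpec()

    space, freq = generate_embedding_space(cfg)
    reference = build_reference_vocabulary(freq, space, cfg.sneigh.n_top, min_size=cfg.sneigh.k + 1)
    stimuli = generate_stimuli(cfg, space)
    density = compute_density_table(stimuli["word"].tolist(), space, reference, cfg.sneigh)
    residual_sd = (
        cfg.rt_model.residual_sd
        if cfg.rt_model.residual_sd is not None
        else calibrate_residual_sd(cfg, density, stimuli)
    )

    chunks = []
    for rep in range(n_replicates):
        trials = generate_trials(cfg, density, stimuli, seed=_rep_seed(seed, rep), residual_sd=residual_sd)
        if clean:
            cleaned, _ = clean_pipeline(trials)
        else:
            cleaned = log_transforms(trials[trials["lexicality"] == "word"].copy())
        merged = cleaned.merge(density[["word", "sneigh"]], left_on="stimulus", right_on="word")
        merged = merged.drop(columns=["word"])
        merged["replicate"] = rep
        chunks.append(merged)
    big = pd.concat(chunks, ignore_index=True)

    fits = _lmm.fit_lmm_many(big, spec, replicate_col="replicate")

    gen = generative_fixed_effects(cfg)
    rows = []
    for rep, fit in enumerate(fits):
        if isinstance(fit, dict):
            rows.append({"replicate": rep, "error": fit.get("error", "unknown")})
            continue
        slopes = _lmm.simple_slopes(fit)
        inter = fit.anova.loc["group:sneigh"]
        row = {
            "replicate": rep,
            "slope_eb": float(slopes.loc["EB", "b"]),
            "slope_eb_se": float(slopes.loc["EB", "se"]),
            "slope_sc": float(slopes.loc["SC", "b"]),
            "slope_sc_se": float(slopes.loc["SC", "se"]),
            "interaction_f": float(inter["f_value"]),
            "interaction_den_df": float(inter["den_df"]),
            "interaction_p": float(inter["p_value"]),
            "singular": bool(fit.singular),
            "converged": bool(fit.converged),
        }
        for name in gen.index:
            if name in fit.coef.index:
                row[f"coef_{name}"] = float(fit.coef[name])
                row[f"se_{name}"] = float(fit.se[name])
        rows.append(row)
    per_rep = pd.DataFrame(rows)

    ok = per_rep[per_rep.get("slope_eb").notna()] if "slope_eb" in per_rep else per_rep.iloc[0:0]
    zcrit = 1.959963984540054
    summary: dict = {
        "n_replicates": n_replicates,
        "n_estimated": int(len(ok)),
        "n_errors": int(n_replicates - len(ok)),
        "n_singular": int(ok["singular"].sum()) if len(ok) else 0,
        "n_converged": int(ok["converged"].sum()) if len(ok) else 0,
        "alpha": alpha,
    }
    for key, true_val in (("slope_eb", cfg.rt_model.slope_eb), ("slope_sc", cfg.rt_model.slope_sc)):
        est = ok[key].to_numpy() if len(ok) else np.empty(0)
        se = ok[f"{key}_se"].to_numpy() if len(ok) else np.empty(0)
        cover = (
            float(np.mean((est - zcrit * se <= true_val) & (true_val <= est + zcrit * se)))
            if len(ok)
            else float("nan")
        )
        summary[key] = {
            "generative": true_val,
            "mean": float(np.mean(est)) if len(ok) else float("nan"),
            "bias": float(np.mean(est) - true_val) if len(ok) else float("nan"),
            "rmse": float(np.sqrt(np.mean((est - true_val) ** 2))) if len(ok) else float("nan"),
            "mc_se": float(np.std(est, ddof=1) / np.sqrt(len(est))) if len(ok) > 1 else float("nan"),
            "ci95_coverage": cover,
        }
    if len(ok):
        summary["interaction_rejection_rate"] = float(np.mean(ok["interaction_p"] < alpha))
        cov_all = []
        for name in gen.index:
            c, s_ = f"coef_{name}", f"se_{name}"
            if c in ok.columns:
                inside = (ok[c] - zcrit * ok[s_] <= gen[name]) & (gen[name] <= ok[c] + zcrit * ok[s_])
                cov_all.append(float(inside.mean()))
        summary["fixed_effect_ci95_coverage"] = {
            name: cov for name, cov in zip([n for n in gen.index if f"coef_{n}" in ok.columns], cov_all)
        }
        summary["fixed_effect_ci95_coverage_mean"] = float(np.mean(cov_all)) if cov_all else float("nan")
        joint = np.ones(len(ok), dtype=bool)
        for name in gen.index:
            c, s_ = f"coef_{name}", f"se_{name}"
            if c in ok.columns:
                joint &= (
                    (ok[c] - zcrit * ok[s_] <= gen[name]) & (gen[name] <= ok[c] + zcrit * ok[s_])
                ).to_numpy()
        summary["fixed_effect_ci95_coverage_joint"] = float(joint.mean())
    return RecoveryReport(per_rep, summary, cfg.to_dict(), n_replicates, int(seed))


def _rep_seed(seed: int, rep: int) -> int:
    # distinct, reproducible per-replicate seed; stays below 2**31
    return (int(seed) * 1_000_003 + 7919 * (rep + 1)) % (2**31 - 1)


@dataclass
class SimulatedStudy:
    """Everything one simulated experiment produces."""

    config: GenerativeConfig
    space: EmbeddingSpace
    frequencies: FrequencyList
    stimuli: pd.DataFrame
    density: pd.DataFrame
    trials: pd.DataFrame
    residual_sd: float


def simulate_study(cfg: GenerativeConfig | None = None, seed: int | None = None) -> SimulatedStudy:
    """Generate embedding space, reference vocabulary, densities, and trials."""
    cfg = (cfg or GenerativeConfig()).validate()
    if seed is not None:
        cfg = replace(cfg, seed=int(seed))
    space, freq = generate_embedding_space(cfg)
    reference = build_reference_vocabulary(
        freq, space, cfg.sneigh.n_top, min_size=cfg.sneigh.k + 1
    )
    stimuli = generate_stimuli(cfg, space)
    density = compute_density_table(stimuli["word"].tolist(), space, reference, cfg.sneigh)
    residual_sd = (
        cfg.rt_model.residual_sd
        if cfg.rt_model.residual_sd is not None
        else calibrate_residual_sd(cfg, density, stimuli)
    )
    trials = generate_trials(cfg, density, stimuli, residual_sd=residual_sd)
    return SimulatedStudy(cfg, space, freq, stimuli, density, trials, residual_sd)
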