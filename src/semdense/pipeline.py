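"""End-to-end orchestration: density -> clean -> fit -> report.

Stages communicate through files (TSV/JSON) so each is independently
inspectable and resumable, and every run writes a machine-readable manifest
(input hashes, config snapshot, per-stage row counts, version, seeds,
timestamps).

The config is a YAML mapping with either a ``simulate`` block (generative
parameters; see :mod:`semdense.synthetic`) or an ``inputs`` block pointing
at real files::

    seed: 1
    out_dir: runs/demo
    simulate: {seed: 1, design: {n_participants_per_group: 21}}
    # or
    # inputs: {vectors: vecs.vec, frequencies: freq.tsv,
    #          stimuli: stimuli.tsv, trials: trials.tsv}
    sneigh: {k: 5, n_top: 20000}
    cleaning: {participant_sd: 2.5, item_sd: 2.5, rt_floor: 300, sd_window: 3}
    model: {reml: true, criticism: false}
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .embedding_io import build_reference_vocabulary, read_frequency_list, read_word2vec_text
from .lmm import ModelSpec, fit_lmm, model_criticism, posthoc_type, r2_nakagawa, simple_slopes
from .preprocessing import clean_pipeline, validate_trials
from .sneigh import SNeighConfig, compute_density_table
from .synthetic import GenerativeConfig, simulate_study

logger = logging.getLogger(__name__)

__all__ = ["PipelineError", "RunManifest", "run_all"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _pkg_version() -> str:
    from importlib.metadata import version

    try:
        return version("semdense")
    except Exception:
        return "unknown"


@dataclass
class RunManifest:
    config: dict
    seed: int | None
    version: str = field(default_factory=_pkg_version)
    started: str = ""
    finished: str = ""
    input_hashes: dict = field(default_factory=dict)
    stage_rows: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2), encoding="utf-8")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _utcnow() -> str:
    return _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds")


def run_all(config: str | Path | dict, out_dir: str | Path | None = None) -> RunManifest:
    """Execute density -> cleaning -> model on the configured inputs.

    ``config`` is a YAML path or an equivalent dict.  Returns the manifest;
    all stage outputs (density.tsv, clean_trials.tsv, cleaning_report.json,
    fit.json, manifest.json) land in the configured ``out_dir``.
    """
    if isinstance(config, (str, Path)):
        cfg_path = Path(config)
        cfg = yaml.safe_load(cfg_path.read_text(encoding="utf-8"))
    else:
        cfg = dict(config)
    out = Path(out_dir or cfg.get("out_dir", "semdense_run"))
    out.mkdir(parents=True, exist_ok=True)

    manifest = RunManifest(config=cfg, seed=cfg.get("seed"), started=_utcnow())
    sneigh_cfg = SNeighConfig(**cfg.get("sneigh", {})) if cfg.get("sneigh") else SNeighConfig()

    has_inputs = "inputs" in cfg
    has_sim = "simulate" in cfg
    if has_inputs == has_sim:
        raise PipelineError("config must contain exactly one of 'inputs' or 'simulate'")

    # ---- stage: inputs / simulation -------------------------------------
    try:
        if has_inputs:
            paths = {k: Path(v) for k, v in cfg["inputs"].items()}
            missing = [str(p) for p in paths.values() if not p.exists()]
            if missing:
                raise PipelineError(f"missing input files: {missing}")
            manifest.input_hashes = {k: _sha256(p) for k, p in paths.items()}
            space = read_word2vec_text(paths["vectors"])
            freq = read_frequency_list(paths["frequencies"])
            stimuli = pd.read_csv(paths["stimuli"], sep=None, engine="python")
            trials = pd.read_csv(paths["trials"], sep=None, engine="python")
            reference = build_reference_vocabulary(
                freq, space, sneigh_cfg.n_top, min_size=sneigh_cfg.k + 1
            )
        else:
            sim_block = dict(cfg["simulate"] or {})
            if "seed" not in sim_block and cfg.get("seed") is not None:
                sim_block["seed"] = cfg["seed"]
            if "sneigh" not in sim_block and cfg.get("sneigh"):
                sim_block["sneigh"] = cfg["sneigh"]
            gen_cfg = GenerativeConfig.from_dict(sim_block)
            study = simulate_study(gen_cfg)
            space, freq = study.space, study.frequencies
            stimuli, trials = study.stimuli, study.trials
            reference = None  # density already computed below from the study
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'inputs' failed: {exc}") from exc
    manifest.stage_rows["trials_in"] = len(trials)

    # ---- stage: density --------------------------------------------------
    try:
        if has_inputs:
            density = compute_density_table(
                stimuli["word"].astype(str).tolist(), space, reference, sneigh_cfg
            )
        else:
            density = study.density
    except Exception as exc:
        raise PipelineError(f"stage 'sneigh' failed: {exc}") from exc
    density_path = out / "density.tsv"
    density.to_csv(density_path, sep="\t", index=False)
    manifest.stage_rows["density"] = len(density)
    manifest.outputs["density"] = str(density_path)

    # ---- stage: cleaning -------------------------------------------------
    try:
        validate_trials(trials)
        cln = cfg.get("cleaning", {})
        cleaned, report = clean_pipeline(
            trials,
            participant_sd=cln.get("participant_sd", 2.5),
            item_sd=cln.get("item_sd", 2.5),
            rt_floor=cln.get("rt_floor", 300.0),
            sd_window=cln.get("sd_window", 3.0),
        )
    except Exception as exc:
        raise PipelineError(f"stage 'preprocessing' failed: {exc}") from exc
    clean_path = out / "clean_trials.tsv"
    cleaned.to_csv(clean_path, sep="\t", index=False)
    report.to_json(out / "cleaning_report.json")
    manifest.stage_rows["clean_trials"] = len(cleaned)
    manifest.outputs["clean_trials"] = str(clean_path)
    manifest.outputs["cleaning_report"] = str(out / "cleaning_report.json")

    # ---- stage: model ----------------------------------------------------
    try:
        model_cfg = cfg.get("model", {})
        spec = ModelSpec(
            reml=model_cfg.get("reml", True),
            ddf=model_cfg.get("ddf", "Satterthwaite"),
        )
        data = cleaned.merge(
            density[["word", "sneigh"]], left_on="stimulus", right_on="word"
        ).drop(columns=["word"])
        fit = fit_lmm(data, spec)
        result = fit.to_dict()
        result["simple_slopes"] = simple_slopes(fit).reset_index().to_dict(orient="records")
        result["posthoc_type"] = posthoc_type(fit).reset_index().to_dict(orient="records")
        marginal, conditional = r2_nakagawa(fit)
        result["r2"] = {"marginal": marginal, "conditional": conditional}
        if model_cfg.get("criticism", False):
            crit = model_criticism(fit, threshold_sd=model_cfg.get("criticism_sd", 2.5))
            result["criticism"] = {
                "threshold_sd": crit.threshold_sd,
                "n_removed": crit.n_removed,
                "fraction_removed": crit.fraction_removed,
                "refit": crit.refit.to_dict(),
            }
    except Exception as exc:
        raise PipelineError(f"stage 'lmm_analysis' failed: {exc}") from exc
    fit_path = out / "fit.json"
    fit_path.write_text(json.dumps(result, indent=2), encoding="utf-8")
    manifest.stage_rows["model_obs"] = int(fit.n_obs)
    manifest.outputs["fit"] = str(fit_path)

    manifest.finished = _utcnow()
    manifest.write(out / "manifest.json")
    logger.info("run complete: %s", out / "manifest.json")
    return manifest
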