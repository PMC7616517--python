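"""Crossed-random-effects model of log reaction times.

The model is the study's:

    log(RT) ~ group * sneigh + group * type + log_duration
              + (sneigh | participant) + (1 | stimulus)

i.e. fixed effects of participant group (early blind EB vs sighted control
SC), semantic neighborhood density, word type (abstract / multimodal /
visual) and log stimulus duration, with the group interactions of interest;
random intercept and correlated random SNeigh slope over participants, and a
random intercept over stimuli.  Estimation is REML with sum-to-zero factor
contrasts, and omnibus tests are Type-III F-tests with Satterthwaite
denominator degrees of freedom (Kenward-Roger available behind a flag).

Fitting is delegated to lme4/lmerTest in R through a subprocess bridge (the
reference stack for this model class); everything downstream of the fitted
coefficient vector and its covariance — group-specific SNeigh slopes,
pairwise Type contrasts on estimated marginal means, model criticism,
marginal/conditional R² — is computed here.
"""

from __future__ import annotations

import json
import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_FORMULA",
    "ModelSpec",
    "ModelFit",
    "CriticismResult",
    "RBridgeError",
    "ConvergenceError",
    "fit_lmm",
    "fit_lmm_many",
    "simple_slopes",
    "posthoc_type",
    "model_criticism",
    "r2_nakagawa",
]

DEFAULT_FORMULA = (
    "log_rt ~ group * sneigh + group * type + log_duration"
    " + (sneigh | participant) + (1 | stimulus)"
)

MODEL_COLUMNS = ("log_rt", "group", "sneigh", "type", "log_duration", "participant", "stimulus")


class RBridgeError(RuntimeError):
    """The R subprocess failed; carries its stderr."""


class ConvergenceError(RuntimeError):
    """The optimizer reported a genuine convergence failure."""


@dataclass(frozen=True)
class ModelSpec:
    """What to fit and how.

    ``coding`` selects the factor contrasts used internally; inferential
    results (Type-III F's, simple slopes) are invariant to it.  Group levels
    are ordered (EB, SC) and type levels (abstract, multimodal, visual); the
    first level is the reference under treatment coding and carries the +1
    code under sum coding.
    """

    formula: str = DEFAULT_FORMULA
    reml: bool = True
    ddf: Literal["Satterthwaite", "Kenward-Roger"] = "Satterthwaite"
    coding: Literal["sum", "treatment"] = "sum"
    group_levels: tuple[str, ...] = ("EB", "SC")
    type_levels: tuple[str, ...] = ("abstract", "multimodal", "visual")


@dataclass
class ModelFit:
    """A fitted model: estimates, tests, variance components, diagnostics."""

    spec: ModelSpec
    coef: pd.Series
    vcov: pd.DataFrame
    anova: pd.DataFrame
    varcorr: dict
    sigma: float
    n_obs: int
    n_participants: int
    n_stimuli: int
    reml_criterion: float
    singular: bool
    converged: bool
    messages: list[str] = field(default_factory=list)
    fitted: np.ndarray | None = None
    fixed_pred: np.ndarray | None = None
    data: pd.DataFrame | None = None
    contrast_tests: pd.DataFrame | None = None
    emmeans_type: pd.DataFrame | None = None

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.vcov)), index=self.coef.index, name="se")

    def residuals(self) -> np.ndarray:
        """Conditional residuals (response minus fitted incl. random effects)."""
        if self.fitted is None or self.data is None:
            raise ValueError("fit was made without return_pred; residuals unavailable")
        return self.data["log_rt"].to_numpy() - self.fitted

    def to_dict(self) -> dict:
        """Summary mirroring a regression table: fixed effects, F-table, variance components, R²."""
        out = {
            "formula": self.spec.formula,
            "fixed_effects": [
                {
                    "term": t,
                    "b": float(self.coef[t]),
                    "se": float(self.se[t]),
                    "z": float(self.coef[t] / self.se[t]),
                }
                for t in self.coef.index
            ],
            "anova": self.anova.reset_index().to_dict(orient="records"),
            "random_effects": self.varcorr,
            "n_obs": self.n_obs,
            "n_participants": self.n_participants,
            "n_stimuli": self.n_stimuli,
            "singular": self.singular,
            "converged": self.converged,
            "messages": self.messages,
        }
        if self.fixed_pred is not None and self.data is not None:
            marginal, conditional = r2_nakagawa(self)
            out["r2"] = {"marginal": marginal, "conditional": conditional}
        return out

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


@dataclass
class CriticismResult:
    """Model criticism: refit after trimming large standardized residuals."""

    original: ModelFit
    refit: ModelFit
    threshold_sd: float
    n_removed: int
    fraction_removed: float


def _r_script_path() -> Path:
    return Path(resources.files("semdense") / "r" / "fit_lmm.R")


def _check_model_columns(data: pd.DataFrame) -> None:
    missing = [c for c in MODEL_COLUMNS if c not in data.columns]
    if missing:
        raise KeyError(f"model data missing columns: {missing}")
    if data[list(MODEL_COLUMNS)].isna().any().any():
        bad = [c for c in MODEL_COLUMNS if data[c].isna().any()]
        raise ValueError(f"model data contains missing values in {bad}")


def _run_r(data: pd.DataFrame, cfg: dict) -> dict | list:
    rscript = shutil.which("Rscript")
    if rscript is None:
        raise RBridgeError("Rscript not found on PATH; the model backend requires R with lme4/lmerTest")
    with tempfile.TemporaryDirectory(prefix="semdense_lmm_") as tmp:
        tmp = Path(tmp)
        data_path = tmp / "data.csv"
        out_path = tmp / "fit.json"
        cfg = dict(cfg, data=str(data_path), out=str(out_path))
        data.to_csv(data_path, index=False)
        cfg_path = tmp / "config.json"
        cfg_path.write_text(json.dumps(cfg), encoding="utf-8")
        proc = subprocess.run(
            [rscript, "--vanilla", str(_r_script_path()), str(cfg_path)],
            capture_output=True,
            text=True,
        )
        if proc.returncode != 0 or not out_path.exists():
            raise RBridgeError(
                f"R model backend failed (exit {proc.returncode}):\n{proc.stderr[-4000:]}"
            )
        with out_path.open(encoding="utf-8") as fh:
            return json.load(fh)


def _as1d(x) -> np.ndarray:
    return np.atleast_1d(np.asarray(x))


def _parse_varcorr(vc: dict, sigma: float) -> dict:
    grp = [g for g in _as1d(vc["grp"])]
    var1 = [None if v is None else v for v in _as1d(vc["var1"])]
    var2 = [None if v is None else v for v in _as1d(vc["var2"])]
    vcv = _as1d(vc["vcov"]).astype(float)
    sdcor = _as1d(vc["sdcor"]).astype(float)
    out = {
        "stimulus_intercept_var": 0.0,
        "participant_intercept_var": 0.0,
        "participant_slope_var": 0.0,
        "intercept_slope_corr": float("nan"),
        "residual_var": float(sigma) ** 2,
        "stimulus_intercept_sd": 0.0,
        "participant_intercept_sd": 0.0,
        "participant_slope_sd": 0.0,
        "residual_sd": float(sigma),
    }
    for g, v1, v2, var, sdc in zip(grp, var1, var2, vcv, sdcor):
        if g == "stimulus" and v1 == "(Intercept)" and v2 is None:
            out["stimulus_intercept_var"] = float(var)
            out["stimulus_intercept_sd"] = float(sdc)
        elif g == "participant" and v1 == "(Intercept)" and v2 is None:
            out["participant_intercept_var"] = float(var)
            out["participant_intercept_sd"] = float(sdc)
        elif g == "participant" and v1 == "sneigh" and v2 is None:
            out["participant_slope_var"] = float(var)
            out["participant_slope_sd"] = float(sdc)
        elif g == "participant" and v2 is not None:
            out["intercept_slope_corr"] = float(sdc)
    return out


def _parse_fit(raw: dict, spec: ModelSpec, data: pd.DataFrame | None) -> ModelFit:
    names = [str(n) for n in _as1d(raw["coef_names"])]
    coef = pd.Series(_as1d(raw["coef"]).astype(float), index=names, name="b")
    vcov = pd.DataFrame(np.asarray(raw["vcov"], dtype=float), index=names, columns=names)
    an = raw["anova"]
    anova = pd.DataFrame(
        {
            "sum_sq": _as1d(an["sum_sq"]).astype(float),
            "mean_sq": _as1d(an["mean_sq"]).astype(float),
            "num_df": _as1d(an["num_df"]).astype(float),
            "den_df": _as1d(an["den_df"]).astype(float),
            "f_value": _as1d(an["f_value"]).astype(float),
            "p_value": _as1d(an["p_value"]).astype(float),
        },
        index=pd.Index([str(t) for t in _as1d(an["terms"])], name="term"),
    )
    contrast_tests = None
    if "contrasts" in raw and raw["contrasts"]:
        rows = []
        for name, r in raw["contrasts"].items():
            rows.append(
                {
                    "contrast": name,
                    "estimate": float(_as1d(r["estimate"])[0]),
                    "se": float(_as1d(r["se"])[0]),
                    "df": float(_as1d(r["df"])[0]),
                    "t_value": float(_as1d(r["t_value"])[0]),
                    "p_value": float(_as1d(r["p_value"])[0]),
                }
            )
        contrast_tests = pd.DataFrame(rows).set_index("contrast")
    emmeans_type = None
    if "emmeans_type" in raw and raw["emmeans_type"]:
        r = raw["emmeans_type"]
        emmeans_type = pd.DataFrame(
            {
                "contrast": [str(c) for c in _as1d(r["contrast"])],
                "estimate": _as1d(r["estimate"]).astype(float),
                "se": _as1d(r["se"]).astype(float),
                "z": _as1d(r["z"]).astype(float),
                "p_value": _as1d(r["p_value"]).astype(float),
            }
        ).set_index("contrast")
    return ModelFit(
        spec=spec,
        coef=coef,
        vcov=vcov,
        anova=anova,
        varcorr=_parse_varcorr(raw["varcorr"], raw["sigma"]),
        sigma=float(raw["sigma"]),
        n_obs=int(raw["n_obs"]),
        n_participants=int(raw["n_participants"]),
        n_stimuli=int(raw["n_stimuli"]),
        reml_criterion=float(raw["reml_criterion"]),
        singular=bool(raw["singular"]),
        converged=bool(raw["converged"]),
        messages=[str(m) for m in _as1d(raw.get("messages", []))] if raw.get("messages") else [],
        fitted=_as1d(raw["fitted"]).astype(float) if "fitted" in raw else None,
        fixed_pred=_as1d(raw["fixed_pred"]).astype(float) if "fixed_pred" in raw else None,
        data=data,
        contrast_tests=contrast_tests,
        emmeans_type=emmeans_type,
    )


def _sum_code(levels: Sequence[str]) -> dict[str, np.ndarray]:
    """Sum-to-zero code rows per level: level i -> indicator row, last level -> -1s."""
    n = len(levels)
    rows = {}
    for i, lev in enumerate(levels):
        if i < n - 1:
            row = np.zeros(n - 1)
            row[i] = 1.0
        else:
            row = -np.ones(n - 1)
        rows[lev] = row
    return rows


def standard_contrasts(spec: ModelSpec) -> dict[str, dict[str, float]]:
    """Named contrast vectors (coefficient-name keyed) for the quantities the
    analysis reports: per-group SNeigh slopes and pairwise Type differences
    of the estimated marginal means (averaged over groups, so group-by-type
    interaction terms cancel).  Sum coding only."""
    if spec.coding != "sum":
        raise ValueError("standard contrasts are defined for sum coding")
    g_codes = _sum_code(spec.group_levels)
    t_codes = _sum_code(spec.type_levels)
    out: dict[str, dict[str, float]] = {}
    for g, code in g_codes.items():
        c = {"sneigh": 1.0}
        for j, w in enumerate(code, start=1):
            if w != 0.0:
                c[f"group{j}:sneigh"] = float(w)
        out[f"slope_{g}"] = c
    levs = list(spec.type_levels)
    for i in range(len(levs)):
        for j in range(i + 1, len(levs)):
            a, b = levs[i], levs[j]
            diff = t_codes[a] - t_codes[b]
            c = {}
            for k, w in enumerate(diff, start=1):
                if w != 0.0:
                    c[f"type{k}"] = float(w)
            out[f"type_{a}_vs_{b}"] = c
    return out


def fit_lmm(
    data: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
    return_pred: bool = True,
    with_contrast_tests: bool = True,
    with_emmeans: bool = False,
    error_on_nonconvergence: bool = False,
) -> ModelFit:
    """Fit the mixed model by REML and return every reported statistic.

    A rank-deficient fixed design is surfaced as an error by the backend; a
    singular random-effects fit is *reported* in ``ModelFit.singular`` (and
    the message list), never silently simplified.  Set
    ``error_on_nonconvergence`` to turn genuine optimizer failures into
    exceptions.
    """
    _check_model_columns(data)
    for g in spec.group_levels:
        if g not in set(data["group"]):
            raise ValueError(f"group level {g!r} absent from data")
    cfg = {
        "formula": spec.formula,
        "reml": spec.reml,
        "ddf": spec.ddf,
        "coding": spec.coding,
        "group_levels": list(spec.group_levels),
        "type_levels": list(spec.type_levels),
        "return_pred": return_pred,
        "emmeans_type": with_emmeans,
    }
    if with_contrast_tests and spec.coding == "sum":
        cfg["contrasts"] = standard_contrasts(spec)
    raw = _run_r(data, cfg)
    fit = _parse_fit(raw, spec, data if return_pred else None)
    if error_on_nonconvergence and not fit.converged:
        raise ConvergenceError("; ".join(fit.messages) or "optimizer failure")
    return fit


def fit_lmm_many(
    data: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
    replicate_col: str = "replicate",
) -> list[ModelFit | dict]:
    """Fit one model per replicate in a single R session.

    Returns, per replicate in sorted order, either a :class:`ModelFit`
    (without fitted values, to keep transport light) or a dict
    ``{"replicate": r, "error": msg}`` when that replicate's fit errored.
    """
    if replicate_col not in data.columns:
        raise KeyError(f"no replicate column {replicate_col!r}")
    cfg = {
        "formula": spec.formula,
        "reml": spec.reml,
        "ddf": spec.ddf,
        "coding": spec.coding,
        "group_levels": list(spec.group_levels),
        "type_levels": list(spec.type_levels),
        "return_pred": False,
        "replicate_col": replicate_col,
    }
    if spec.coding == "sum":
        cfg["contrasts"] = standard_contrasts(spec)
    raw_list = _run_r(data, cfg)
    out: list[ModelFit | dict] = []
    for raw in raw_list:
        if "error" in raw:
            out.append({"replicate": raw.get("replicate"), "error": raw["error"]})
        else:
            out.append(_parse_fit(raw, spec, None))
    return out


def _contrast_test(fit: ModelFit, weights: dict[str, float]) -> tuple[float, float]:
    c = np.zeros(len(fit.coef))
    for name, w in weights.items():
        if name not in fit.coef.index:
            raise KeyError(f"coefficient {name!r} not in fit ({list(fit.coef.index)})")
        c[fit.coef.index.get_loc(name)] = w
    b = float(c @ fit.coef.to_numpy())
    var = float(c @ fit.vcov.to_numpy() @ c)
    if var <= 0 or not math.isfinite(var):
        raise ValueError("non-positive contrast variance; covariance unavailable or degenerate")
    return b, math.sqrt(var)


def simple_slopes(fit: ModelFit) -> pd.DataFrame:
    """Per-group SNeigh slope: estimate, SE, z = b/SE, and p-values.

    ``p_normal`` uses the normal approximation on z (the convention behind
    reported z statistics); ``p_t`` and ``df`` are the Satterthwaite-t
    results when the fit carried contrast tests.
    """
    if fit.spec.coding != "sum":
        raise ValueError("simple slopes require a sum-coded fit")
    rows = []
    for g in fit.spec.group_levels:
        weights = standard_contrasts(fit.spec)[f"slope_{g}"]
        b, se = _contrast_test(fit, weights)
        z = b / se
        row = {
            "group": g,
            "b": b,
            "se": se,
            "z": z,
            "p_normal": 2 * stats.norm.sf(abs(z)),
            "df": np.nan,
            "p_t": np.nan,
        }
        if fit.contrast_tests is not None and f"slope_{g}" in fit.contrast_tests.index:
            ct = fit.contrast_tests.loc[f"slope_{g}"]
            row["df"] = float(ct["df"])
            row["p_t"] = float(ct["p_value"])
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


def posthoc_type(fit: ModelFit) -> pd.DataFrame:
    """Pairwise differences among Type estimated marginal means.

    EMMs average over groups (sum coding makes the group and group-by-type
    terms drop out of the differences) at the observed covariate means, so
    each pairwise difference is a linear combination of the type
    coefficients alone.  p-values are unadjusted, as reported.
    """
    if fit.spec.coding != "sum":
        raise ValueError("post-hoc type contrasts require a sum-coded fit")
    contrasts = standard_contrasts(fit.spec)
    rows = []
    levs = list(fit.spec.type_levels)
    for i in range(len(levs)):
        for j in range(i + 1, len(levs)):
            name = f"type_{levs[i]}_vs_{levs[j]}"
            b, se = _contrast_test(fit, contrasts[name])
            z = b / se
            row = {
                "contrast": f"{levs[i]} - {levs[j]}",
                "estimate": b,
                "se": se,
                "z": z,
                "p_normal": 2 * stats.norm.sf(abs(z)),
                "df": np.nan,
                "p_t": np.nan,
            }
            if fit.contrast_tests is not None and name in fit.contrast_tests.index:
                ct = fit.contrast_tests.loc[name]
                row["df"] = float(ct["df"])
                row["p_t"] = float(ct["p_value"])
            rows.append(row)
    return pd.DataFrame(rows).set_index("contrast")


def model_criticism(
    fit: ModelFit,
    threshold_sd: float = 2.5,
    spec: ModelSpec | None = None,
) -> CriticismResult:
    """Trim observations with |standardized conditional residual| > threshold and refit.

    Standardized residuals are conditional residuals divided by the estimated
    residual SD.  The refit errors if trimming empties a group or type cell.
    """
    if fit.data is None or fit.fitted is None:
        raise ValueError("model criticism needs a fit with return_pred=True")
    spec = spec or fit.spec
    std_resid = fit.residuals() / fit.sigma
    keep = np.abs(std_resid) <= threshold_sd
    n_removed = int((~keep).sum())
    if n_removed == 0:
        return CriticismResult(fit, fit, threshold_sd, 0, 0.0)
    sub = fit.data.loc[keep].copy()
    for col, levels in (("group", spec.group_levels), ("type", spec.type_levels)):
        present = set(sub[col])
        lost = [lev for lev in levels if lev not in present]
        if lost:
            raise ValueError(f"criticism removed every observation of {col} level(s) {lost}")
    refit = fit_lmm(sub, spec, return_pred=True, with_contrast_tests=fit.contrast_tests is not None)
    return CriticismResult(fit, refit, threshold_sd, n_removed, n_removed / len(keep))


def r2_nakagawa(fit: ModelFit) -> tuple[float, float]:
    """Marginal and conditional R² for the mixed model.

    Marginal R² is the fixed-effect share of total variance; conditional R²
    adds the random-effect share.  The fixed-effect variance is the variance
    of the fixed-effect linear predictor over the data; with a random slope,
    the participant contribution is averaged over the observed covariate:
    mean over rows of ``var_int + 2*cov*sneigh + var_slope*sneigh²``.
    """
    if fit.fixed_pred is None or fit.data is None:
        raise ValueError("r2 needs a fit with return_pred=True")
    var_f = float(np.var(fit.fixed_pred))
    vc = fit.varcorr
    s = fit.data["sneigh"].to_numpy(dtype=float)
    corr = vc["intercept_slope_corr"]
    cov = (
        corr * vc["participant_intercept_sd"] * vc["participant_slope_sd"]
        if math.isfinite(corr)
        else 0.0
    )
    var_participant = float(
        np.mean(
            vc["participant_intercept_var"] + 2.0 * cov * s + vc["participant_slope_var"] * s**2
        )
    )
    var_r = vc["stimulus_intercept_var"] + var_participant
    var_e = vc["residual_var"]
    total = var_f + var_r + var_e
    if total <= 0:
        raise ValueError("zero total variance; R² undefined")
    return var_f / total, (var_f + var_r) / total
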