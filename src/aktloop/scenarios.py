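"""End-to-end computational experiments: generation, calibration, prediction,
identifiability, and reporting, with seed-pinned manifests.

Scenarios mirror the study's in-silico experiments:

* ``fig1_rapamycin_prediction`` — mTORC1 inhibition (Ki2 = 0) at 1 nM on the
  calibrated mTORC1-feedback model: percent change in peak PM-Akt
  recruitment and loss of the overshoot.
* ``fig2_akt_inhibition_prediction`` — pan-Akt inhibition
  ({Ki2a, Ki2b, Kf11a, Kf11b} = 0): fold change in recruitment and
  overshoot presence.
* ``fig2_phosphosite_loss`` — T309A (Kf6 = 0) and S474A (Kf7 = 0) traces.
* ``fig4_wortmannin_dissociation`` — PI3K inhibition (Kf3 = 0) after the
  trace plateaus: one-phase decay rate constants with vs without Akt
  inhibition.
* ``model_selection`` — calibrate competing variants and rank by global
  optimum.
* ``identifiability_survey`` — profile likelihood over all free parameters.

Overshoot presence is operationalised as (peak amplitude)/(10-min amplitude)
above basal exceeding 1.2.
"""

from __future__ import annotations

import json
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .calibration import GAConfig, rank_models
from .dataset import TimeCourseDataset, write_timecourse_table
from .fitmodel import GA_PRESETS, CalibrationResults, InsulinSignallingModel
from .models import PERTURBATIONS
from .synthetic import GeneratorConfig, default_training_bundle

__all__ = [
    "SCENARIOS",
    "OVERSHOOT_RATIO_THRESHOLD",
    "ScenarioSpec",
    "RunManifest",
    "run_prediction",
    "run_model_selection_study",
    "run_identifiability_survey",
    "run_full_pipeline",
]

OVERSHOOT_RATIO_THRESHOLD = 1.2

SCENARIOS = (
    "fig1_rapamycin_prediction",
    "fig2_akt_inhibition_prediction",
    "fig2_phosphosite_loss",
    "fig4_wortmannin_dissociation",
    "model_selection",
    "identifiability_survey",
)

_SCENARIO_PERTURBATION = {
    "fig1_rapamycin_prediction": "mtorc1_inhibition",
    "fig2_akt_inhibition_prediction": "akt_inhibition",
    "fig2_phosphosite_loss": "t309a",          # plus s474a, handled in-scenario
    "fig4_wortmannin_dissociation": "pi3k_inhibition",
    "model_selection": "none",
    "identifiability_survey": "none",
}


@dataclass(frozen=True)
class ScenarioSpec:
    """One named in-silico experiment."""

    scenario: str
    variants: tuple[int, ...] = (9,)
    dose: float = 1.0
    washout_time: float = 600.0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; expected {SCENARIOS}")
        pert = _SCENARIO_PERTURBATION[self.scenario]
        params = PERTURBATIONS[pert]
        from .models import build_model

        for v in self.variants:
            names = build_model(v).parameter_names
            missing = [p for p in params if p not in names]
            if missing:
                raise ValueError(
                    f"scenario {self.scenario!r} needs parameter(s) {missing} "
                    f"absent from variant {v}"
                )


def run_prediction(scenario: ScenarioSpec, results: CalibrationResults) -> dict:
    """Simulate control and perturbed protocols at the global optimum."""
    if results.model.variant not in scenario.variants:
        raise ValueError(
            f"ensemble variant {results.model.variant} does not match scenario "
            f"variants {scenario.variants}"
        )
    name = scenario.scenario
    if name == "fig1_rapamycin_prediction":
        m = results.peak_recruitment_change("mtorc1_inhibition", dose=scenario.dose)
        m["perturbed_overshoot_lost"] = bool(
            m["perturbed_overshoot_ratio"] < OVERSHOOT_RATIO_THRESHOLD
        )
        return m
    if name == "fig2_akt_inhibition_prediction":
        m = results.peak_recruitment_change("akt_inhibition", dose=scenario.dose)
        m["fold_change_peak"] = m["perturbed_peak"] / m["control_peak"]
        m["perturbed_overshoot_lost"] = bool(
            m["perturbed_overshoot_ratio"] < OVERSHOOT_RATIO_THRESHOLD
        )
        return m
    if name == "fig2_phosphosite_loss":
        out = {}
        for pert in ("t309a", "s474a"):
            tr = results.predict(scenario.dose, perturbation=pert)
            out[pert] = {"t": tr["_t"].tolist(), "pm_akt": tr["pm_akt"].tolist()}
            m = results.peak_recruitment_change(pert, dose=scenario.dose)
            out[f"{pert}_metrics"] = m
        return out
    if name == "fig4_wortmannin_dissociation":
        k_ctrl = results.wortmannin_dissociation_rate(
            washout_time=scenario.washout_time, akt_inhibited=False
        )
        k_akti = results.wortmannin_dissociation_rate(
            washout_time=scenario.washout_time, akt_inhibited=True
        )
        return {
            "rate_control": k_ctrl,
            "rate_akt_inhibited": k_akti,
            "rate_ratio": k_akti / k_ctrl,
            "percent_difference": 100.0 * (k_akti - k_ctrl) / k_ctrl,
        }
    raise ValueError(f"scenario {name!r} is not a prediction scenario")


def run_model_selection_study(
    data: TimeCourseDataset,
    variants: Sequence[int] = (4, 5, 6, 7, 8, 9),
    *,
    preset: str = "smoke",
    config: GAConfig | None = None,
    n_runs: int | None = None,
    seed: int = 0,
) -> dict:
    """Calibrate each variant against the shared dataset and rank them."""
    fits: dict[int, CalibrationResults] = {}
    for v in variants:
        model = InsulinSignallingModel(data, variant=v)
        fits[v] = model.fit(preset=None if config is not None else preset,
                            config=config, n_runs=n_runs, seed=seed + v)
    ranked = rank_models([r.ensemble for r in fits.values()])
    return {
        "ranking": [e.variant for e in ranked],
        "global_optima": {e.variant: e.global_optimum for e in ranked},
        "local_minima": {e.variant: e.local_minima.tolist() for e in ranked},
        "summaries": {e.variant: e.summary_stats() for e in ranked},
        "fits": fits,
        "dataset_fingerprint": data.fingerprint(),
    }


def plot_local_minima(study: dict, ax=None):
    """Box-and-whiskers of per-variant local minima (global optima marked)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    variants = study["ranking"]
    data = [study["local_minima"][v] for v in variants]
    ax.boxplot(data, tick_labels=[str(v) for v in variants], whis=(0, 100))
    ax.scatter(range(1, len(variants) + 1),
               [study["global_optima"][v] for v in variants],
               marker="_", s=200, color="C3", label="global optimum")
    ax.set_yscale("log")
    ax.set_xlabel("model variant")
    ax.set_ylabel("objective J (local minima)")
    ax.legend(fontsize=8)
    return ax


def run_identifiability_survey(results: CalibrationResults, *, n_grid: int = 6,
                               inner_maxfun: int = 60) -> dict:
    survey = results.profile(n_grid=n_grid, inner_maxfun=inner_maxfun)
    return {
        "variant": results.model.variant,
        "classes": survey.classes(),
        "n_nonidentifiable": survey.n_nonidentifiable(),
        "survey": survey,
    }


def rapamycin_prediction_study(
    *,
    seed: int = 0,
    n_outer: int = 3,
    preset: str = "reduced",
    variant: int = 1,
    generator_config: GeneratorConfig | None = None,
) -> dict:
    """The mTORC1-feedback prediction experiment at reduced optimisation scale.

    Calibrates the mTORC1-feedback variant against the default synthetic
    bundle (its generator seed is part of the study conditions) once per
    outer seed, then simulates 1 nM insulin with and without Ki2 nulled at
    each global optimum and reports the percent change in peak PM-Akt
    recruitment.  The reported value is the median over outer seeds; the
    overshoot-loss flag is a majority vote.
    """
    gen_cfg = generator_config or GeneratorConfig()
    data = default_training_bundle(gen_cfg)
    outer_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_outer)
    per_seed = []
    for s in outer_seeds:
        model = InsulinSignallingModel(data, variant=variant)
        res = model.fit(preset=preset, seed=int(s))
        m = res.peak_recruitment_change("mtorc1_inhibition", dose=1.0)
        m["seed"] = int(s)
        m["objective"] = res.objective_value
        m["overshoot_lost"] = bool(
            m["perturbed_overshoot_ratio"] < OVERSHOOT_RATIO_THRESHOLD
        )
        per_seed.append(m)
    changes = [m["peak_change_percent"] for m in per_seed]
    return {
        "per_seed": per_seed,
        "peak_change_percent_median": float(np.median(changes)),
        "peak_change_percent_all": changes,
        "overshoot_lost_majority": sum(m["overshoot_lost"] for m in per_seed) > n_outer / 2,
        "dataset_fingerprint": data.fingerprint(),
    }


@dataclass
class RunManifest:
    """Everything needed to reproduce a pipeline run bit-for-bit."""

    config: dict
    seed: int
    dataset_fingerprint: str = ""
    stages: dict = field(default_factory=dict)
    software: dict = field(default_factory=lambda: {
        "python": platform.python_version(),
    })

    def record(self, stage: str, payload: dict, elapsed_s: float) -> None:
        self.stages[stage] = {"elapsed_s": round(elapsed_s, 3), **payload}

    def to_json(self, path: str | Path | None = None) -> str:
        import aktloop

        doc = {
            "package_version": aktloop.__version__,
            "seed": self.seed,
            "config": self.config,
            "dataset_fingerprint": self.dataset_fingerprint,
            "software": self.software,
            "stages": self.stages,
        }
        text = json.dumps(doc, indent=2, default=_jsonable)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


DEFAULT_PIPELINE_CONFIG: dict = {
    "preset": "smoke",
    "variants": [1, 9],
    "prediction_variant": 1,
    "profile_variant": 9,
    "profile_n_grid": 4,
    "profile_inner_maxfun": 40,
    "generator": {},
}


def validate_pipeline_config(config: Mapping) -> dict:
    """Schema-check a pipeline configuration before any compute starts."""
    cfg = dict(DEFAULT_PIPELINE_CONFIG)
    cfg["generator"] = dict(cfg["generator"])
    for key, value in config.items():
        if key not in cfg:
            raise ValueError(f"unknown pipeline config field {key!r}")
        cfg[key] = value
    if cfg["preset"] not in GA_PRESETS:
        raise ValueError(f"config field 'preset': unknown preset {cfg['preset']!r}")
    for v in list(cfg["variants"]) + [cfg["prediction_variant"], cfg["profile_variant"]]:
        if v not in range(1, 10):
            raise ValueError(f"config field 'variants': variant id {v!r} outside 1-9")
    gen_fields = set(GeneratorConfig.__dataclass_fields__)
    for key in cfg["generator"]:
        if key not in gen_fields:
            raise ValueError(f"config field 'generator.{key}' is not a generator option")
    return cfg


def run_full_pipeline(config: Mapping | None = None, *, seed: int = 0,
                      outdir: str | Path | None = None) -> RunManifest:
    """generate -> calibrate -> predict -> profile -> report.

    All stochastic stages derive their seeds from ``seed``; re-running with
    the same config and seed reproduces every output exactly.
    """
    cfg = validate_pipeline_config(config or {})
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg, seed=seed)

    t0 = time.time()
    gen_cfg = GeneratorConfig(**{**cfg["generator"], "seed": seed})
    data = default_training_bundle(gen_cfg)
    manifest.dataset_fingerprint = data.fingerprint()
    if outdir is not None:
        write_timecourse_table(data, outdir / "training_data.csv")
    manifest.record("generate", {"n_series": data.n_series, "n_points": data.n_points,
                                 "fingerprint": data.fingerprint()}, time.time() - t0)

    t0 = time.time()
    study = run_model_selection_study(data, cfg["variants"], preset=cfg["preset"], seed=seed)
    manifest.record("calibrate", {
        "ranking": study["ranking"],
        "global_optima": {str(k): v for k, v in study["global_optima"].items()},
    }, time.time() - t0)

    t0 = time.time()
    pred_variant = cfg["prediction_variant"]
    if pred_variant not in study["fits"]:
        model = InsulinSignallingModel(data, variant=pred_variant)
        fit = model.fit(preset=cfg["preset"], seed=seed + pred_variant)
    else:
        fit = study["fits"][pred_variant]
    pert = "mtorc1_inhibition" if "Ki2" in fit.params.values else "akt_inhibition"
    scenario = ScenarioSpec(
        "fig1_rapamycin_prediction" if pert == "mtorc1_inhibition"
        else "fig2_akt_inhibition_prediction",
        variants=(pred_variant,),
    )
    prediction = run_prediction(scenario, fit)
    manifest.record("predict", {"scenario": scenario.scenario,
                                "metrics": {k: v for k, v in prediction.items()}},
                    time.time() - t0)

    t0 = time.time()
    prof_variant = cfg["profile_variant"]
    prof_fit = study["fits"].get(prof_variant)
    if prof_fit is None:
        model = InsulinSignallingModel(data, variant=prof_variant)
        prof_fit = model.fit(preset=cfg["preset"], seed=seed + prof_variant)
    survey = run_identifiability_survey(prof_fit, n_grid=cfg["profile_n_grid"],
                                        inner_maxfun=cfg["profile_inner_maxfun"])
    if outdir is not None:
        survey["survey"].to_json(outdir / f"profiles_variant{prof_variant}.json")
    manifest.record("profile", {"variant": prof_variant,
                                "classes": survey["classes"],
                                "n_nonidentifiable": survey["n_nonidentifiable"]},
                    time.time() - t0)

    t0 = time.time()
    if outdir is not None:
        for v, fitres in study["fits"].items():
            fitres.ensemble.to_json(outdir / f"calibration_variant{v}.json",
                                    objective=fitres.model.objective)
        (outdir / "report.txt").write_text(fit.summary() + "\n", encoding="utf-8")
    manifest.record("report", {}, time.time() - t0)
    if outdir is not None:
        manifest.to_json(outdir / "manifest.json")
    return manifest
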