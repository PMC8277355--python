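"""Model/Results interface for calibrating signalling variants to data.

:class:`InsulinSignallingModel` binds one network variant to a time-course
dataset (statsmodels-style); ``fit()`` runs the genetic-algorithm ensemble
and returns a :class:`CalibrationResults` carrying the best-fit parameters,
the spread of local minima across runs, goodness of fit, and methods for
prediction under inhibitor perturbations and profile-likelihood
identifiability analysis.

Example
-------
>>> from aktloop import InsulinSignallingModel, default_training_bundle
>>> data = default_training_bundle()
>>> model = InsulinSignallingModel(data, variant=9)
>>> res = model.fit(preset="smoke", seed=1)
>>> print(res.summary())                       # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .calibration import (
    CalibrationEnsemble,
    GAConfig,
    ObjectiveSpec,
    calibrate_ensemble,
)
from .dataset import TimeCourseDataset
from .models import (
    ModelSpecification,
    ParameterSet,
    PERTURBATIONS,
    StimulusProtocol,
    build_model,
    default_protocols,
    step_protocol,
)
from .profile import ProfileSurvey, ThresholdSpec
from .simulate import (
    ObservableMap,
    basal_steady_state,
    default_observable_map,
    fit_one_phase_decay,
    observe,
    simulate,
)

__all__ = ["InsulinSignallingModel", "CalibrationResults", "GA_PRESETS"]

#: Named GA scales.  "full" is the method's published operating point
#: (population 200, 800 generations, 200 repeated runs); the others trade
#: optimisation quality for turnaround on a single CPU.
GA_PRESETS: dict[str, dict] = {
    "smoke": {"population": 20, "generations": 30, "n_runs": 2},
    "reduced": {"population": 60, "generations": 150, "n_runs": 5},
    "full": {"population": 200, "generations": 800, "n_runs": 200},
}


class InsulinSignallingModel:
    """One network variant bound to a training dataset.

    Parameters
    ----------
    data
        Tidy time-course dataset (see :class:`TimeCourseDataset`).
    variant
        Network variant id (1-9) selecting the feedback topology.
    protocols
        Condition name -> stimulation protocol; defaults cover the standard
        condition names of the synthetic bundle.
    weights
        Optional per-series objective weights w_j.
    """

    def __init__(
        self,
        data: TimeCourseDataset,
        variant: int = 9,
        *,
        protocols: Mapping[str, StimulusProtocol] | None = None,
        observable_map: ObservableMap | None = None,
        weights: Mapping[tuple[str, str], float] | None = None,
        reference_condition: str = "100nM",
        template: ParameterSet | None = None,
    ) -> None:
        self.data = data
        self.spec: ModelSpecification = build_model(variant)
        self.protocols = dict(protocols) if protocols is not None else default_protocols(self.spec)
        self.observable_map = observable_map or default_observable_map(self.spec)
        self.objective = ObjectiveSpec(
            dataset=data,
            model=self.spec,
            protocols=self.protocols,
            observable_map=self.observable_map,
            weights=weights,
            reference_condition=reference_condition,
            template=template,
        )

    @property
    def variant(self) -> int:
        return self.spec.variant

    @classmethod
    def from_dataframe(cls, frame, variant: int = 9, **kwargs) -> "InsulinSignallingModel":
        """Build from a tidy pandas DataFrame with the table column contract."""
        return cls(TimeCourseDataset(frame), variant, **kwargs)

    def fit(
        self,
        *,
        preset: str | None = "reduced",
        config: GAConfig | None = None,
        n_runs: int | None = None,
        seed: int = 0,
    ) -> "CalibrationResults":
        """Calibrate by repeated genetic-algorithm runs with resampled starts."""
        if config is None:
            if preset not in GA_PRESETS:
                raise ValueError(f"unknown preset {preset!r}; expected {sorted(GA_PRESETS)}")
            p = GA_PRESETS[preset]
            config = GAConfig(population=p["population"], generations=p["generations"], seed=seed)
            if n_runs is None:
                n_runs = p["n_runs"]
        elif n_runs is None:
            n_runs = 1
        ensemble = calibrate_ensemble(self.objective, config, n_runs, seed=seed)
        return CalibrationResults(model=self, ensemble=ensemble)

    def results_from_params(self, params: ParameterSet) -> "CalibrationResults":
        """Wrap an externally supplied parameter set (no optimisation)."""
        from .calibration import CalibrationRun

        genes = self.objective.encode(params)
        j = self.objective.evaluate_penalized(params)
        run = CalibrationRun(best_genes=genes, best_objective=j,
                            history=np.array([j]), seed=-1)
        ens = CalibrationEnsemble(runs=(run,), variant=self.variant,
                                 dataset_fingerprint=self.data.fingerprint(),
                                 config=GAConfig(population=4, generations=1), seed=-1)
        return CalibrationResults(model=self, ensemble=ens)


@dataclass(frozen=True)
class CalibrationResults:
    """Best-fit parameters plus everything derived from them."""

    model: InsulinSignallingModel
    ensemble: CalibrationEnsemble

    # -- estimates ---------------------------------------------------------

    @property
    def params(self) -> ParameterSet:
        return self.model.objective.decode(self.ensemble.best_run.best_genes)

    @property
    def objective_value(self) -> float:
        """J at the global optimum."""
        return self.ensemble.global_optimum

    @property
    def reduced_objective(self) -> float:
        """J divided by the number of fitted data points."""
        return self.ensemble.global_optimum / self.model.objective.n_points

    @property
    def local_minima(self) -> np.ndarray:
        return self.ensemble.local_minima

    # -- simulation and prediction ----------------------------------------

    def default_grid(self, horizon: float = 1200.0, basal_window: float = 60.0,
                     dt: float = 15.0) -> np.ndarray:
        return np.arange(-basal_window, horizon + dt / 2, dt)

    def predict(
        self,
        dose: float = 1.0,
        *,
        perturbation: str = "none",
        null_at: float | None = None,
        grid: np.ndarray | None = None,
        params: ParameterSet | None = None,
    ) -> dict[str, np.ndarray]:
        """Observable traces for one insulin dose, optionally perturbed.

        ``perturbation`` names a parameter-nulling recipe (rapamycin,
        pan-Akt inhibition, T309A/S474A, wortmannin).  ``null_at`` delays
        the nulling to mid-course (wortmannin washout); by default the
        nulling is applied together with the stimulus, over an unperturbed
        basal state, mirroring acute inhibitor treatment.
        """
        p = params if params is not None else self.params
        spec = self.model.spec
        if perturbation not in PERTURBATIONS:
            raise ValueError(f"unknown perturbation {perturbation!r}")
        null = PERTURBATIONS[perturbation]
        missing = [n for n in null if n not in p.values]
        if missing:
            raise KeyError(
                f"perturbation {perturbation!r} references parameter(s) {missing} "
                f"absent from variant {spec.variant}"
            )
        protocol = step_protocol(dose, null=null, null_at=null_at)
        g = grid if grid is not None else self.default_grid()
        basal = basal_steady_state(spec, p)
        # fitted parameters can sit at the bounds; prediction-grade
        # tolerances keep the stiff solver robust there
        traj = simulate(spec, p, protocol, g, basal=basal, rtol=1e-7, atol=1e-9)
        traces = observe(traj, self.model.observable_map, reference=traj)
        traces["_t"] = traj.t
        return traces

    def peak_recruitment_change(self, perturbation: str, dose: float = 1.0) -> dict[str, float]:
        """Percent change in PM-Akt recruitment when a perturbation is applied.

        Reports the change in the trace peak (default comparator) and in the
        10-min (post-overshoot) level, plus overshoot ratios
        (peak amplitude / 10-min amplitude above basal).
        """
        ctrl = self.predict(dose)
        pert = self.predict(dose, perturbation=perturbation)
        out: dict[str, float] = {}
        for label, tr in (("control", ctrl), ("perturbed", pert)):
            t, y = tr["_t"], tr["pm_akt"]
            i600 = int(np.searchsorted(t, 600.0))
            peak = float(y.max())
            steady = float(y[i600])
            out[f"{label}_peak"] = peak
            out[f"{label}_steady"] = steady
            denom = max(steady - 1.0, 1e-12)
            out[f"{label}_overshoot_ratio"] = (peak - 1.0) / denom
        out["peak_change_percent"] = 100.0 * (out["perturbed_peak"] - out["control_peak"]) / out["control_peak"]
        out["steady_change_percent"] = (
            100.0 * (out["perturbed_steady"] - out["control_steady"]) / out["control_steady"]
        )
        return out

    def wortmannin_dissociation_rate(
        self,
        *,
        dose: float = 100.0,
        washout_time: float = 600.0,
        akt_inhibited: bool = False,
        horizon: float = 1800.0,
    ) -> float:
        """One-phase decay rate of PM-Akt after PI3K inhibition (Kf3 = 0).

        ``akt_inhibited`` additionally applies the pan-Akt-inhibitor nulling
        from the stimulus onward, mimicking the paired experiment.
        """
        p = self.params
        null = list(PERTURBATIONS["pi3k_inhibition"])
        events_null = PERTURBATIONS["akt_inhibition"] if akt_inhibited else ()
        protocol = step_protocol(dose, null=events_null)
        # append the wortmannin event
        from .models import StimulusEvent, StimulusProtocol

        events = list(protocol.events) + [
            StimulusEvent(washout_time, "parameter_null", parameters=tuple(null))
        ]
        protocol = StimulusProtocol(events=tuple(events))
        grid = np.arange(-60.0, horizon + 7.5, 15.0)
        spec = self.model.spec
        basal = basal_steady_state(spec, p)
        traj = simulate(spec, p, protocol, grid, basal=basal, rtol=1e-7, atol=1e-9)
        traces = observe(traj, self.model.observable_map, reference=traj)
        k, _, _ = fit_one_phase_decay(traj.t, traces["pm_akt"], washout_time)
        return k

    # -- identifiability ---------------------------------------------------

    def profile(
        self,
        names: Sequence[str] | None = None,
        *,
        threshold: ThresholdSpec = ThresholdSpec(),
        n_grid: int = 10,
        inner_maxfun: int = 150,
    ) -> ProfileSurvey:
        """Profile-likelihood survey of the calibrated optimum."""
        obj = self.model.objective
        free = list(obj.free_names)
        if names is None:
            names = free
        theta = np.array([self.params[n] for n in free])
        bounds = [obj.template.bounds[n] for n in free]

        def fun(vec: np.ndarray) -> float:
            p = obj.template.with_values(dict(zip(free, vec)))
            return obj.evaluate_penalized(p)

        surveys = []
        from .profile import classify_identifiability, profile_confidence_interval, profile_parameter

        chi2_opt = fun(theta)
        for name in names:
            pr = profile_parameter(fun, theta, free, bounds, name,
                                   n_grid=n_grid, inner_maxfun=inner_maxfun,
                                   chi2_opt=chi2_opt)
            pr = classify_identifiability(profile_confidence_interval(pr, threshold))
            surveys.append(pr)
        return ProfileSurvey(profiles=tuple(surveys), variant=self.model.variant)

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        """Human-readable calibration report."""
        stats = self.ensemble.summary_stats()
        p = self.params
        lines = [
            "Insulin signalling model calibration",
            "=" * 52,
            f"variant:           {self.model.variant} "
            f"(feedback: {self._feedback_label()})",
            f"data:              {self.model.data.n_series} series, "
            f"{self.model.objective.n_points} points "
            f"[{self.ensemble.dataset_fingerprint[:12]}]",
            f"GA runs:           {len(self.ensemble.runs)} "
            f"(pop {self.ensemble.config.population}, "
            f"{self.ensemble.config.generations} generations)",
            f"objective J:       {self.objective_value:.4g} (global optimum)",
            f"J / n_points:      {self.reduced_objective:.4g}",
            f"local minima:      median {stats['median']:.4g}, IQR {stats['iqr']:.4g}, "
            f"min {stats['min']:.4g}, max {stats['max']:.4g}",
            "-" * 52,
            f"{'parameter':<10}{'estimate':>14}",
        ]
        for name, v in p.values.items():
            lines.append(f"{name:<10}{v:>14.5g}")
        return "\n".join(lines)

    def _feedback_label(self) -> str:
        fb = self.model.spec.feedback
        if fb is None:
            return "none"
        return f"{fb[0]} -| {fb[1]}"
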