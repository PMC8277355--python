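"""Weighted least-squares objective and genetic-algorithm calibration.

The objective is ``J(p) = sum_j w_j sum_i ((yD_ji - y_j(t_i, p)) / sigma_ji)**2``
over all M data series (observable x condition), with simulations normalised
exactly as the data (same basal window, same reference maximum).

The optimizer is a real-coded genetic algorithm in bounds-normalised log10
coordinates: elite preservation (5% of the population), uniform "scattered"
two-parent crossover on a 0.8 fraction of the non-elite offspring, and
Gaussian mutation whose standard deviation follows the shrinking recursion
``sigma_k = sigma_{k-1} * (1 - k/G)`` from ``sigma_0 = 1``.  Repeated runs
with resampled starting populations form a :class:`CalibrationEnsemble`
whose lowest local minimum is the global optimum.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from .dataset import TimeCourseDataset
from .models import (
    ModelSpecification,
    ParameterSet,
    StimulusProtocol,
    default_parameters,
)
from .simulate import (
    ObservableMap,
    SimulationError,
    SteadyStateError,
    ZeroBasalError,
    basal_steady_state,
    default_observable_map,
    simulate,
)

__all__ = [
    "PENALTY_OBJECTIVE",
    "ObjectiveSpec",
    "GAConfig",
    "CalibrationRun",
    "CalibrationEnsemble",
    "objective_value",
    "mutation_sigma",
    "ga_optimize",
    "calibrate_ensemble",
    "rank_models",
]

#: Finite score assigned to failed simulations so the GA can proceed.
PENALTY_OBJECTIVE = 1e12


@dataclass
class ObjectiveSpec:
    """Everything needed to score a parameter set against a dataset."""

    dataset: TimeCourseDataset
    model: ModelSpecification
    protocols: Mapping[str, StimulusProtocol]
    observable_map: ObservableMap | None = None
    weights: Mapping[tuple[str, str], float] | None = None   #: per-series w_j
    reference_condition: str = "100nM"
    sigma_floor_frac: float | None = 1e-3    #: sem floor, fraction of dynamic range
    rtol: float = 1e-5
    atol: float = 1e-8
    max_steps: int = 600           #: per-condition solver step budget
    fast_basal: bool = True        #: Newton-only basal search (no integration fallback)
    template: ParameterSet | None = None

    def __post_init__(self) -> None:
        if self.observable_map is None:
            self.observable_map = default_observable_map(self.model)
        if self.template is None:
            self.template = default_parameters(self.model)
        for obs, cond, _ in self._iter_series_keys():
            if cond not in self.protocols:
                raise KeyError(f"dataset condition {cond!r} has no protocol")
        if self.weights is not None:
            for key, w in self.weights.items():
                if w <= 0:
                    raise ValueError(f"weight for series {key} must be > 0")
        self._compile()

    def _iter_series_keys(self):
        for obs, cond, sub in self.dataset.iter_series():
            yield obs, cond, sub

    def _compile(self) -> None:
        """Precompute per-condition grids and per-series index arrays."""
        omap = self.observable_map
        grids: dict[str, np.ndarray] = {}
        for cond in self.dataset.conditions:
            times = np.unique(
                self.dataset.frame.loc[self.dataset.frame["condition"] == cond, "time_s"]
            )
            grids[cond] = times
        series = []
        for obs, cond, sub in self.dataset.iter_series():
            t = sub["time_s"].to_numpy()
            y = sub["mean"].to_numpy()
            sem = sub["sem"].to_numpy().copy()
            if np.any(sem == 0):
                if self.sigma_floor_frac is None:
                    raise ValueError(
                        f"series ({obs!r}, {cond!r}) has sem = 0 points and no sigma floor "
                        "is configured"
                    )
                floor = self.sigma_floor_frac * max(self.dataset.dynamic_range(obs), 1e-12)
                sem = np.maximum(sem, floor)
            idx = np.searchsorted(grids[cond], t)
            w = 1.0 if self.weights is None else self.weights.get((obs, cond), 1.0)
            mode = self.dataset.normalization(obs)
            if mode != omap.modes.get(obs):
                raise ValueError(
                    f"normalization mismatch for {obs!r}: data says {mode!r}, "
                    f"map says {omap.modes.get(obs)!r}"
                )
            series.append((obs, cond, idx, y, sem, w, mode))
        self._grids = grids
        self._series = series
        # reference-index per observable for percent_of_max scaling
        self._ref_idx: dict[str, np.ndarray] = {}
        for obs, cond, idx, *_ in [s[:3] for s in series]:
            if cond == self.reference_condition:
                self._ref_idx[obs] = idx

    @property
    def n_points(self) -> int:
        return self.dataset.n_points

    @property
    def free_names(self) -> tuple[str, ...]:
        return self.template.free_names()

    # -- evaluation --------------------------------------------------------

    def evaluate(self, params: ParameterSet) -> float:
        """J(p); simulation failures raise."""
        traces = self._raw_traces(params)
        return self._score(traces, params)

    def evaluate_penalized(self, params: ParameterSet) -> float:
        """J(p), with solver blow-ups scored as a large finite penalty."""
        try:
            return self.evaluate(params)
        except (SimulationError, SteadyStateError, ZeroBasalError, FloatingPointError):
            return PENALTY_OBJECTIVE

    def _raw_traces(self, params: ParameterSet):
        omap = self.observable_map
        basal = basal_steady_state(self.model, params, tol=1e-7, fast=self.fast_basal)
        out = {}
        basal_vals = {}
        for cond, grid in self._grids.items():
            traj = simulate(self.model, params, self.protocols[cond], grid,
                            rtol=self.rtol, atol=self.atol, basal=basal,
                            max_steps=self.max_steps)
            for obs in omap.weights:
                out[(obs, cond)] = omap.raw_trace(traj, obs)
                basal_vals[obs] = omap.raw_basal(traj, obs)
        return out, basal_vals

    def _score(self, traces, params: ParameterSet) -> float:
        out, basal_vals = traces
        # percent-of-max scale from the reference condition, measured at the
        # reference series' own sampling times (as the data are normalised)
        scales: dict[str, float] = {}
        for obs, idx in self._ref_idx.items():
            ref = out[(obs, self.reference_condition)][idx]
            m = float(np.max(ref))
            if m <= 1e-300:
                raise ZeroBasalError(f"reference maximum of {obs!r} is zero")
            scales[obs] = 100.0 / m
        j = 0.0
        for obs, cond, idx, y, sem, w, mode in self._series:
            sim = out[(obs, cond)][idx]
            if mode == "fold_over_basal":
                basal = basal_vals[obs]
                if basal <= 1e-300:
                    raise ZeroBasalError(f"basal signal of {obs!r} is zero")
                sim = sim / basal
            else:
                sim = sim * scales[obs]
            r = (y - sim) / sem
            j += w * float(r @ r)
        return j

    # -- gene coding (bounds-normalised log10 coordinates) -----------------

    def decode(self, genes: np.ndarray) -> ParameterSet:
        vals = {}
        for g, name in zip(genes, self.free_names):
            lo, hi = self.template.bounds[name]
            lg = math.log10(lo) + float(g) * (math.log10(hi) - math.log10(lo))
            vals[name] = 10.0 ** lg
        return self.template.with_values(vals)

    def encode(self, params: ParameterSet) -> np.ndarray:
        genes = np.empty(len(self.free_names))
        for i, name in enumerate(self.free_names):
            lo, hi = self.template.bounds[name]
            v = min(max(params[name], lo), hi)
            genes[i] = (math.log10(v) - math.log10(lo)) / (math.log10(hi) - math.log10(lo))
        return genes

    def evaluate_genes(self, genes: np.ndarray) -> float:
        return self.evaluate_penalized(self.decode(genes))

    @property
    def n_genes(self) -> int:
        return len(self.free_names)


def objective_value(params: ParameterSet, spec: ObjectiveSpec) -> float:
    """J(p): weighted sum of squared, sigma-scaled residuals."""
    return spec.evaluate(params)


# ---------------------------------------------------------------------------
# Genetic algorithm
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GAConfig:
    population: int = 200
    generations: int = 800
    elite_fraction: float = 0.05
    crossover_fraction: float = 0.8
    sigma0: float = 1.0
    #: bounds-sampling scheme for the starting population, as a sub-interval
    #: of the normalised gene range (0, 1) = the full log10 bounds.
    init_range: tuple = (0.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.elite_fraction < 1:
            raise ValueError("elite_fraction must lie in (0, 1)")
        if not 0 <= self.crossover_fraction <= 1:
            raise ValueError("crossover_fraction must lie in [0, 1]")
        if self.sigma0 <= 0:
            raise ValueError("sigma0 must be > 0")
        if self.population < 4 or self.generations < 1:
            raise ValueError("population must be >= 4 and generations >= 1")
        lo, hi = self.init_range
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("init_range must be a sub-interval of (0, 1)")

    def scaled(self, **updates) -> "GAConfig":
        return replace(self, **updates)


def mutation_sigma(k: int, config: GAConfig) -> float:
    """Mutation standard deviation at generation k (exact recursion)."""
    if k < 0 or k > config.generations:
        raise ValueError(f"generation index {k} outside [0, {config.generations}]")
    sigma = config.sigma0
    for j in range(1, k + 1):
        sigma = sigma * (1.0 - j / config.generations)
    return sigma


@dataclass(frozen=True)
class CalibrationRun:
    """One GA run: its local minimum and per-generation history."""

    best_genes: np.ndarray = field(repr=False)
    best_objective: float
    history: np.ndarray = field(repr=False)      # best-so-far per generation
    seed: int
    n_evaluations: int = 0

    def __post_init__(self) -> None:
        if np.any(np.diff(self.history) > 1e-12):
            raise ValueError("best-so-far history must be non-increasing")

    def to_dict(self) -> dict:
        return {
            "seed": int(self.seed),
            "best_objective": float(self.best_objective),
            "best_genes": [float(g) for g in self.best_genes],
            "history": [float(h) for h in self.history],
            "n_evaluations": int(self.n_evaluations),
        }


def _sus_select(fitness_rank: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Rank-based stochastic universal sampling; returns selected indices."""
    p = fitness_rank.shape[0]
    # linear ranking weights: best rank gets weight p, worst gets 1
    weights = np.empty(p)
    weights[fitness_rank] = np.arange(p, 0, -1, dtype=float)
    cum = np.cumsum(weights)
    total = cum[-1]
    step = total / n
    start = rng.random() * step
    points = start + step * np.arange(n)
    return np.searchsorted(cum, points)


def ga_optimize(
    evaluate: Callable[[np.ndarray], float],
    n_genes: int,
    config: GAConfig,
    *,
    seed: int | None = None,
    x0: np.ndarray | None = None,
) -> CalibrationRun:
    """Minimise ``evaluate`` over the unit hypercube ``[0, 1]^n_genes``.

    The caller owns the gene coding (log10 bounds-normalised for rate
    constants).  Fully reproducible under a fixed seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    pop_n, gens = config.population, config.generations
    n_elite = max(1, int(round(config.elite_fraction * pop_n)))
    n_cross = int(round(config.crossover_fraction * (pop_n - n_elite)))
    n_mut = pop_n - n_elite - n_cross

    lo, hi = config.init_range
    pop = lo + (hi - lo) * rng.random((pop_n, n_genes))
    if x0 is not None:
        pop[0] = np.clip(x0, 0.0, 1.0)
    fit = np.array([evaluate(x) for x in pop])
    n_eval = pop_n
    if np.all(fit >= PENALTY_OBJECTIVE):
        raise RuntimeError(
            "every individual of the initial population failed evaluation; "
            "check bounds and the simulation configuration"
        )

    history = np.empty(gens)
    sigma = config.sigma0
    for k in range(1, gens + 1):
        sigma = sigma * (1.0 - k / gens)
        order = np.argsort(fit, kind="stable")
        rank_of = np.empty(pop_n, dtype=np.int64)
        rank_of[order] = np.arange(pop_n)

        elites = pop[order[:n_elite]]
        elite_fit = fit[order[:n_elite]]

        parent_idx = _sus_select(rank_of, 2 * n_cross + n_mut, rng)
        rng.shuffle(parent_idx)
        new = np.empty((pop_n - n_elite, n_genes))
        # uniform (scattered) crossover
        for i in range(n_cross):
            a = pop[parent_idx[2 * i]]
            b = pop[parent_idx[2 * i + 1]]
            mask = rng.random(n_genes) < 0.5
            new[i] = np.where(mask, a, b)
        # Gaussian mutation in normalised coordinates, clipped to bounds
        for i in range(n_mut):
            parent = pop[parent_idx[2 * n_cross + i]]
            new[n_cross + i] = np.clip(parent + rng.normal(0.0, sigma, n_genes), 0.0, 1.0)

        new_fit = np.array([evaluate(x) for x in new])
        n_eval += len(new)
        pop = np.vstack([elites, new])
        fit = np.concatenate([elite_fit, new_fit])
        history[k - 1] = float(fit.min())

    best = int(np.argmin(fit))
    history = np.minimum.accumulate(history)
    return CalibrationRun(
        best_genes=pop[best].copy(),
        best_objective=float(fit[best]),
        history=history,
        seed=int(config.seed if seed is None else seed),
        n_evaluations=n_eval,
    )


# ---------------------------------------------------------------------------
# Ensembles and model ranking
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationEnsemble:
    """Repeated GA runs with resampled starts; min is the global optimum."""

    runs: tuple[CalibrationRun, ...]
    variant: int
    dataset_fingerprint: str
    config: GAConfig
    seed: int

    @property
    def local_minima(self) -> np.ndarray:
        return np.array([r.best_objective for r in self.runs])

    @property
    def best_run(self) -> CalibrationRun:
        return min(self.runs, key=lambda r: r.best_objective)

    @property
    def global_optimum(self) -> float:
        return float(self.local_minima.min())

    def summary_stats(self) -> dict[str, float]:
        lm = self.local_minima
        return {
            "median": float(np.median(lm)),
            "iqr": float(np.percentile(lm, 75) - np.percentile(lm, 25)),
            "min": float(lm.min()),
            "max": float(lm.max()),
        }

    def to_json(self, path: str | Path | None = None, *,
                objective: ObjectiveSpec | None = None) -> str:
        doc = {
            "variant": self.variant,
            "seed": self.seed,
            "dataset_fingerprint": self.dataset_fingerprint,
            "ga_config": {
                "population": self.config.population,
                "generations": self.config.generations,
                "elite_fraction": self.config.elite_fraction,
                "crossover_fraction": self.config.crossover_fraction,
                "sigma0": self.config.sigma0,
            },
            "global_optimum": self.global_optimum,
            "summary": self.summary_stats(),
            "runs": [r.to_dict() for r in self.runs],
        }
        if objective is not None:
            doc["best_parameters"] = objective.decode(self.best_run.best_genes).values
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


def calibrate_ensemble(
    spec: ObjectiveSpec,
    config: GAConfig,
    n_runs: int,
    *,
    seed: int | None = None,
) -> CalibrationEnsemble:
    """Run ``n_runs`` independent GA calibrations with resampled starts."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    base_seed = config.seed if seed is None else seed
    run_seeds = np.random.default_rng(base_seed).integers(0, 2**31 - 1, size=n_runs)
    runs = []
    for i, s in enumerate(run_seeds):
        try:
            runs.append(ga_optimize(spec.evaluate_genes, spec.n_genes, config, seed=int(s)))
        except Exception as exc:
            raise RuntimeError(f"calibration run {i} (seed {s}) failed") from exc
    return CalibrationEnsemble(
        runs=tuple(runs),
        variant=spec.model.variant,
        dataset_fingerprint=spec.dataset.fingerprint(),
        config=config,
        seed=int(base_seed),
    )


def rank_models(ensembles: Sequence[CalibrationEnsemble]) -> list[CalibrationEnsemble]:
    """Sort variants by global optimum (ascending); ties break on variant id."""
    fps = {e.dataset_fingerprint for e in ensembles}
    if len(fps) > 1:
        raise ValueError(
            "ensembles were calibrated against different datasets "
            f"(fingerprints {sorted(fps)})"
        )
    return sorted(ensembles, key=lambda e: (e.global_optimum, e.variant))
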