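"""Synthetic training data emulating insulin-stimulated Akt signalling kinetics.

The generator produces, in *feature mode*, noiseless reference curves whose
printed kinetic features are met exactly by construction:

* Akt plasma-membrane (PM) recruitment at 1 nM insulin rises to a maximum at
  75 s and settles to an amplitude of half the peak by 10 min (an overshoot,
  the signature of fast negative feedback);
* at 100 nM insulin the peak amplitude is fourfold the 1 nM peak, followed by
  a dip and a slow secondary rise;
* a pan-Akt-inhibitor condition loses the overshoot and saturates at three
  times the control amplitude (3.5-fold for the kinase-dead mutant);
* an mTORC1-inhibitor (rapamycin) condition is identical to control;
* a PI3K-inhibitor (wortmannin) washout condition follows a plateau plus
  one-phase exponential decay after the inhibitor time;
* immunoblot-style pAkt T309 / pAkt S474 / pPRAS40 T246 time courses, with
  T309 phosphorylation peaking earlier than S474 and PRAS40 saturating
  without an overshoot.

The overshoot family is ``g(t) = (1-phi) * O(t)/O(tp) + phi * (1-exp(-ka t))``
with ``O(t) = exp(-kd t) - exp(-ka t)``; given the rise rate ``ka``, the decay
rate ``kd`` and plateau weight ``phi`` are obtained by root-finding so the
peak time and steady-state fraction hit their targets exactly.

*Ground-truth mode* (:func:`generate_from_model`) instead samples a
known-parameter ODE model, for parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .dataset import TimeCourseDataset

__all__ = [
    "GeneratorConfig",
    "NoiselessCurveSet",
    "FeatureConstraintError",
    "CONDITIONS",
    "OBSERVABLES",
    "TRAINING_SERIES",
    "generate_reference_curves",
    "add_measurement_noise",
    "default_training_bundle",
    "generate_from_model",
    "solve_overshoot_family",
]

# Observable names used throughout the package.
PM_AKT = "pm_akt"
PT309 = "pakt_t309"
PS474 = "pakt_s474"
PPRAS40 = "ppras40_t246"
OBSERVABLES = (PM_AKT, PT309, PS474, PPRAS40)

# Stimulation/perturbation conditions.
COND_1NM = "1nM"
COND_100NM = "100nM"
COND_RAPA = "1nM+rapamycin"
COND_AKTI = "1nM+akt_inhibitor"
COND_KD = "1nM+kinase_dead"
COND_WORT = "100nM+wortmannin"
CONDITIONS = (COND_1NM, COND_100NM, COND_RAPA, COND_AKTI, COND_KD, COND_WORT)

#: The (observable, condition) series used for model calibration: recruitment
#: and the three phospho read-outs at both insulin doses.
TRAINING_SERIES = tuple(
    [(PM_AKT, COND_1NM), (PM_AKT, COND_100NM)]
    + [(obs, cond) for obs in (PT309, PS474, PPRAS40) for cond in (COND_1NM, COND_100NM)]
)


class FeatureConstraintError(ValueError):
    """A requested kinetic feature cannot be realised by the curve family."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the synthetic time-course generator.

    All times are in seconds.  The defaults encode the kinetic features of
    the training data; the immunoblot sampling grid and the 100 nM endpoint
    amplitude are not pinned by any measured number and are free defaults
    (see ``endpoint_peak_fraction``, ``blot_times``).
    """

    basal_window: float = 60.0       #: duration of pre-stimulus sampling (s)
    sample_interval: float = 15.0    #: TIRF-like sampling interval (s)
    horizon: float = 1200.0          #: post-stimulus duration (s)
    rise_rate: float = 0.03          #: k_a, recruitment rise rate (1/s)
    peak_time_target: float = 75.0   #: 1 nM recruitment peak time (s)
    steady_fraction_target: float = 0.5   #: 10-min amplitude / peak amplitude
    dose_peak_ratio: float = 4.0     #: 100 nM vs 1 nM peak amplitude
    akt_inhibitor_amplitude_ratio: float = 3.0
    kinase_dead_amplitude_ratio: float = 3.5
    peak_fold_1nm: float = 2.0       #: 1 nM peak in fold-over-basal units
    endpoint_peak_fraction: float = 0.95  #: 100 nM final amplitude / first peak
    secondary_rise_midpoint: float = 400.0
    secondary_rise_tau: float = 80.0
    washout_time: float = 600.0      #: PI3K-inhibitor addition time (s)
    washout_decay_rate: float = 0.01      #: one-phase decay rate constant (1/s)
    washout_rise_rate: float = 0.02
    pt309_peak_time: float = 120.0
    ps474_peak_time: float = 300.0
    phospho_steady_fraction: float = 0.6
    phospho_dose_fraction: float = 0.6    #: 1 nM phospho max / 100 nM phospho max
    phospho_basal_percent: float = 2.0
    pras40_rise_rate: float = 0.01
    blot_times: tuple[float, ...] = (0.0, 30.0, 60.0, 150.0, 300.0, 600.0, 1200.0)
    noise_sd: float = 0.1            #: fraction of each observable's dynamic range
    n_replicates: int = 4
    seed: int = 0

    def validate(self) -> None:
        c = self
        if c.sample_interval <= 0 or c.horizon <= 0 or c.basal_window < 0:
            raise ValueError("sample_interval/horizon must be > 0, basal_window >= 0")
        if abs(c.peak_time_target / c.sample_interval - round(c.peak_time_target / c.sample_interval)) > 1e-9:
            raise ValueError("peak_time_target must be a multiple of sample_interval")
        for name in ("rise_rate", "washout_decay_rate", "washout_rise_rate", "pras40_rise_rate"):
            if getattr(c, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < c.steady_fraction_target < 1:
            raise ValueError("steady_fraction_target must lie in (0, 1)")
        if not 0 < c.phospho_steady_fraction < 1:
            raise ValueError("phospho_steady_fraction must lie in (0, 1)")
        if c.dose_peak_ratio <= 0 or c.akt_inhibitor_amplitude_ratio <= 0:
            raise ValueError("amplitude ratios must be > 0")
        if c.peak_fold_1nm <= 1:
            raise ValueError("peak_fold_1nm must exceed the baseline of 1")
        if c.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if c.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if c.peak_time_target >= c.horizon or c.washout_time >= c.horizon:
            raise ValueError("peak_time_target and washout_time must precede the horizon")


@dataclass(frozen=True)
class NoiselessCurveSet:
    """Reference curves per (observable, condition), prior to noise.

    Recruitment curves are in fold-over-basal units (baseline 1.0); phospho
    curves in percent-of-max units (the 100 nM reference peaks at 100).
    """

    curves: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = field(repr=False)
    normalization: dict[str, str]
    config: GeneratorConfig

    def series(self, observable: str, condition: str) -> tuple[np.ndarray, np.ndarray]:
        return self.curves[(observable, condition)]

    def keys(self) -> list[tuple[str, str]]:
        return list(self.curves)

    def peak_time(self, observable: str, condition: str) -> float:
        t, y = self.series(observable, condition)
        return float(t[int(np.argmax(y))])

    def baseline(self, observable: str) -> float:
        return 1.0 if self.normalization[observable] == "fold_over_basal" else float(
            self.config.phospho_basal_percent
        )


# ---------------------------------------------------------------------------
# Overshoot curve family
# ---------------------------------------------------------------------------

def _envelope(t: np.ndarray | float, ka: float, kd: float) -> np.ndarray | float:
    return np.exp(-kd * t) - np.exp(-ka * t)


def solve_overshoot_family(
    ka: float, peak_time: float, steady_fraction: float, steady_time: float = 600.0
) -> tuple[float, float]:
    """Solve (kd, phi) so that g peaks at ``peak_time`` and g(steady_time) =
    steady_fraction * g(peak_time).

    The stationarity condition at the peak is linear in phi, which reduces
    the problem to a 1-D root find in kd.  Raises
    :class:`FeatureConstraintError` when no bracket exists.
    """
    tp = peak_time

    def phi_of(kd: float) -> float:
        o_tp = _envelope(tp, ka, kd)
        a = (-kd * math.exp(-kd * tp) + ka * math.exp(-ka * tp)) / o_tp
        b = ka * math.exp(-ka * tp)
        return a / (a - b)

    def g(t: float, kd: float, phi: float) -> float:
        return (1 - phi) * _envelope(t, ka, kd) / _envelope(tp, ka, kd) + phi * (
            1 - math.exp(-ka * t)
        )

    def fraction_residual(kd: float) -> float:
        phi = phi_of(kd)
        return g(steady_time, kd, phi) - steady_fraction * g(tp, kd, phi)

    # kd must exceed the value at which the bare envelope peaks exactly at tp
    # (below it, no phi in (0, 1) can move the peak out to tp).
    def t_env_peak(kd: float) -> float:
        return math.log(ka / kd) / (ka - kd)

    lo, hi = 1e-8, ka * (1 - 1e-9)
    if t_env_peak(lo) < tp:
        raise FeatureConstraintError(
            f"peak_time_target={tp}: rise rate ka={ka} is too slow for the envelope to peak there"
        )
    kd_min = brentq(lambda kd: t_env_peak(kd) - tp, lo, hi, xtol=1e-14)
    grid = np.geomspace(kd_min * (1 + 1e-6), hi, 400)
    vals = np.array([fraction_residual(k) for k in grid])
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if len(sign_change) == 0:
        raise FeatureConstraintError(
            f"steady_fraction_target={steady_fraction} unreachable at peak_time_target={tp} "
            f"with rise rate ka={ka} (constraint 'steady fraction' cannot be bracketed)"
        )
    i = int(sign_change[0])
    kd = brentq(fraction_residual, grid[i], grid[i + 1], xtol=1e-15, rtol=1e-14)
    phi = phi_of(kd)
    if not 0 <= phi < 1:
        raise FeatureConstraintError(f"plateau weight phi={phi:.3g} outside [0, 1)")
    return float(kd), float(phi)


def _overshoot_curve(t: np.ndarray, ka: float, kd: float, phi: float, tp: float) -> np.ndarray:
    """Unit family g(t) for t >= 0 (g(0) = 0), clamped to 0 before stimulus."""
    tt = np.maximum(t, 0.0)
    g = (1 - phi) * _envelope(tt, ka, kd) / _envelope(tp, ka, kd) + phi * (1 - np.exp(-ka * tt))
    return np.where(t > 0, g, 0.0)


def _logistic_rise(t: np.ndarray, midpoint: float, tau: float) -> np.ndarray:
    tt = np.maximum(t, 0.0)
    s = 1.0 / (1.0 + np.exp(-(tt - midpoint) / tau))
    s0 = 1.0 / (1.0 + np.exp(midpoint / tau))
    return np.where(t > 0, s - s0, 0.0)


def _saturating(t: np.ndarray, k: float, horizon: float) -> np.ndarray:
    tt = np.maximum(t, 0.0)
    y = (1 - np.exp(-k * tt)) / (1 - np.exp(-k * horizon))
    return np.where(t > 0, y, 0.0)


# ---------------------------------------------------------------------------
# Feature-mode generation
# ---------------------------------------------------------------------------

def generate_reference_curves(config: GeneratorConfig | None = None) -> NoiselessCurveSet:
    """Build the full noiseless reference curve set (feature mode)."""
    c = config or GeneratorConfig()
    c.validate()

    dt, tp, H = c.sample_interval, c.peak_time_target, c.horizon
    t_rec = np.arange(-c.basal_window, H + dt / 2, dt)
    ka = c.rise_rate

    kd, phi = solve_overshoot_family(ka, tp, c.steady_fraction_target)
    g1 = _overshoot_curve(t_rec, ka, kd, phi, tp)
    gp = float(_overshoot_curve(np.array([tp]), ka, kd, phi, tp)[0])
    a1 = c.peak_fold_1nm - 1.0          # 1 nM peak amplitude above basal
    rec_1nm = 1.0 + a1 * g1 / gp
    if int(np.argmax(rec_1nm)) != int(np.searchsorted(t_rec, tp)):
        raise FeatureConstraintError(
            "discrete argmax of the 1 nM recruitment curve is not at peak_time_target"
        )

    # 100 nM: overshoot component plus slow logistic secondary rise.  The
    # peak amplitude (at tp) and the endpoint amplitude are two linear
    # constraints in the two component amplitudes.
    s = _logistic_rise(t_rec, c.secondary_rise_midpoint, c.secondary_rise_tau)
    i_tp = int(np.searchsorted(t_rec, tp))
    g_tp, g_H = g1[i_tp] / gp, g1[-1] / gp
    s_tp, s_H = s[i_tp], s[-1]
    p100 = c.dose_peak_ratio * a1
    target = np.array([p100, c.endpoint_peak_fraction * p100])
    mat = np.array([[g_tp, s_tp], [g_H, s_H]])
    try:
        a_os, a_log = np.linalg.solve(mat, target)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise FeatureConstraintError("100 nM amplitude system is singular") from exc
    if a_os <= 0 or a_log < 0:
        raise FeatureConstraintError(
            "100 nM secondary-rise constraint infeasible (negative component amplitude)"
        )
    rec_100nm = 1.0 + a_os * g1 / gp + a_log * s
    _check_100nm_shape(t_rec, rec_100nm, tp)

    # Akt-inhibitor / kinase-dead: monotone saturating, amplitude ratio exact
    # at the final grid point.
    sat = _saturating(t_rec, 1.0 / 150.0, H)
    rec_akti = 1.0 + c.akt_inhibitor_amplitude_ratio * a1 * sat
    rec_kd = 1.0 + c.kinase_dead_amplitude_ratio * a1 * sat

    # Wortmannin washout: rise to plateau, then one-phase decay after t_w.
    tw = c.washout_time
    plateau_amp = c.endpoint_peak_fraction * p100
    rise = 1.0 + plateau_amp * np.where(
        t_rec > 0, 1 - np.exp(-c.washout_rise_rate * np.maximum(t_rec, 0.0)), 0.0
    )
    v_tw = 1.0 + plateau_amp * (1 - math.exp(-c.washout_rise_rate * tw))
    decay = 1.0 + (v_tw - 1.0) * np.exp(-c.washout_decay_rate * (t_rec - tw))
    rec_wort = np.where(t_rec <= tw, rise, decay)

    curves: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {
        (PM_AKT, COND_1NM): (t_rec, rec_1nm),
        (PM_AKT, COND_100NM): (t_rec, rec_100nm),
        (PM_AKT, COND_RAPA): (t_rec, rec_1nm.copy()),
        (PM_AKT, COND_AKTI): (t_rec, rec_akti),
        (PM_AKT, COND_KD): (t_rec, rec_kd),
        (PM_AKT, COND_WORT): (t_rec, rec_wort),
    }

    # Immunoblot-style phospho curves on the blot grid, percent-of-max units.
    t_blot = np.concatenate([[-c.basal_window], np.asarray(c.blot_times, dtype=float)])
    b = c.phospho_basal_percent
    for obs, shape in (
        (PT309, _phospho_shape(c, c.pt309_peak_time)),
        (PS474, _phospho_shape(c, c.ps474_peak_time)),
        (PPRAS40, lambda t: _saturating(t, c.pras40_rise_rate, H)),
    ):
        y = shape(t_blot)
        ymax = y.max()
        if ymax <= 0:
            raise FeatureConstraintError(f"degenerate phospho shape for {obs}")
        y100 = b + (100.0 - b) * y / ymax
        y1 = b + c.phospho_dose_fraction * (100.0 - b) * y / ymax
        curves[(obs, COND_100NM)] = (t_blot, y100)
        curves[(obs, COND_1NM)] = (t_blot, y1)

    normalization = {PM_AKT: "fold_over_basal", PT309: "percent_of_max",
                     PS474: "percent_of_max", PPRAS40: "percent_of_max"}
    return NoiselessCurveSet(curves=curves, normalization=normalization, config=c)


def _phospho_shape(c: GeneratorConfig, peak_time: float) -> Callable[[np.ndarray], np.ndarray]:
    # Blot kinetics are slower than recruitment: scale the rise rate to the
    # peak time (ka * tp = 2.5) and pin the residual overshoot fraction at
    # the 20-min endpoint of the blot grid.
    ka = 2.5 / peak_time
    kd, phi = solve_overshoot_family(
        ka, peak_time, c.phospho_steady_fraction, steady_time=float(max(c.blot_times))
    )
    return lambda t: _overshoot_curve(t, ka, kd, phi, peak_time)


def _check_100nm_shape(t: np.ndarray, y: np.ndarray, tp: float) -> None:
    post = t > 0
    ts, ys = t[post], y[post]
    i_tp = int(np.searchsorted(ts, tp))
    early = ys[: i_tp + 2]
    if int(np.argmax(early)) != i_tp:
        raise FeatureConstraintError("100 nM curve lacks a local maximum at the target peak time")
    after = ys[i_tp:]
    i_min = int(np.argmin(after))
    if i_min == 0 or i_min == len(after) - 1:
        raise FeatureConstraintError("100 nM curve lacks a post-peak local minimum")
    if after[-1] <= after[i_min]:
        raise FeatureConstraintError("100 nM curve lacks a secondary rise after the dip")


# ---------------------------------------------------------------------------
# Noise model
# ---------------------------------------------------------------------------

def add_measurement_noise(
    curves: NoiselessCurveSet, config: GeneratorConfig | None = None
) -> TimeCourseDataset:
    """Replicate-level Gaussian noise, homoscedastic per observable.

    Each data point is the mean of ``n_replicates`` draws of
    ``reference + N(0, noise_sd * dynamic_range(observable))``; the SEM is
    the replicate sample standard deviation over sqrt(n).  With a fixed seed
    the output is byte-identical across calls.
    """
    c = config or curves.config
    c.validate()
    rng = np.random.default_rng(c.seed)

    dyn: dict[str, float] = {}
    for obs in {k[0] for k in curves.keys()}:
        vals = np.concatenate([curves.series(obs, k[1])[1] for k in curves.keys() if k[0] == obs])
        dyn[obs] = float(vals.max() - vals.min())

    rows = []
    for (obs, cond) in curves.keys():
        t, y = curves.series(obs, cond)
        sd = c.noise_sd * dyn[obs]
        draws = y[None, :] + rng.normal(0.0, 1.0, size=(c.n_replicates, len(y))) * sd
        mean = draws.mean(axis=0)
        if c.n_replicates > 1 and sd > 0:
            sem = draws.std(axis=0, ddof=1) / math.sqrt(c.n_replicates)
        else:
            sem = np.zeros_like(mean)
        for ti, mi, si in zip(t, mean, sem):
            rows.append((obs, cond, float(ti), float(mi), float(si), c.n_replicates,
                         curves.normalization[obs]))
    frame = pd.DataFrame(rows, columns=["observable", "condition", "time_s", "mean",
                                        "sem", "n", "normalization"])
    return TimeCourseDataset(frame)


def default_training_bundle(
    config: GeneratorConfig | None = None, *, training_only: bool = True
) -> TimeCourseDataset:
    """Noised dataset over the training series (or all conditions)."""
    c = config or GeneratorConfig()
    curves = generate_reference_curves(c)
    ds = add_measurement_noise(curves, c)
    if not training_only:
        return ds
    keep = ds.frame.apply(
        lambda r: (r["observable"], r["condition"]) in TRAINING_SERIES, axis=1
    )
    return TimeCourseDataset(ds.frame[keep].reset_index(drop=True))


# ---------------------------------------------------------------------------
# Ground-truth mode
# ---------------------------------------------------------------------------

def generate_from_model(spec, params, protocols, config: GeneratorConfig | None = None,
                        observable_map=None) -> TimeCourseDataset:
    """Sample a known-parameter ODE model and add measurement noise.

    ``protocols`` maps condition name -> StimulusProtocol.  Observables are
    computed with the standard observable map via ``model_core`` simulation
    and normalisation; with ``noise_sd = 0`` the output equals the observed
    simulation exactly.
    """
    from .simulate import observe_conditions, default_observable_map

    c = config or GeneratorConfig()
    c.validate()
    omap = observable_map or default_observable_map(spec)
    dt = c.sample_interval
    t_rec = np.arange(-c.basal_window, c.horizon + dt / 2, dt)
    grids = {cond: t_rec for cond in protocols}
    observed = observe_conditions(spec, params, protocols, grids, omap,
                                  reference_condition=_reference_condition(protocols))
    curves = {}
    for (obs, cond), (t, y) in observed.items():
        curves[(obs, cond)] = (t, y)
    normalization = {obs: omap.modes[obs] for obs in omap.modes}
    cs = NoiselessCurveSet(curves=curves, normalization=normalization, config=c)
    return add_measurement_noise(cs, c)


def _reference_condition(protocols) -> str:
    # percent-of-max reference: the condition with the highest insulin dose.
    def dose(p) -> float:
        return max((ev.dose for ev in p.events if ev.kind == "insulin_dose"), default=0.0)

    return max(protocols, key=lambda k: dose(protocols[k]))
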