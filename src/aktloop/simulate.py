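"""Simulation of the signalling models: equilibration, stimulation protocols,
observable mapping, and one-phase decay fitting.

Every simulation starts from the basal (insulin-free) steady state, applies
the protocol's timed events (insulin steps, parameter nullings) by piecewise
integration with state continuity, and maps states to the measured
observables: PM-Akt recruitment (fold over the pre-stimulus baseline) and
the phospho read-outs (percent of the maximum of a reference condition).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import curve_fit

from . import _kinetics
from .models import (
    MEMBRANE_AKT_STATES,
    MOIETIES,
    STATES,
    ModelSpecification,
    ParameterSet,
    StimulusProtocol,
)

__all__ = [
    "Trajectory",
    "ObservableMap",
    "SimulationError",
    "SteadyStateError",
    "ZeroBasalError",
    "DegenerateDecayError",
    "basal_steady_state",
    "simulate",
    "observe",
    "observe_conditions",
    "default_observable_map",
    "fit_one_phase_decay",
]

_STATE_INDEX = {s: i for i, s in enumerate(STATES)}

# Reduced coordinates for steady-state root finding: one representative
# state per two-state moiety plus the four membrane Akt forms.
_FREE = [_STATE_INDEX[s] for s in (
    "IR_active", "IRS_active", "PIP3", "PDPK1_mem",
    "Akt_mem", "Akt_mem_pT309", "Akt_mem_pS474", "Akt_mem_pT309_pS474",
    "mTORC2_active", "pPRAS40",
)]


class SimulationError(RuntimeError):
    """The stiff solver failed on a protocol segment."""


class SteadyStateError(RuntimeError):
    """Basal steady-state search did not converge."""


class ZeroBasalError(ZeroDivisionError):
    """Fold-over-basal normalisation hit a zero basal signal."""


class DegenerateDecayError(RuntimeError):
    """A one-phase decay fit was requested on a non-decaying trace."""


@dataclass(frozen=True)
class Trajectory:
    """Simulated states on a time grid, with provenance."""

    t: np.ndarray = field(repr=False)
    states: np.ndarray = field(repr=False)      # shape (len(t), 18)
    spec: ModelSpecification
    params: ParameterSet
    protocol: StimulusProtocol
    basal_state: np.ndarray = field(repr=False)

    def state(self, name: str) -> np.ndarray:
        return self.states[:, _STATE_INDEX[name]]

    def moiety_totals(self) -> dict[str, np.ndarray]:
        return {
            m: self.states[:, [_STATE_INDEX[s] for s in states]].sum(axis=1)
            for m, states in MOIETIES.items()
        }

    def max_conservation_drift(self) -> float:
        """Largest relative drift of any moiety total along the trajectory."""
        drift = 0.0
        for tot in self.moiety_totals().values():
            ref = tot[0] if tot[0] != 0 else 1.0
            drift = max(drift, float(np.max(np.abs(tot - tot[0])) / abs(ref)))
        return drift


def _initial_guess() -> np.ndarray:
    y = np.zeros(_kinetics.N_STATES)
    y[_STATE_INDEX["IR_inactive"]] = 1.0
    y[_STATE_INDEX["IRS_inactive"]] = 1.0
    y[_STATE_INDEX["PIP2"]] = 1.0
    y[_STATE_INDEX["PDPK1_cyt"]] = 1.0
    y[_STATE_INDEX["Akt_cyt"]] = 1.0
    y[_STATE_INDEX["mTORC2_inactive"]] = 1.0
    y[_STATE_INDEX["PRAS40"]] = 1.0
    y[_STATE_INDEX["PTEN"]] = 1.0
    return y


def _expand(free: np.ndarray) -> np.ndarray:
    """Full state from reduced coordinates, enforcing unit moiety totals."""
    y = np.zeros(_kinetics.N_STATES)
    y[_FREE] = free
    y[_STATE_INDEX["IR_inactive"]] = 1.0 - y[_STATE_INDEX["IR_active"]]
    y[_STATE_INDEX["IRS_inactive"]] = 1.0 - y[_STATE_INDEX["IRS_active"]]
    y[_STATE_INDEX["PIP2"]] = 1.0 - y[_STATE_INDEX["PIP3"]]
    y[_STATE_INDEX["PDPK1_cyt"]] = 1.0 - y[_STATE_INDEX["PDPK1_mem"]]
    mem = sum(y[_STATE_INDEX[s]] for s in MEMBRANE_AKT_STATES)
    y[_STATE_INDEX["Akt_cyt"]] = 1.0 - mem
    y[_STATE_INDEX["mTORC2_inactive"]] = 1.0 - y[_STATE_INDEX["mTORC2_active"]]
    y[_STATE_INDEX["PRAS40"]] = 1.0 - y[_STATE_INDEX["pPRAS40"]]
    y[_STATE_INDEX["PTEN"]] = 1.0
    return y


def basal_steady_state(
    spec: ModelSpecification,
    params: ParameterSet,
    *,
    tol: float = 1e-9,
    t_equil: float = 2e4,
    fast: bool = False,
) -> np.ndarray:
    """Insulin-free steady state of the model.

    Solved by damped Newton iteration in reduced (moiety-eliminated)
    coordinates, warm-started from a short loose integration when the cold
    start fails.  The returned state satisfies
    ``||f(y)||_inf < tol * (1 + ||y||_inf)`` and lies exactly on the unit
    moiety totals.
    """
    K = params.vector()
    newton_tol = min(tol, 1e-12)
    # primary: closed-form cascade fixed point (full relative precision,
    # which the fold-over-basal normalisation requires)
    x, status = _kinetics.steady_state_cascade(K, spec.variant, 0.0, 0.5, 600, 1e-13)
    if status != 0:
        for start in (0.02, 0.3, 0.001, 0.1, 0.7):   # multi-start damped Newton
            x, status = _kinetics.steady_state_newton(
                np.full(_kinetics.N_FREE, start), K, spec.variant, 0.0, newton_tol, 60
            )
            if status == 0:
                break
    if status != 0 and not fast:
        y_eq, st_eq = _kinetics.equilibrate(_initial_guess(), K, spec.variant, 0.0,
                                            1e-4, 1e-7, t_equil, 3000)
        if st_eq == 0:
            x, status = _kinetics.steady_state_newton(
                np.clip(y_eq[_FREE], 0.0, 1.0), K, spec.variant, 0.0, newton_tol, 60
            )
            if status != 0:
                x = np.clip(y_eq[_FREE], 0.0, 1.0)

    y = _expand(np.clip(x, 0.0, 1.0))
    f = np.empty(_kinetics.N_STATES)
    _kinetics.rhs(y, K, spec.variant, 0.0, f)
    res = float(np.max(np.abs(f)))
    if res >= tol * (1.0 + float(np.max(np.abs(y)))):
        raise SteadyStateError(
            f"basal steady state did not converge: residual {res:.3e} (tol {tol:.1e})"
        )
    return y


def simulate(
    spec: ModelSpecification,
    params: ParameterSet,
    protocol: StimulusProtocol,
    t_grid: np.ndarray,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    basal: np.ndarray | None = None,
    max_steps: int = 100_000,
) -> Trajectory:
    """Piecewise integration of a stimulation protocol over ``t_grid``.

    Grid times at or before the first event are reported at the basal steady
    state.  Parameter-nulling events zero the named rate constants from the
    event time onward; state continuity holds across every event.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("time grid must be strictly increasing")
    for ev in protocol.events:
        if ev.time > t_grid[-1]:
            raise ValueError(f"event at t={ev.time} s outside the time grid")

    if basal is None:
        if protocol.pre_equilibrate:
            basal = basal_steady_state(spec, params, tol=1e-7)
        else:
            basal = _initial_guess()

    K = params.vector().copy()
    from .models import VECTOR_ORDER

    vec_index = {n: i for i, n in enumerate(VECTOR_ORDER)}
    ins = 0.0

    # Segment boundaries: event times (>=0) then the grid end.
    ev_times = sorted({ev.time for ev in protocol.events})
    boundaries = [t for t in ev_times if t < t_grid[-1]] + [t_grid[-1]]

    n = len(t_grid)
    states = np.empty((n, _kinetics.N_STATES))
    t0 = boundaries[0]
    pre = t_grid <= t0 + 1e-12
    states[pre] = basal
    y = basal.copy()
    t_cur = t0

    for i, t_next in enumerate(boundaries):
        # apply events scheduled at the segment start
        for ev in protocol.events:
            if abs(ev.time - t_cur) <= 1e-12:
                if ev.kind == "insulin_dose":
                    ins = ev.dose
                elif ev.kind == "parameter_null":
                    for name in ev.parameters:
                        if name not in params.values:
                            raise KeyError(
                                f"protocol nulls parameter {name!r} absent from variant "
                                f"{spec.variant}"
                            )
                        K[vec_index[name]] = 0.0
                elif ev.kind == "parameter_restore":
                    for name in ev.parameters:
                        K[vec_index[name]] = params.values[name]
        if i == 0:
            continue
        t_prev = boundaries[i - 1]
        mask = (t_grid > t_prev + 1e-12) & (t_grid <= t_next + 1e-12)
        seg_list = [t_prev] + list(t_grid[mask])
        if abs(seg_list[-1] - t_next) > 1e-12:
            seg_list.append(t_next)
        seg_out = np.array(seg_list)
        seg_states, status = _kinetics.integrate_segment(
            y, seg_out, K, spec.variant, ins, rtol, atol, max_steps
        )
        if status != 0:
            raise SimulationError(
                f"solver failed on segment [{t_prev}, {t_next}] s of variant {spec.variant}"
            )
        if mask.any():
            states[mask] = seg_states[1 : 1 + int(mask.sum())]
        y = seg_states[-1]
        t_cur = t_next

    # re-apply dangling events exactly at the grid end (no integration left)
    return Trajectory(t=t_grid, states=states, spec=spec, params=params,
                      protocol=protocol, basal_state=basal)


# ---------------------------------------------------------------------------
# Observables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ObservableMap:
    """Observable -> non-negative weighted sum of states + normalisation mode."""

    weights: Mapping[str, Mapping[str, float]]
    modes: Mapping[str, str]

    def __post_init__(self) -> None:
        for obs, w in self.weights.items():
            for state, wt in w.items():
                if state not in _STATE_INDEX:
                    raise KeyError(f"observable {obs!r} references unknown state {state!r}")
                if wt < 0:
                    raise ValueError(f"observable {obs!r}: weight for {state!r} must be >= 0")
            if self.modes[obs] not in ("fold_over_basal", "percent_of_max", "raw"):
                raise ValueError(f"unknown normalisation mode {self.modes[obs]!r}")

    def raw_trace(self, trajectory: Trajectory, observable: str) -> np.ndarray:
        w = self.weights[observable]
        idx = [_STATE_INDEX[s] for s in w]
        return trajectory.states[:, idx] @ np.array(list(w.values()))

    def raw_basal(self, trajectory: Trajectory, observable: str) -> float:
        w = self.weights[observable]
        idx = [_STATE_INDEX[s] for s in w]
        return float(trajectory.basal_state[idx] @ np.array(list(w.values())))


def default_observable_map(spec: ModelSpecification | None = None) -> ObservableMap:
    """PM-Akt recruitment plus the three phospho read-outs."""
    return ObservableMap(
        weights={
            "pm_akt": {s: 1.0 for s in MEMBRANE_AKT_STATES},
            "pakt_t309": {"Akt_mem_pT309": 1.0, "Akt_mem_pT309_pS474": 1.0},
            "pakt_s474": {"Akt_mem_pS474": 1.0, "Akt_mem_pT309_pS474": 1.0},
            "ppras40_t246": {"pPRAS40": 1.0},
        },
        modes={
            "pm_akt": "fold_over_basal",
            "pakt_t309": "percent_of_max",
            "pakt_s474": "percent_of_max",
            "ppras40_t246": "percent_of_max",
        },
    )


def observe(
    trajectory: Trajectory,
    omap: ObservableMap,
    *,
    reference: Trajectory | None = None,
) -> dict[str, np.ndarray]:
    """Normalised observable traces for one trajectory.

    ``fold_over_basal`` divides by the pre-stimulus (basal steady state)
    level, so the basal-window mean is exactly 1.  ``percent_of_max`` scales
    by the maximum of the same observable in the ``reference`` trajectory
    (the trajectory itself by default), putting the reference maximum at 100.
    """
    ref = reference if reference is not None else trajectory
    out: dict[str, np.ndarray] = {}
    for obs in omap.weights:
        trace = omap.raw_trace(trajectory, obs)
        mode = omap.modes[obs]
        if mode == "fold_over_basal":
            basal = omap.raw_basal(trajectory, obs)
            if basal <= 1e-300:
                raise ZeroBasalError(
                    f"observable {obs!r}: basal signal is zero; fold-over-basal undefined "
                    "(check the basal ligand constant L0)"
                )
            out[obs] = trace / basal
        elif mode == "percent_of_max":
            ref_trace = omap.raw_trace(ref, obs)
            m = float(ref_trace.max())
            if m <= 1e-300:
                raise ZeroBasalError(f"observable {obs!r}: reference maximum is zero")
            out[obs] = 100.0 * trace / m
        else:
            out[obs] = trace
    return out


def observe_conditions(
    spec: ModelSpecification,
    params: ParameterSet,
    protocols: Mapping[str, StimulusProtocol],
    grids: Mapping[str, np.ndarray],
    omap: ObservableMap,
    *,
    reference_condition: str,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    basal: np.ndarray | None = None,
) -> dict[tuple[str, str], tuple[np.ndarray, np.ndarray]]:
    """Simulate several conditions and normalise them jointly.

    Percent-of-max observables share the maximum of ``reference_condition``
    (the highest-dose condition in the training data), exactly mirroring how
    the data are normalised.
    """
    if reference_condition not in protocols:
        raise KeyError(f"reference condition {reference_condition!r} has no protocol")
    if basal is None and any(p.pre_equilibrate for p in protocols.values()):
        basal = basal_steady_state(spec, params, tol=1e-7)
    trajs = {
        cond: simulate(spec, params, protocols[cond], grids[cond],
                       rtol=rtol, atol=atol, basal=basal)
        for cond in protocols
    }
    ref = trajs[reference_condition]
    out: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for cond, traj in trajs.items():
        traces = observe(traj, omap, reference=ref)
        for obs, y in traces.items():
            out[(obs, cond)] = (traj.t, y)
    return out


# ---------------------------------------------------------------------------
# One-phase decay
# ---------------------------------------------------------------------------

def fit_one_phase_decay(
    t: np.ndarray, y: np.ndarray, t0: float
) -> tuple[float, float, float]:
    """Least-squares fit of ``y = plateau + amplitude * exp(-k (t - t0))``.

    Fits the points with ``t >= t0`` (at least four required).  Returns
    ``(k, plateau, amplitude)`` with k > 0; raises
    :class:`DegenerateDecayError` when the trace does not decay.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = t >= t0 - 1e-12
    ts, ys = t[mask] - t0, y[mask]
    if len(ts) < 4:
        raise ValueError(f"need >= 4 points after t0={t0}, got {len(ts)}")
    drop = ys[0] - ys[-1]
    spread = float(ys.max() - ys.min())
    if drop <= 0 or spread <= 0 or drop < 0.1 * spread:
        raise DegenerateDecayError(
            f"trace does not decay after t0={t0} (start {ys[0]:.4g}, end {ys[-1]:.4g})"
        )

    def model(tt, k, plateau, amp):
        return plateau + amp * np.exp(-k * tt)

    k0 = 3.0 / max(ts[-1], 1e-9)
    p0 = (k0, float(ys[-1]), float(ys[0] - ys[-1]))
    popt, _ = curve_fit(
        model, ts, ys, p0=p0,
        bounds=([1e-12, -np.inf, 0.0], [np.inf, np.inf, np.inf]),
        maxfev=20000,
    )
    k, plateau, amp = (float(v) for v in popt)
    if k <= 1e-10 or amp <= 0:
        raise DegenerateDecayError(f"degenerate decay fit: k={k:.3g}, amplitude={amp:.3g}")
    return k, plateau, amp
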