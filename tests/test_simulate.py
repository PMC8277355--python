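"""Simulation correctness: steady states, conservation, integrator accuracy,
observable normalisation, and decay fitting."""

import numpy as np
import pytest

from aktloop import _kinetics
from aktloop.models import (
    build_model,
    default_parameters,
    step_protocol,
)
from aktloop.simulate import (
    DegenerateDecayError,
    SimulationError,
    basal_steady_state,
    default_observable_map,
    fit_one_phase_decay,
    observe,
    simulate,
)

ALL_VARIANTS = list(range(1, 10))


def _perturbed_defaults(spec, rng, scale=0.5):
    """Random log-normal perturbation of the default rate constants."""
    p = default_parameters(spec)
    vals = {}
    for name, v in p.values.items():
        if name == "L0":
            vals[name] = v
        else:
            vals[name] = float(np.clip(v * 10 ** rng.normal(0.0, scale), 1e-3, 1e3))
    return p.with_values(vals)


class TestBasalSteadyState:
    @pytest.mark.parametrize("variant", ALL_VARIANTS)
    def test_residual_below_tolerance(self, variant):
        spec = build_model(variant)
        y = basal_steady_state(spec, default_parameters(spec), tol=1e-9)
        f = np.empty(_kinetics.N_STATES)
        _kinetics.rhs(y, default_parameters(spec).vector(), variant, 0.0, f)
        assert np.max(np.abs(f)) < 1e-9 * (1 + np.max(np.abs(y)))

    @pytest.mark.parametrize("variant", ALL_VARIANTS)
    def test_moiety_totals_are_unit(self, variant):
        spec = build_model(variant)
        y = basal_steady_state(spec, default_parameters(spec))
        traj_like = {
            "IR": y[0] + y[1], "IRS": y[2] + y[3], "PIP": y[4] + y[5],
            "PDPK1": y[6] + y[7], "Akt": y[8] + y[9] + y[10] + y[11] + y[12],
            "mTORC2": y[13] + y[14], "PRAS40": y[15] + y[16], "PTEN": y[17],
        }
        for name, total in traj_like.items():
            assert total == pytest.approx(1.0, abs=1e-12), name

    def test_agrees_with_long_time_integration(self):
        """Independent oracle: a 1e5 s zero-insulin integration."""
        spec = build_model(9)
        p = default_parameters(spec)
        y_ss = basal_steady_state(spec, p)
        y0 = np.zeros(_kinetics.N_STATES)
        y0[[0, 2, 4, 6, 8, 13, 15, 17]] = 1.0
        y_int, status = _kinetics.equilibrate(y0, p.vector(), 9, 0.0, 1e-10, 1e-13, 1e5)
        assert status == 0
        assert np.max(np.abs(y_ss - y_int)) < 1e-6


class TestSimulate:
    def test_zero_insulin_protocol_stays_at_steady_state(self):
        spec = build_model(9)
        p = default_parameters(spec)
        traj = simulate(spec, p, step_protocol(0.0), np.arange(-60.0, 1201.0, 15.0))
        drift = np.max(np.abs(traj.states - traj.states[0]), axis=0)
        assert np.max(drift) < 1e-8

    def test_pip3_monotone_after_pi3k_nulling(self):
        spec = build_model(9)
        p = default_parameters(spec)
        prot = step_protocol(0.0, null=("Kf3",))
        traj = simulate(spec, p, prot, np.arange(0.0, 601.0, 5.0))
        pip3 = traj.state("PIP3")
        assert np.all(np.diff(pip3) <= 1e-9)  # slack at solver noise level

    @pytest.mark.parametrize("variant", ALL_VARIANTS)
    def test_conservation_on_stimulated_trajectory(self, variant):
        spec = build_model(variant)
        p = default_parameters(spec)
        traj = simulate(spec, p, step_protocol(1.0), np.arange(-60.0, 1201.0, 15.0))
        assert traj.max_conservation_drift() < 1e-6
        assert np.min(traj.states) > -1e-8  # non-negativity within tolerance

    @pytest.mark.parametrize("variant", ALL_VARIANTS)
    def test_agrees_with_small_step_rk4(self, variant):
        """Brute-force oracle: fixed-step classical RK4 at dt = 0.01 s."""
        spec = build_model(variant)
        p = default_parameters(spec)
        grid = np.arange(0.0, 301.0, 15.0)
        basal = basal_steady_state(spec, p)
        traj = simulate(spec, p, step_protocol(1.0), grid, basal=basal)

        K = p.vector()
        y = basal.copy()
        dt = 0.01
        k1 = np.empty(18); k2 = np.empty(18); k3 = np.empty(18); k4 = np.empty(18)
        ref = [y.copy()]
        t = 0.0
        next_out = 15.0
        while t < 300.0 - 1e-9:
            _kinetics.rhs(y, K, variant, 1.0, k1)
            _kinetics.rhs(y + 0.5 * dt * k1, K, variant, 1.0, k2)
            _kinetics.rhs(y + 0.5 * dt * k2, K, variant, 1.0, k3)
            _kinetics.rhs(y + dt * k3, K, variant, 1.0, k4)
            y = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            t += dt
            if t >= next_out - 1e-9:
                ref.append(y.copy())
                next_out += 15.0
        ref = np.array(ref)
        err = np.max(np.abs(traj.states - ref) / (np.abs(ref) + 1e-9))
        assert err < 1e-4

    def test_solver_failure_names_segment(self):
        spec = build_model(9)
        p = default_parameters(spec)
        with pytest.raises(SimulationError, match=r"segment \[0.0, 300.0\]"):
            simulate(spec, p, step_protocol(1.0), np.array([0.0, 300.0]), max_steps=2)

    def test_feedback_removal_never_reduces_recruitment(self):
        """Variant 9: nulling the Akt feedback limbs raises PM-Akt pointwise."""
        spec = build_model(9)
        omap = default_observable_map()
        rng = np.random.default_rng(2024)
        grid = np.arange(0.0, 901.0, 30.0)
        checked = 0
        while checked < 50:
            p = _perturbed_defaults(spec, rng)
            try:
                basal_on = basal_steady_state(spec, p, tol=1e-7)
                t_on = simulate(spec, p, step_protocol(1.0), grid, basal=basal_on)
                p_off = p.null(["Ki2a", "Ki2b"])
                basal_off = basal_steady_state(spec, p_off, tol=1e-7)
                t_off = simulate(spec, p_off, step_protocol(1.0), grid, basal=basal_off)
            except Exception:
                continue
            pm_on = omap.raw_trace(t_on, "pm_akt")
            pm_off = omap.raw_trace(t_off, "pm_akt")
            assert np.all(pm_off >= pm_on - 1e-7)
            checked += 1


class TestObserve:
    def test_fold_over_basal_is_one_at_baseline(self):
        spec = build_model(9)
        p = default_parameters(spec)
        traj = simulate(spec, p, step_protocol(1.0), np.arange(-60.0, 601.0, 15.0))
        traces = observe(traj, default_observable_map())
        basal_part = traces["pm_akt"][traj.t <= 0]
        assert np.allclose(basal_part, 1.0, atol=1e-9)

    def test_percent_of_max_is_100_on_reference(self):
        spec = build_model(9)
        p = default_parameters(spec)
        grid = np.arange(-60.0, 601.0, 15.0)
        basal = basal_steady_state(spec, p)
        ref = simulate(spec, p, step_protocol(100.0), grid, basal=basal)
        low = simulate(spec, p, step_protocol(1.0), grid, basal=basal)
        tr_ref = observe(ref, default_observable_map(), reference=ref)
        tr_low = observe(low, default_observable_map(), reference=ref)
        for obs in ("pakt_t309", "pakt_s474", "ppras40_t246"):
            assert tr_ref[obs].max() == pytest.approx(100.0)
            assert tr_low[obs].max() <= 100.0 + 1e-9

    def test_pm_akt_is_sum_of_membrane_states(self):
        spec = build_model(9)
        p = default_parameters(spec)
        traj = simulate(spec, p, step_protocol(1.0), np.arange(0.0, 301.0, 15.0))
        omap = default_observable_map()
        manual = (traj.state("Akt_mem") + traj.state("Akt_mem_pT309")
                  + traj.state("Akt_mem_pS474") + traj.state("Akt_mem_pT309_pS474"))
        assert np.allclose(omap.raw_trace(traj, "pm_akt"), manual)


class TestOnePhaseDecay:
    def test_exact_recovery(self):
        t = np.arange(0.0, 600.0, 10.0)
        y = 1.2 + 2.5 * np.exp(-0.01 * (t - 100.0))
        k, plateau, amp = fit_one_phase_decay(t, np.where(t >= 100, y, 3.7), 100.0)
        assert k == pytest.approx(0.01, abs=1e-6)
        assert plateau == pytest.approx(1.2, abs=1e-6)
        assert amp == pytest.approx(2.5, abs=1e-6)

    def test_constant_trace_is_degenerate(self):
        t = np.arange(0.0, 300.0, 10.0)
        with pytest.raises(DegenerateDecayError):
            fit_one_phase_decay(t, np.full_like(t, 2.0), 0.0)

    def test_noisy_recovery_monte_carlo(self):
        """sd = 5% of amplitude: median relative error in k below 5%."""
        t = np.arange(0.0, 610.0, 15.0)
        true_k, plateau, amp = 0.01, 1.0, 3.0
        clean = plateau + amp * np.exp(-true_k * t)
        errs = []
        rng = np.random.default_rng(11)
        for _ in range(200):
            noisy = clean + rng.normal(0.0, 0.05 * amp, size=t.shape)
            k, _, _ = fit_one_phase_decay(t, noisy, 0.0)
            errs.append(abs(k - true_k) / true_k)
        assert np.median(errs) < 0.05
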