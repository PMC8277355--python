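"""Feature constraints of the synthetic time-course generator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import gammaln

from aktloop import GeneratorConfig, add_measurement_noise, generate_reference_curves
from aktloop.simulate import fit_one_phase_decay
from aktloop.synthetic import (
    COND_100NM,
    COND_1NM,
    COND_AKTI,
    COND_KD,
    COND_RAPA,
    COND_WORT,
    FeatureConstraintError,
    PM_AKT,
    PPRAS40,
    PS474,
    PT309,
)


class TestRecruitmentFeatures:
    def test_1nm_peaks_at_75s_on_default_grid(self, reference_curves):
        t, y = reference_curves.series(PM_AKT, COND_1NM)
        assert t[int(np.argmax(y))] == 75.0

    def test_1nm_settles_to_half_peak_amplitude_by_10min(self, reference_curves):
        t, y = reference_curves.series(PM_AKT, COND_1NM)
        peak = y.max() - 1.0
        at600 = y[int(np.searchsorted(t, 600.0))] - 1.0
        assert abs(at600 / peak - 0.5) < 1e-6

    def test_100nm_peak_amplitude_is_fourfold(self, reference_curves):
        _, y1 = reference_curves.series(PM_AKT, COND_1NM)
        t, y100 = reference_curves.series(PM_AKT, COND_100NM)
        i75 = int(np.searchsorted(t, 75.0))
        assert (y100[i75] - 1.0) / (y1.max() - 1.0) == pytest.approx(4.0, abs=1e-9)

    def test_100nm_has_dip_then_secondary_rise(self, reference_curves):
        t, y = reference_curves.series(PM_AKT, COND_100NM)
        post = y[t > 0]
        i_peak = int(np.argmax(post[:10]))
        tail = post[i_peak:]
        i_min = int(np.argmin(tail))
        assert 0 < i_min < len(tail) - 1
        assert tail[-1] > tail[i_min]

    def test_akt_inhibitor_monotone_with_threefold_amplitude(self, reference_curves):
        _, y1 = reference_curves.series(PM_AKT, COND_1NM)
        t, y = reference_curves.series(PM_AKT, COND_AKTI)
        assert np.all(np.diff(y[t >= 0]) >= 0)
        assert (y.max() - 1.0) / (y1.max() - 1.0) == pytest.approx(3.0, abs=1e-9)

    def test_kinase_dead_amplitude_ratio(self, reference_curves):
        _, y1 = reference_curves.series(PM_AKT, COND_1NM)
        _, y = reference_curves.series(PM_AKT, COND_KD)
        assert (y.max() - 1.0) / (y1.max() - 1.0) == pytest.approx(3.5, abs=1e-9)

    def test_rapamycin_identical_to_control(self, reference_curves):
        _, y1 = reference_curves.series(PM_AKT, COND_1NM)
        _, yr = reference_curves.series(PM_AKT, COND_RAPA)
        assert np.array_equal(y1, yr)

    def test_all_curves_at_baseline_before_stimulus(self, reference_curves):
        for (obs, cond) in reference_curves.keys():
            t, y = reference_curves.series(obs, cond)
            base = reference_curves.baseline(obs)
            assert np.allclose(y[t <= 0], base), (obs, cond)

    def test_wortmannin_condition_decays_at_configured_rate(self, reference_curves):
        cfg = reference_curves.config
        t, y = reference_curves.series(PM_AKT, COND_WORT)
        k, plateau, amp = fit_one_phase_decay(t, y, cfg.washout_time)
        assert k == pytest.approx(cfg.washout_decay_rate, rel=1e-4)


class TestPhosphoFeatures:
    def test_t309_peaks_before_s474(self, reference_curves):
        t3, y3 = reference_curves.series(PT309, COND_100NM)
        t4, y4 = reference_curves.series(PS474, COND_100NM)
        assert t3[int(np.argmax(y3))] < t4[int(np.argmax(y4))]

    def test_phospho_reference_max_is_100(self, reference_curves):
        for obs in (PT309, PS474, PPRAS40):
            _, y = reference_curves.series(obs, COND_100NM)
            assert y.max() == pytest.approx(100.0)

    def test_phospho_bounded_and_overshoot_pattern(self, reference_curves):
        for obs in (PT309, PS474, PPRAS40):
            for cond in (COND_1NM, COND_100NM):
                t, y = reference_curves.series(obs, cond)
                assert np.all((y >= 0) & (y <= 100.0 + 1e-12)), (obs, cond)
        t, y = reference_curves.series(PPRAS40, COND_100NM)
        assert np.all(np.diff(y[t >= 0]) >= 0)  # saturating, no overshoot
        _, y3 = reference_curves.series(PT309, COND_100NM)
        assert y3[-1] < y3.max()                # overshoot present


class TestRandomizedConfigs:
    """Feature constraints hold exactly for every feasible config."""

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        peak=st.sampled_from([45.0, 60.0, 75.0, 90.0]),
        frac=st.floats(0.25, 0.65),
        ratio=st.floats(2.0, 6.0),
        akti=st.floats(1.5, 5.0),
    )
    def test_constraints_hold_for_random_config(self, peak, frac, ratio, akti):
        cfg = GeneratorConfig(
            peak_time_target=peak,
            steady_fraction_target=frac,
            dose_peak_ratio=ratio,
            akt_inhibitor_amplitude_ratio=akti,
        )
        try:
            curves = generate_reference_curves(cfg)
        except FeatureConstraintError:
            return  # infeasible corner: raised explicitly, never silent
        t, y = curves.series(PM_AKT, COND_1NM)
        assert t[int(np.argmax(y))] == peak
        at600 = y[int(np.searchsorted(t, 600.0))] - 1.0
        assert abs(at600 / (y.max() - 1.0) - frac) < 1e-6
        _, y100 = curves.series(PM_AKT, COND_100NM)
        ipk = int(np.searchsorted(t, peak))
        assert (y100[ipk] - 1.0) / (y.max() - 1.0) == pytest.approx(ratio, abs=1e-9)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="multiple of"):
            GeneratorConfig(peak_time_target=77.0).validate()
        with pytest.raises(ValueError, match="steady_fraction"):
            GeneratorConfig(steady_fraction_target=1.5).validate()
        with pytest.raises(ValueError, match="rise_rate"):
            GeneratorConfig(rise_rate=-1.0).validate()


class TestNoiseModel:
    def test_zero_noise_identity(self, reference_curves):
        cfg = GeneratorConfig(noise_sd=0.0)
        ds = add_measurement_noise(reference_curves, cfg)
        for obs, cond, sub in ds.iter_series():
            t_ref, y_ref = reference_curves.series(obs, cond)
            assert np.allclose(sub["mean"].to_numpy(), y_ref)
            assert np.all(sub["sem"].to_numpy() == 0.0)

    def test_seeded_reproducibility(self, reference_curves):
        a = add_measurement_noise(reference_curves, GeneratorConfig(seed=7))
        b = add_measurement_noise(reference_curves, GeneratorConfig(seed=7))
        c = add_measurement_noise(reference_curves, GeneratorConfig(seed=8))
        assert a.equals(b)
        assert not a.equals(c)

    def test_sem_matches_sampling_theory(self, reference_curves):
        """Mean SEM over many seeds equals sigma * c4(n) / sqrt(n)."""
        n = 9
        sd_frac = 0.1
        sems = []
        for seed in range(1000):
            cfg = GeneratorConfig(noise_sd=sd_frac, n_replicates=n, seed=seed)
            ds = add_measurement_noise(reference_curves, cfg)
            sub = ds.series(PM_AKT, COND_1NM)
            sems.append(sub["sem"].mean())
        vals = np.concatenate(
            [reference_curves.series(PM_AKT, c)[1]
             for (o, c) in reference_curves.keys() if o == PM_AKT]
        )
        sigma_abs = sd_frac * (vals.max() - vals.min())
        c4 = math.exp(
            0.5 * math.log(2.0 / (n - 1)) + gammaln(n / 2) - gammaln((n - 1) / 2)
        )
        expected = sigma_abs * c4 / math.sqrt(n)
        assert np.mean(sems) == pytest.approx(expected, rel=0.05)
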