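"""Vesicle-depletion synapse dynamics and the two-hemifield model."""

import numpy as np
import pytest

from rgcsubunits import (
    DynamicSynapseParams,
    calibration_filters,
    calibration_synapse,
    effective_release_rate,
    ei_temporal_offset,
    initial_occupancy,
    phi,
    run_paired_pulse,
    simulate_hemifield,
    steady_state_occupancy,
    vesicle_integrate,
)

DT = 1.0 / 600


def euler_oracle(drive, p, n_init, dt, refine=100):
    """Brute-force forward Euler at dt/refine with zero-order-hold drive."""
    n = np.empty(drive.size)
    n[0] = cur = n_init
    h = dt / refine
    for k in range(1, drive.size):
        d = drive[k - 1]
        for _ in range(refine):
            cur = cur + h * ((1 - cur) * p.krec - p.b * p.krel * cur * d)
        n[k] = cur
    return n


class TestPhi:
    @pytest.mark.parametrize("x,gamma,expected", [
        (2.0, 0.25, 2.0),
        (-2.0, 0.25, -0.5),
        (0.0, 0.25, 0.0),
    ])
    def test_piecewise_values(self, x, gamma, expected):
        assert phi(x, gamma) == pytest.approx(expected)

    def test_gamma_one_is_identity(self):
        x = np.linspace(-5, 5, 41)
        np.testing.assert_array_equal(phi(x, 1.0), x)

    def test_gamma_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            phi(1.0, 1.5)


class TestInitialOccupancy:
    def test_no_baseline_release_fills_the_pool(self):
        p = DynamicSynapseParams(e0=0.0)
        assert initial_occupancy(p) == 1.0

    def test_unit_release_recovery_balance_gives_half(self):
        # b*e0*krel/krec = 1
        p = DynamicSynapseParams(krec=2.0, krel=10.0, b=1.0, e0=0.2)
        assert initial_occupancy(p) == pytest.approx(0.5)

    def test_closed_form_is_ode_fixed_point(self):
        """dn/dt vanishes at n0 under constant baseline drive, zero inhibition."""
        p = calibration_synapse()
        n0 = initial_occupancy(p)
        residual = (1 - n0) * p.krec - p.b * p.krel * n0 * p.e0
        assert abs(residual) < 1e-12

    def test_coupled_fixed_point_matches_closed_form_with_consistent_r0(self):
        p = DynamicSynapseParams(e0=0.5, r0=None)  # r0 defaults to e0*(1-n0)
        assert steady_state_occupancy(p) == pytest.approx(initial_occupancy(p), abs=1e-12)


class TestVesicleIntegrate:
    def test_zero_drive_closed_form(self):
        p = DynamicSynapseParams(krec=1.0, krel=10.0, e0=0.0)
        t = np.arange(0, 1.0 + 1e-9, 1e-3)
        n = vesicle_integrate(np.zeros(t.size), p, n_init=0.5, dt=1e-3)
        np.testing.assert_allclose(n, 1 - 0.5 * np.exp(-t), atol=1e-9)
        assert n[-1] == pytest.approx(0.81606, abs=1e-4)

    def test_constant_baseline_drive_holds_fixed_point(self):
        p = calibration_synapse()
        n0 = initial_occupancy(p)
        n = vesicle_integrate(np.full(500, p.e0), p, n_init=n0, dt=DT)
        np.testing.assert_allclose(n, n0, atol=1e-10)

    def test_matches_fine_euler_oracle_on_seeded_drives(self):
        p = calibration_synapse()
        rng = np.random.default_rng(1234)
        for _ in range(10):
            drive = rng.uniform(0.0, 3.0, 120)
            n = vesicle_integrate(drive, p, n_init=0.5, dt=1e-3)
            ref = euler_oracle(drive, p, 0.5, 1e-3)
            assert np.max(np.abs(n - ref)) < 1e-4

    def test_occupancy_stays_in_unit_interval(self):
        p = calibration_synapse()
        rng = np.random.default_rng(7)
        drive = rng.uniform(0.0, 50.0, 400)
        for n_init in (0.0, 0.37, 1.0):
            n = vesicle_integrate(drive, p, n_init=n_init, dt=DT)
            assert np.all(n >= 0.0) and np.all(n <= 1.0)

    def test_negative_drive_rejected(self):
        with pytest.raises(ValueError):
            vesicle_integrate(np.array([0.0, -1.0]), calibration_synapse(), 0.5, DT)


class TestEffectiveReleaseRate:
    def test_no_inhibition_leaves_release_unscaled(self):
        assert effective_release_rate(0.0, calibration_synapse()) == 1.0

    def test_beta_zero_decouples(self):
        p = calibration_synapse(beta=0.0)
        assert effective_release_rate(5.0, p) == 1.0

    def test_higher_beta_suppresses_more(self):
        m4 = effective_release_rate(0.5, calibration_synapse(beta=4.0))
        m1 = effective_release_rate(0.5, calibration_synapse(beta=1.0))
        assert m4 < m1

    def test_monotone_decreasing_in_drive(self):
        p = calibration_synapse()
        i = np.linspace(0, 10, 50)
        assert np.all(np.diff(effective_release_rate(i, p)) < 0)


class TestSimulateHemifield:
    def test_zero_contrast_gives_stationary_resting_traces(self, filters):
        p = calibration_synapse()
        z = np.zeros(int(1.0 / DT))
        tr = simulate_hemifield(z, z, filters, p, DT)
        n_ss = steady_state_occupancy(p)
        np.testing.assert_allclose(tr.n[0], n_ss, atol=1e-9)
        np.testing.assert_allclose(tr.i_total, 0.0, atol=1e-12)
        expected = n_ss * max(0.0, float(phi(p.e0, p.gamma))) + p.r0
        np.testing.assert_allclose(tr.e_total, expected, atol=1e-9)

    def test_occupancy_bounded_for_strong_stimuli(self, filters):
        p = calibration_synapse(alpha=0.8, beta=8.0)
        rng = np.random.default_rng(11)
        s = np.clip(rng.normal(0, 0.6, int(2.0 / DT)), -1, 1)
        tr = simulate_hemifield(s, -s, filters, p, DT)
        for n in tr.n:
            assert np.all(n >= 0) and np.all(n <= 1)

    def test_linear_regime_reduces_to_ln_model(self):
        """gamma=1, alpha=0 and a frozen pool leave a pure LN cascade."""
        from rgcsubunits import TemporalFilter

        # freeze the pool via krec >> any release rate
        p = DynamicSynapseParams(krec=1e8, krel=1e-8, b=1.0, gamma=1.0,
                                 alpha=0.0, beta=0.0, e0=10.0, r0=0.0)
        filters = (TemporalFilter(gain=0.5, polarity=-1),
                   TemporalFilter(gain=1.0, polarity=1))
        t = np.arange(int(4.0 / DT)) * DT
        s = 0.2 * np.sin(2 * np.pi * 4.0 * t)
        tr = simulate_hemifield(s, s, filters, p, DT)
        y = tr.e_total[int(2.0 / DT):] - np.mean(tr.e_total[int(2.0 / DT):])
        # harmonic distortion at 8 Hz relative to the 4 Hz fundamental
        tt = np.arange(y.size) * DT
        f1 = np.abs(np.sum(y * np.exp(-2j * np.pi * 4.0 * tt)))
        f2 = np.abs(np.sum(y * np.exp(-2j * np.pi * 8.0 * tt)))
        assert f2 / f1 < 1e-6

    def test_grating_flash_suppression_then_rebound(self, filters):
        for alpha in (0.4, 0.8):
            p = calibration_synapse(alpha=alpha)
            seg = lambda d, c: np.full(int(round(d / DT)), c)
            s1 = np.concatenate([seg(0.5, 0), seg(0.5, 0.9), seg(1.5, 0)])
            s2 = np.concatenate([seg(0.5, 0), seg(0.5, -0.9), seg(1.5, 0)])
            tr = simulate_hemifield(s1, s2, filters, p, DT)
            i0, i1 = int(0.65 / DT), int(1.0 / DT)
            assert tr.e_total[i0:i1].mean() < tr.baseline_e
            assert tr.e_total[i1:i1 + int(0.5 / DT)].max() > tr.baseline_e

    def test_inhibition_leads_excitation_by_half_f2_cycle(self, filters):
        """Opposing-hemifield contrast reversal at 2 Hz: I precedes E by ~half
        of the 250 ms frequency-doubled response cycle."""
        p = calibration_synapse()
        cyc = 0.5
        t = np.arange(int(4 * cyc / DT)) * DT
        mod = np.where((t % cyc) < cyc / 2, 0.9, -0.9)
        tr = simulate_hemifield(mod, -mod, filters, p, DT)
        skip = int(cyc / DT)
        for method in ("xcorr", "com"):
            lag = ei_temporal_offset(tr.e_total[skip:], tr.i_total[skip:],
                                     cyc / 2, DT, method=method)
            assert 0.35 < abs(lag) <= 0.5

    def test_mismatched_stimuli_rejected(self, filters):
        with pytest.raises(ValueError):
            simulate_hemifield(np.zeros(10), np.zeros(11), filters, calibration_synapse(), DT)


class TestPairedPulse:
    def test_instant_recovery_removes_facilitation(self, filters):
        p = calibration_synapse(alpha=0.8, beta=8.0, krec=1e4, n0=0.12)
        _, ppr = run_paired_pulse(p, filters)
        assert ppr == pytest.approx(1.0, abs=0.01)

    def test_no_inhibition_means_no_facilitation(self, filters):
        _, ppr = run_paired_pulse(calibration_synapse(alpha=0.0), filters)
        assert ppr <= 1.0

    def test_facilitation_decays_with_interval_toward_plateau(self, filters):
        p = calibration_synapse(alpha=0.8, beta=8.0)
        pprs = [run_paired_pulse(p, filters, interval_duration=iv)[1]
                for iv in (0.2, 0.5, 2.0, 5.0)]
        assert all(a > b for a, b in zip(pprs, pprs[1:]))
        assert pprs[-1] == pytest.approx(1.0, abs=0.05)
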