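"""Spatiotemporal subunit model: fields, pooling, readout and NLI experiments."""

from dataclasses import replace

import numpy as np
import pytest

from rgcsubunits import (
    GaussianRFParams,
    default_config,
    ganglion_readout,
    image_vs_disc_experiment,
    make_synthetic_patch,
    simulate_field,
)
from rgcsubunits.filters import apply_filter
from rgcsubunits.spatiotemporal import (
    _flash_field,
    excitatory_field,
    inhibitory_field,
    presynaptic_pool,
)
from rgcsubunits.stimuli import StimulusField
from rgcsubunits.subunits import SubunitGrid
from rgcsubunits.synapse import steady_state_occupancy

DT = 1.0 / 120


@pytest.fixture(scope="module")
def cfg1d():
    return default_config(alpha=0.8, dims=1)


@pytest.fixture(scope="module")
def cfg2d():
    return default_config(alpha=0.8, dims=2)


def uniform_field(c, n=121, nt=90, dx=6.6, dims=1):
    shape = (n, nt) if dims == 1 else (n, n, nt)
    return StimulusField(np.full(shape, float(c)), dx=dx, dt=DT)


def flash_series(c, n=121, nt=120, dx=6.6):
    v = np.zeros((n, nt))
    v[:, 40:80] = c
    return StimulusField(v, dx=dx, dt=DT)


class TestInhibitoryField:
    def test_zero_stimulus_is_silent(self, cfg1d):
        i = inhibitory_field(uniform_field(0.0), cfg1d)
        np.testing.assert_array_equal(i, 0.0)

    def test_uniform_step_drives_all_subunits_identically(self, cfg1d):
        i = inhibitory_field(flash_series(0.6), cfg1d)
        np.testing.assert_allclose(i, np.broadcast_to(i[:1, :], i.shape), atol=1e-9)

    def test_single_subunit_impulse_response_is_rectified_kernel(self, cfg1d):
        """A one-frame uniform flash reproduces the rectified temporal kernel
        scaled by the subunit's spatial weight."""
        n, nt = 121, 240
        v = np.zeros((n, nt))
        v[:, 10] = 1.0
        stim = StimulusField(v, dx=6.6, dt=DT)
        single = replace(cfg1d, inh_grid=SubunitGrid(np.array([0.0]), 20.0, 50.0))
        got = inhibitory_field(stim, single)[0]
        # oracle: spatial weight for a uniform frame, then direct convolution
        from rgcsubunits.spatiotemporal import _spatial_drive

        coeff = _spatial_drive(uniform_field(1.0), single.inh_grid, single.inh_params)[0, 0]
        drive = np.zeros(nt)
        drive[10] = coeff
        expected = np.maximum(0.0, apply_filter(single.inh_filter, drive, DT))
        np.testing.assert_allclose(got, expected, atol=1e-10)


class TestPresynapticPool:
    def test_alpha_zero_silences_the_route(self, cfg1d):
        cfg0 = default_config(alpha=0.0, dims=1)
        i = np.ones((cfg0.inh_grid.n, 5))
        np.testing.assert_array_equal(presynaptic_pool(i, cfg0), 0.0)

    def test_colocated_subunit_dominates(self):
        cfg = default_config(alpha=0.5, dims=1)
        cfg = replace(cfg, inh_grid=SubunitGrid(np.array([0.0]), 20.0, 50.0))
        i = np.full((1, 4), 2.0)
        out = presynaptic_pool(i, cfg)
        np.testing.assert_allclose(out, 0.5 * 2.0, atol=1e-12)

    def test_two_equidistant_subunits_average_by_hand(self):
        cfg = default_config(alpha=0.5, dims=1)
        cfg = replace(cfg, inh_grid=SubunitGrid(np.array([-30.0, 30.0]), 60.0, 50.0),
                      exc_grid=SubunitGrid(np.array([0.0]), 60.0, 50.0))
        i = np.vstack([np.full(4, 1.5), np.full(4, 1.5)])
        out = presynaptic_pool(i, cfg)
        # equal weights normalised to one: alpha * (0.5*1.5 + 0.5*1.5)
        np.testing.assert_allclose(out, 0.5 * 1.5, atol=1e-12)


class TestExcitatoryField:
    def test_uniform_stimulus_keeps_subunits_identical(self, cfg1d):
        stim = flash_series(-0.5)
        i_eff = presynaptic_pool(inhibitory_field(stim, cfg1d), cfg1d)
        e_out, n = excitatory_field(stim, i_eff, cfg1d)
        np.testing.assert_allclose(e_out, np.broadcast_to(e_out[:1, :], e_out.shape), atol=1e-9)
        assert np.all(n >= 0) and np.all(n <= 1)

    def test_reduces_to_static_ln_when_dynamics_removed(self):
        """alpha=0, frozen pool and gamma=1 leave filter + rectification + r0."""
        # krec huge and n0 ~ 1 freeze the pool without inflating the tonic drive
        cfg = default_config(alpha=0.0, dims=1,
                             overrides={"synapse": {"krec": 1e8, "krel": 1.0, "gamma": 1.0,
                                                    "n0": 1 - 1e-7}})
        stim = flash_series(-0.7)
        i_eff = np.zeros((cfg.exc_grid.n, stim.n_time))
        e_out, n = excitatory_field(stim, i_eff, cfg)
        from rgcsubunits.spatiotemporal import _spatial_drive

        p = cfg.synapse
        drive = _spatial_drive(stim, cfg.exc_grid, cfg.exc_params)
        expected = np.maximum(0.0, p.e0 + apply_filter(cfg.exc_filter, drive, stim.dt)) + p.r0
        np.testing.assert_allclose(e_out, expected, atol=1e-5 * p.e0)


class TestGanglionReadout:
    def test_strong_inhibition_floors_the_rate(self, cfg1d):
        e = np.full(10, 1.0)
        i = np.full(10, 100.0)
        assert np.all(ganglion_readout(e, i, cfg1d, threshold=0.0) == 0.0)

    def test_no_inhibition_passes_scaled_excitation(self, cfg1d):
        e = np.full(10, 2.0)
        out = ganglion_readout(e, np.zeros(10), cfg1d, threshold=0.0)
        np.testing.assert_allclose(out, cfg1d.readout_gain * 2.0)

    def test_arithmetic(self, cfg1d):
        out = ganglion_readout(np.array([1.0]), np.array([1.0]), cfg1d,
                               scale_by_alpha=False, threshold=0.0)
        assert out[0] == pytest.approx(3.0 - 1.0)


class TestSimulateField:
    def test_translation_equivariance(self):
        """Shifting stimulus and subunit grids together leaves totals unchanged."""
        cfg = default_config(alpha=0.8, dims=1)
        rng = np.random.default_rng(3)
        n = 181
        profile = rng.uniform(-0.5, 0.5, n)
        shift_px = 5  # 33 um at 6.6 um/px
        v = np.zeros((n, 60))
        v[:, 20:40] = profile[:, None]
        stim = StimulusField(v, dx=6.6, dt=DT)
        v2 = np.zeros((n, 60))
        v2[:, 20:40] = np.roll(profile, shift_px)[:, None]
        stim2 = StimulusField(v2, dx=6.6, dt=DT)
        shift = shift_px * 6.6
        cfg2 = replace(
            cfg,
            exc_grid=SubunitGrid(cfg.exc_grid.positions + shift, cfg.exc_grid.spacing,
                                 cfg.exc_grid.pooling_sigma),
            inh_grid=SubunitGrid(cfg.inh_grid.positions + shift, cfg.inh_grid.spacing,
                                 cfg.inh_grid.pooling_sigma),
        )
        a = simulate_field(stim, cfg)
        b = simulate_field(stim2, cfg2)
        # pooling weights are position-dependent; compare per-subunit outputs
        np.testing.assert_allclose(b.e_out, a.e_out, atol=1e-10)
        np.testing.assert_allclose(b.i, a.i, atol=1e-10)

    def test_rate_nonnegative_and_occupancy_bounded(self, cfg2d):
        pair = make_synthetic_patch(0.9, -0.3, seed=17, extent=400.0)
        stim = _flash_field(pair.patch, pair.dx, DT, 0.2, 0.2, 0.4)
        tr = simulate_field(stim, cfg2d)
        assert np.all(tr.rate >= 0)
        assert np.all(tr.n >= 0) and np.all(tr.n <= 1)

    def test_resting_state_is_stationary(self, cfg1d):
        tr = simulate_field(uniform_field(0.0), cfg1d)
        n_ss = steady_state_occupancy(cfg1d.synapse)
        np.testing.assert_allclose(tr.n, n_ss, atol=1e-9)
        assert np.ptp(tr.e_total) < 1e-9


class TestImageVsDisc:
    def test_uniform_patch_equals_its_disc_exactly(self, cfg2d):
        pair = make_synthetic_patch(0.0, -0.35, extent=400.0)
        res = image_vs_disc_experiment([pair], cfg2d, dt=DT)[0]
        assert res.onset_nli == 0.0
        assert res.offset_nli == 0.0
        assert res.r_image_on == pytest.approx(res.r_disc_on, rel=1e-12)

    @pytest.mark.parametrize("seed", [5, 17, 23])
    def test_structured_zero_mean_patch_suppressed_at_onset_enhanced_at_offset(self, cfg2d, seed):
        """A high-contrast zero-mean patch recruits strong inhibition: firing
        drops below the spontaneous level at onset (its disc is just the
        background) and rebounds above it at offset."""
        rf = GaussianRFParams(50.0)
        pair = make_synthetic_patch(1.0, 0.0, seed=seed, extent=400.0, rf=rf,
                                    base_amplitude=0.7)
        res = image_vs_disc_experiment([pair], cfg2d, dt=DT)[0]
        assert res.onset_nli < -0.5
        assert res.offset_nli > 0

    def test_grid_refinement_stability(self):
        """Halving subunit spacing moves the NLI by less than 2 points."""
        pair = make_synthetic_patch(1.0, -0.3, seed=23, extent=400.0,
                                    base_amplitude=0.7)
        coarse = default_config(alpha=0.8, dims=2)
        fine = default_config(alpha=0.8, dims=2,
                              overrides={"spatial": {"exc_spacing": 10.0, "inh_spacing": 10.0}})
        a = image_vs_disc_experiment([pair], coarse, dt=DT)[0]
        b = image_vs_disc_experiment([pair], fine, dt=DT)[0]
        assert abs(a.onset_nli - b.onset_nli) < 0.02
        assert abs(a.offset_nli - b.offset_nli) < 0.02

    def test_disc_equivalence_identity_for_linearised_model(self):
        """With whole-RF Gaussian subunits and every nonlinearity removed, the
        model cannot distinguish a patch from its linear-equivalent disc."""
        from rgcsubunits.spatiotemporal import _spatial_drive

        rf = GaussianRFParams(50.0)
        pair = make_synthetic_patch(0.9, -0.25, seed=31, extent=440.0, rf=rf)
        cfg = default_config(dims=2)
        # single whole-RF subunit, truncated+renormalised like the disc weights
        from rgcsubunits.receptive_field import rf_weights
        from rgcsubunits.stimuli import grid_coords

        x = grid_coords(pair.patch.shape[0], pair.dx)
        w = rf_weights((x, x), rf).ravel()
        resp_patch = float(w @ pair.patch.ravel())
        resp_disc = float(w @ np.full(pair.patch.size, pair.disc_intensity))
        assert resp_patch == pytest.approx(resp_disc, rel=1e-9, abs=1e-12)
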