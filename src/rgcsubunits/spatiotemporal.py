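"""Two-stream spatiotemporal subunit model with presynaptic inhibition.

Grids of excitatory and inhibitory subunits tile the receptive field.  Each
inhibitory subunit is a static LN unit: DoG spatial profile, temporal
filter, half-wave rectification.  Each excitatory subunit is a dynamic LN
unit: Gaussian spatial profile and Off-sign temporal filter, subtractive
presynaptic inhibition pooled from nearby inhibitory subunits with Gaussian
weights w(x_i, y_j) = exp(-(x_i - y_j)^2 / (2 sigma_inh^2)), an output
nonlinearity, and vesicle-depletion gain dynamics (see
:mod:`rgcsubunits.synapse`).  The ganglion cell reads out Gaussian-weighted
sums of both populations: rate = [readout_gain * E_total - I_total]_+.

This is the machinery behind the image-versus-disc experiments: flashing
natural-image-like patches and their linear-equivalent discs, integrating
the readout in onset/offset windows, and summarising spatial selectivity
with the nonlinearity index (NLI).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .filters import TemporalFilter, apply_filter
from .metrics import nli, offset_nli_with_exclusion
from .receptive_field import GaussianRFParams
from .stimuli import PatchPair, StimulusField, grid_coords
from .subunits import SubunitGrid, SubunitRFParams, subunit_weight_matrix
from .synapse import (
    DynamicSynapseParams,
    effective_release_rate,
    integrate_coupled,
    phi,
    steady_state_occupancy,
)

__all__ = [
    "SpatioTemporalConfig",
    "SpatioTraces",
    "NLIResult",
    "default_config",
    "inhibitory_field",
    "presynaptic_pool",
    "excitatory_field",
    "ganglion_readout",
    "simulate_field",
    "image_vs_disc_experiment",
    "alpha_sweep",
    "subunit_size_ratio_sweep",
]


@dataclass(frozen=True)
class SpatioTemporalConfig:
    exc_params: SubunitRFParams
    inh_params: SubunitRFParams
    exc_grid: SubunitGrid
    inh_grid: SubunitGrid
    synapse: DynamicSynapseParams
    exc_filter: TemporalFilter
    inh_filter: TemporalFilter
    presyn_pool_sigma: float | None = None  # defaults to inh sigma_center
    readout_gain: float = 3.0
    spont_rate: float = 0.5
    substeps: int = 4

    @property
    def pool_sigma(self) -> float:
        return self.presyn_pool_sigma if self.presyn_pool_sigma is not None else self.inh_params.sigma_center


@dataclass
class SpatioTraces:
    """Population time series from a spatiotemporal simulation."""

    t: np.ndarray
    e_out: np.ndarray   # (n_exc, nt) per-subunit excitatory output
    n: np.ndarray       # (n_exc, nt) vesicle occupancy
    i: np.ndarray       # (n_inh, nt) rectified inhibitory subunit output
    e_total: np.ndarray
    i_total: np.ndarray
    rate: np.ndarray
    dt: float
    baseline_rate: float


@dataclass
class NLIResult:
    """Onset/offset nonlinearity indices for one patch/disc pair."""

    patch_id: int
    onset_nli: float
    offset_nli: float
    excluded_offset: bool
    r_image_on: float
    r_disc_on: float
    r_image_off: float
    r_disc_off: float


def default_config(alpha: float | None = None, beta: float | None = None,
                   size_ratio: float | None = None, dims: int = 2,
                   overrides: dict | None = None) -> SpatioTemporalConfig:
    """Calibration-preset spatiotemporal configuration.

    ``size_ratio`` rescales the inhibitory subunit (centre and surround, and
    the presynaptic pooling sigma with them) to ``ratio`` times the
    excitatory subunit size.
    """
    from .presets import calibration_filters, calibration_synapse, validate_config

    cfg = validate_config(overrides)
    sp = cfg["spatial"]
    if beta is None:
        beta = sp["beta"]
    exc_params = SubunitRFParams(sp["exc_sigma"], 3.0 * sp["exc_sigma"], 0.0)
    inh_sigma = sp["inh_sigma"]
    inh_params = SubunitRFParams(inh_sigma, sp["inh_surround_ratio"] * inh_sigma, sp["inh_delta"])
    if size_ratio is not None:
        inh_params = SubunitRFParams(
            size_ratio * sp["exc_sigma"],
            sp["inh_surround_ratio"] * size_ratio * sp["exc_sigma"],
            sp["inh_delta"],
        )
    maker = SubunitGrid.make_2d if dims == 2 else SubunitGrid.make_1d
    exc_grid = maker(spacing=sp["exc_spacing"], pooling_sigma=sp["pooling_sigma"], extent_sigmas=1.6)
    inh_grid = maker(spacing=sp["inh_spacing"], pooling_sigma=sp["pooling_sigma"], extent_sigmas=1.6)
    exc_filter, inh_filter = calibration_filters(overrides)
    exc_filter = replace(exc_filter, gain=sp["exc_gain"], kernel_length=0.0)
    inh_filter = replace(inh_filter, gain=sp["inh_gain"], kernel_length=0.0)
    synapse = calibration_synapse(alpha=alpha, beta=beta, overrides=overrides)
    return SpatioTemporalConfig(
        exc_params=exc_params,
        inh_params=inh_params,
        exc_grid=exc_grid,
        inh_grid=inh_grid,
        synapse=synapse,
        exc_filter=exc_filter,
        inh_filter=inh_filter,
        readout_gain=cfg["simulation"]["readout_gain"],
        substeps=cfg["simulation"]["substeps"],
    )


def _spatial_drive(stim: StimulusField, grid: SubunitGrid, p: SubunitRFParams) -> np.ndarray:
    """(n_subunits, nt) spatial inner products, contrast-normalised units."""
    w = subunit_weight_matrix(stim.x, grid, p, stim.dx, normalize="center")
    frames = stim.values.reshape(-1, stim.n_time)
    return w @ frames


def inhibitory_field(stim: StimulusField, cfg: SpatioTemporalConfig) -> np.ndarray:
    """Rectified inhibitory subunit outputs I_j(t), shape (n_inh, nt).

    Space-then-time separable convolution with the inhibitory DoG profile
    and temporal filter, half-wave rectified per subunit and time step.
    """
    drive = _spatial_drive(stim, cfg.inh_grid, cfg.inh_params)
    return np.maximum(0.0, apply_filter(cfg.inh_filter, drive, stim.dt))


def presynaptic_pool(i_traces: np.ndarray, cfg: SpatioTemporalConfig) -> np.ndarray:
    """Per-excitatory-subunit effective inhibition I_eff_i(t).

    Gaussian pooling over inhibitory subunits (sigma = the inhibitory
    subunit centre scale), weights normalised to sum to one per excitatory
    subunit so the pooled drive is grid-density invariant, scaled by alpha.
    """
    xp = cfg.exc_grid.positions
    yp = cfg.inh_grid.positions
    if xp.ndim == 1:
        d2 = (xp[:, None] - yp[None, :]) ** 2
    else:
        d2 = np.sum((xp[:, None, :] - yp[None, :, :]) ** 2, axis=2)
    w = np.exp(-d2 / (2.0 * cfg.pool_sigma**2))
    w /= w.sum(axis=1, keepdims=True)
    return cfg.synapse.alpha * (w @ i_traces)


def excitatory_field(
    stim: StimulusField, i_eff: np.ndarray, cfg: SpatioTemporalConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subunit excitatory outputs E~_i(t) and occupancies n_i(t).

    E_raw is the filtered stimulus plus the tonic drive e0; presynaptic
    inhibition subtracts from the drive and divisively scales the vesicle
    release rate; the output is n * max(0, E) + r0 with n from the
    depletion-recovery ODE.
    """
    p = cfg.synapse
    drive = _spatial_drive(stim, cfg.exc_grid, cfg.exc_params)
    e_raw = p.e0 + apply_filter(cfg.exc_filter, drive, stim.dt)
    e = phi(e_raw - i_eff, p.gamma)
    e_pos = np.maximum(0.0, e)
    mult = effective_release_rate(i_eff, p)
    n = integrate_coupled(e_pos, mult, p, steady_state_occupancy(p), stim.dt, substeps=cfg.substeps)
    return n * e_pos + p.r0, n


def ganglion_readout(e_total: np.ndarray, i_total: np.ndarray, cfg: SpatioTemporalConfig,
                     scale_by_alpha: bool = True, threshold: float | None = None) -> np.ndarray:
    """Rectified spike-rate proxy: [readout_gain * E_total - alpha * I_total - theta]_+.

    alpha is a global glycinergic strength: it scales the direct (readout)
    inhibition together with the presynaptic route, so alpha = 0 emulates a
    complete block of glycinergic transmission (the strychnine condition);
    ``scale_by_alpha=False`` restores an alpha-independent direct route.
    The spike threshold theta maps the resting drive to a small spontaneous
    rate (``cfg.spont_rate``), so windowed rate integrals behave like spike
    counts rather than riding on the tonic drive pedestal; pass
    ``threshold=0.0`` for the bare rectified difference.
    """
    a = cfg.synapse.alpha if scale_by_alpha else 1.0
    if threshold is None:
        p = cfg.synapse
        e_base = steady_state_occupancy(p) * p.e0 + p.r0
        threshold = max(0.0, cfg.readout_gain * e_base - cfg.spont_rate)
    return np.maximum(0.0, cfg.readout_gain * e_total - a * i_total - threshold)


def simulate_field(stim: StimulusField, cfg: SpatioTemporalConfig) -> SpatioTraces:
    """Run the full model on a stimulus field (zero-contrast history assumed).

    The simulation starts from the resting fixed point (uniform background),
    which is exact because a zero-contrast past contributes nothing to the
    filter convolutions.
    """
    i_traces = inhibitory_field(stim, cfg)
    i_eff = presynaptic_pool(i_traces, cfg)
    e_out, n = excitatory_field(stim, i_eff, cfg)
    e_total = cfg.exc_grid.pooling_weights @ e_out
    i_total = cfg.inh_grid.pooling_weights @ i_traces
    rate = ganglion_readout(e_total, i_total, cfg)
    p = cfg.synapse
    e_base = steady_state_occupancy(p) * p.e0 + p.r0
    base_rate = min(cfg.spont_rate, cfg.readout_gain * e_base)
    return SpatioTraces(
        t=stim.t, e_out=e_out, n=n, i=i_traces, e_total=e_total,
        i_total=i_total, rate=rate, dt=stim.dt, baseline_rate=base_rate,
    )


def _flash_field(frame: np.ndarray, dx: float, dt: float, pre: float, flash: float, post: float) -> StimulusField:
    frame = np.atleast_2d(np.asarray(frame, dtype=float))
    n_pre, n_on, n_post = (int(round(d / dt)) for d in (pre, flash, post))
    values = np.zeros(frame.shape + (n_pre + n_on + n_post,))
    values[..., n_pre:n_pre + n_on] = frame[..., None]
    return StimulusField(values, dx=dx, dt=dt)


def _window_response(rate: np.ndarray, dt: float, start: float, duration: float) -> float:
    """Windowed integral of the (non-negative) readout rate: a spike-count analogue."""
    i0 = int(round(start / dt))
    return float(np.sum(rate[i0:i0 + int(round(duration / dt))]) * dt)


def image_vs_disc_experiment(
    pairs: list[PatchPair],
    cfg: SpatioTemporalConfig,
    flash_duration: float = 0.2,
    pre: float = 0.3,
    post: float | None = None,
    dt: float = 1.0 / 120,
    offset_exclusion_threshold: float = 0.0,
) -> list[NLIResult]:
    """Flash each patch and its linear-equivalent disc; compute onset/offset NLIs.

    The response scalar is the time-integral of the readout rate above its
    resting level in the window (onset = the flash; offset = an equal window
    from stimulus offset), floored at zero — a spike-count analogue.  The
    offset exclusion rule zeroes the offset NLI when both offset responses
    fall below ``offset_exclusion_threshold`` (disabled at 0, the default,
    where responses are continuous rate integrals rather than spike counts).
    """
    if post is None:
        post = flash_duration + 0.3
    results = []
    for k, pair in enumerate(pairs):
        resp = {}
        for label, frame in (("image", pair.patch), ("disc", np.full_like(pair.patch, pair.disc_intensity))):
            stim = _flash_field(frame, pair.dx, dt, pre, flash_duration, post)
            tr = simulate_field(stim, cfg)
            resp[label + "_on"] = _window_response(tr.rate, dt, pre, flash_duration)
            resp[label + "_off"] = _window_response(tr.rate, dt, pre + flash_duration, flash_duration)
        onset = nli(resp["image_on"], resp["disc_on"])
        if offset_exclusion_threshold > 0:
            offset, excluded = offset_nli_with_exclusion(
                resp["image_off"], resp["disc_off"], offset_exclusion_threshold
            )
        else:
            offset, excluded = nli(resp["image_off"], resp["disc_off"]), False
        results.append(NLIResult(
            patch_id=k, onset_nli=onset, offset_nli=offset, excluded_offset=excluded,
            r_image_on=resp["image_on"], r_disc_on=resp["disc_on"],
            r_image_off=resp["image_off"], r_disc_off=resp["disc_off"],
        ))
    return results


def mean_nlis(results: list[NLIResult]) -> tuple[float, float]:
    """(mean onset NLI, mean offset NLI) over patch/disc pairs."""
    return (
        float(np.mean([r.onset_nli for r in results])),
        float(np.mean([r.offset_nli for r in results])),
    )


def alpha_sweep(pairs, alphas, beta: float | None = None, dims: int = 2,
                overrides: dict | None = None, **kw) -> dict[float, list[NLIResult]]:
    """Image-vs-disc experiment repeated over presynaptic-inhibition strengths."""
    return {
        a: image_vs_disc_experiment(
            pairs, default_config(alpha=a, beta=beta, dims=dims, overrides=overrides), **kw)
        for a in alphas
    }


def subunit_size_ratio_sweep(ratios, pairs, alpha: float | None = None, beta: float | None = None,
                             dims: int = 2, overrides: dict | None = None, **kw) -> dict[float, list[NLIResult]]:
    """Image-vs-disc experiment over inhibitory/excitatory subunit size ratios."""
    return {
        r: image_vs_disc_experiment(
            pairs, default_config(alpha=alpha, beta=beta, size_ratio=r, dims=dims,
                                  overrides=overrides), **kw)
        for r in ratios
    }
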