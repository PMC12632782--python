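"""Dynamic vesicle-depletion synapse and the two-hemifield temporal model.

The excitatory pathway is a dynamic LN cascade: linearly filtered drive,
subtractive presynaptic inhibition, a piecewise-linear output nonlinearity
``phi``, and multiplicative scaling by the vesicle occupancy ``n(t)`` of a
depletion-and-recovery pool,

    dn/dt = (1 - n) * Krec - b * Krel * m(I_eff) * n * E_tilde(t),

with output ``E_tilde = n * max(0, E) + R0``.  Presynaptic inhibition acts
twice: subtractively on the drive (strength ``alpha``) and divisively on the
release rate through ``m(I_eff) = 1 / (1 + beta * I_eff)``, so that strong
inhibition halts release and lets the pool refill — the mechanism behind
paired-pulse facilitation and offset rebound in Off-transient cells.

The inhibitory pathway is a static LN model (filter + half-wave
rectification) with no vesicle dynamics.

The two-hemifield model collapses space: each hemifield holds one excitatory
and one inhibitory subunit, and each excitatory subunit receives the combined
inhibition of both hemifields, ``I_eff = alpha * (I_L + I_R)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .filters import TemporalFilter, apply_filter

__all__ = [
    "DynamicSynapseParams",
    "ModelTraces",
    "phi",
    "initial_occupancy",
    "steady_state_occupancy",
    "effective_release_rate",
    "vesicle_integrate",
    "integrate_coupled",
    "simulate_hemifield",
    "run_paired_pulse",
]


@dataclass(frozen=True)
class DynamicSynapseParams:
    """Parameters of the excitatory pathway's gain dynamics.

    krec, krel : vesicle recovery / release rate constants (1/s).
    b          : release gain (dimensionless).
    gamma      : rectification ratio, slope of phi on the negative side.
    r0         : tonic additive output offset (drive units).
    alpha      : global presynaptic inhibition strength (>= 0).
    beta       : inhibition sensitivity of the release rate (>= 0).
    e0         : baseline excitatory drive (drive units); sets the resting
                 occupancy n0 = 1 / (1 + b*e0*krel/krec).
    """

    krec: float = 2.0
    krel: float = 10.0
    b: float = 1.0
    gamma: float = 0.5
    alpha: float = 0.4
    beta: float = 4.0
    e0: float = 0.4666666666666667
    r0: float | None = None

    def __post_init__(self):
        if min(self.krec, self.krel) <= 0 or self.b <= 0:
            raise ValueError("rates krec, krel and gain b must be positive")
        if not 0 < self.gamma <= 1:
            raise ValueError("gamma must lie in (0, 1]")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if self.e0 < 0:
            raise ValueError("e0 must be non-negative")
        if self.r0 is None:
            # Consistency default: with r0 = e0*(1 - n0) the resting state
            # n = n0, E_tilde = e0 is an exact fixed point of the ODE.
            object.__setattr__(self, "r0", self.e0 * (1.0 - initial_occupancy(self)))
        if self.r0 < 0:
            raise ValueError("r0 must be non-negative")


@dataclass
class ModelTraces:
    """Time series produced by the two-hemifield simulation (reported from t=0)."""

    t: np.ndarray
    stim: tuple[np.ndarray, np.ndarray]
    e_raw: tuple[np.ndarray, np.ndarray]
    i: tuple[np.ndarray, np.ndarray]
    n: tuple[np.ndarray, np.ndarray]
    e_out: tuple[np.ndarray, np.ndarray]
    e_total: np.ndarray
    i_total: np.ndarray
    rate: np.ndarray
    dt: float
    baseline_e: float

    def __post_init__(self):
        for nj in self.n:
            if np.any(nj < -1e-12) or np.any(nj > 1 + 1e-12):
                raise ValueError("occupancy left [0, 1]")


def phi(x, gamma: float):
    """Piecewise-linear output nonlinearity: gamma*x for x<0, x for x>=0."""
    if not 0 < gamma <= 1:
        raise ValueError("gamma must lie in (0, 1]")
    x = np.asarray(x, dtype=float)
    return np.where(x < 0, gamma * x, x)


def initial_occupancy(p: DynamicSynapseParams) -> float:
    """Resting occupancy n0 = 1 / (1 + b*e0*krel/krec).

    Fixed point of the vesicle ODE under constant baseline release drive e0
    with zero baseline inhibition.
    """
    return 1.0 / (1.0 + p.b * p.e0 * p.krel / p.krec)


def steady_state_occupancy(p: DynamicSynapseParams) -> float:
    """Zero-stimulus fixed point of the *coupled* ODE.

    Solves (1-n)*krec = b*krel*n*(n*e0 + r0); coincides with
    :func:`initial_occupancy` under the default r0 = e0*(1-n0).
    """
    a = p.b * p.krel * p.e0
    bb = p.krec + p.b * p.krel * p.r0
    # conjugate form of the positive quadratic root: stable when a*krec << bb^2
    return 2.0 * p.krec / (bb + np.sqrt(bb * bb + 4.0 * a * p.krec))


def effective_release_rate(i_eff, p: DynamicSynapseParams):
    """Divisive release-rate multiplier m = 1/(1 + beta*I_eff), in (0, 1]."""
    i_eff = np.asarray(i_eff, dtype=float)
    if np.any(i_eff < 0):
        raise ValueError("effective inhibitory drive must be non-negative")
    return 1.0 / (1.0 + p.beta * i_eff)


def vesicle_integrate(
    drive: np.ndarray,
    p: DynamicSynapseParams,
    n_init: float,
    dt: float,
    substeps: int = 4,
) -> np.ndarray:
    """Integrate dn/dt = (1-n)*krec - b*krel*n*drive(t) for an exogenous drive.

    The drive is held constant over each sample, which makes the per-step
    exponential update exact for this linear-in-n ODE.  Returns n at the
    sample times of ``drive`` (n[0] = n_init).
    """
    drive = np.asarray(drive, dtype=float)
    if np.any(drive < 0):
        raise ValueError("release drive must be non-negative")
    if not 0 <= n_init <= 1:
        raise ValueError("n_init must lie in [0, 1]")
    lam = p.krec + p.b * p.krel * drive
    decay = np.exp(-lam * dt)
    n_inf = p.krec / lam
    n = np.empty_like(drive)
    n[0] = n_init
    cur = float(n_init)
    for k in range(1, drive.size):
        cur = n_inf[k - 1] + (cur - n_inf[k - 1]) * decay[k - 1]
        n[k] = cur
    return n

def integrate_coupled(
    e_pos: np.ndarray,
    mult: np.ndarray,
    p: DynamicSynapseParams,
    n_init: float,
    dt: float,
    substeps: int = 4,
    check_stability: bool = True,
) -> np.ndarray:
    """Integrate the occupancy ODE with the self-coupled drive E_tilde = n*e_pos + r0.

    ``e_pos`` is max(0, E) (rectified post-nonlinearity drive) and ``mult``
    the release-rate multiplier; both sampled on the simulation grid, with
    leading axis = subunits (vectorised) or 1-D for a single pathway.
    Exponential-Euler substeps freeze E_tilde at the current occupancy, which
    keeps n in (0, 1] unconditionally; a step-halving check guards accuracy.
    Output shape matches ``e_pos`` (always 2-D internally).
    """
    e_pos = np.atleast_2d(np.asarray(e_pos, dtype=float))
    mult = np.atleast_2d(np.asarray(mult, dtype=float))
    mult = np.broadcast_to(mult, e_pos.shape)
    n_sub, nt = e_pos.shape
    h = dt / substeps

    def _run(hh, nsub):
        n = np.empty((n_sub, nt))
        cur = np.full(n_sub, float(n_init))
        n[:, 0] = cur
        for k in range(1, nt):
            ep, m = e_pos[:, k - 1], mult[:, k - 1]
            c = p.b * p.krel * m
            # equilibrium of (1-n)krec = c*n*(n*ep + r0) for this sample's drive
            a = c * ep
            bb = p.krec + c * p.r0
            # stable conjugate form of the positive quadratic root
            n_star = 2.0 * p.krec / (bb + np.sqrt(bb * bb + 4.0 * a * p.krec))
            lam = p.krec + c * (2.0 * n_star * ep + p.r0)  # linearised rate at n*
            for _ in range(nsub):
                cur = n_star + (cur - n_star) * np.exp(-lam * hh)
            n[:, k] = cur
        return n

    n = _run(h, substeps)
    if check_stability and nt > 1:
        n2 = _run(h / 2.0, 2 * substeps)
        err = float(np.max(np.abs(n - n2)))
        if err > 5e-3:
            raise RuntimeError(
                f"occupancy integration not converged at dt={dt:g} "
                f"(step-halving change {err:.2e}); reduce dt or raise substeps"
            )
    return n


def _hemifield_core(s_l, s_r, exc_filter, inh_filter, p, dt, substeps=4):
    stim = np.vstack([s_l, s_r])
    i_traces = np.maximum(0.0, apply_filter(inh_filter, stim, dt))
    i_eff = p.alpha * (i_traces[0] + i_traces[1])
    mult = effective_release_rate(i_eff, p)
    e_raw = p.e0 + apply_filter(exc_filter, stim, dt)
    e = phi(e_raw - i_eff[None, :], p.gamma)
    e_pos = np.maximum(0.0, e)
    n0 = steady_state_occupancy(p)
    n = integrate_coupled(e_pos, mult[None, :], p, n0, dt, substeps=substeps)
    n = np.atleast_2d(n)
    e_out = n * e_pos + p.r0
    return stim, e_raw, i_traces, n, e_out


def simulate_hemifield(
    stim_left: np.ndarray,
    stim_right: np.ndarray,
    filters: tuple[TemporalFilter, TemporalFilter],
    p: DynamicSynapseParams,
    dt: float,
    settle: float | None = None,
    readout_gain: float = 3.0,
    substeps: int = 4,
) -> ModelTraces:
    """Simulate the two-hemifield temporal model.

    ``stim_left``/``stim_right`` are Weber-contrast time series sharing ``dt``
    (t=0 at their first sample).  ``filters`` is the (excitatory, inhibitory)
    pair.  A zero-contrast settling segment is prepended so that traces start
    from the resting fixed point; it must out-last both the filter memory and
    the occupancy relaxation time, and the settled baseline is verified.
    """
    s_l = np.asarray(stim_left, dtype=float)
    s_r = np.asarray(stim_right, dtype=float)
    if s_l.shape != s_r.shape:
        raise ValueError("hemifield stimuli must share the time grid")
    exc_filter, inh_filter = filters
    if settle is None:
        settle = 3.0 / p.krec + max(exc_filter.kernel_length, inh_filter.kernel_length)
    n_settle = int(round(settle / dt))
    pad = np.zeros(n_settle)
    stim, e_raw, i_traces, n, e_out = _hemifield_core(
        np.concatenate([pad, s_l]), np.concatenate([pad, s_r]),
        exc_filter, inh_filter, p, dt, substeps=substeps,
    )
    # settled-baseline check: occupancy must be stationary entering t=0
    if n_settle > 2 and abs(n[0, n_settle - 1] - n[0, n_settle - 2]) > 1e-6 * dt / 1e-3:
        raise RuntimeError("baseline not settled before stimulus onset; increase settle")
    sl = slice(n_settle, None)
    e_total = 0.5 * (e_out[0, sl] + e_out[1, sl])
    i_total = 0.5 * (i_traces[0, sl] + i_traces[1, sl])
    rate = np.maximum(0.0, readout_gain * e_total - i_total)
    baseline_e = float(np.mean(e_out[:, max(0, n_settle - int(0.1 / dt)):n_settle]))
    t = np.arange(s_l.size) * dt
    return ModelTraces(
        t=t,
        stim=(s_l, s_r),
        e_raw=(e_raw[0, sl], e_raw[1, sl]),
        i=(i_traces[0, sl], i_traces[1, sl]),
        n=(n[0, sl], n[1, sl]),
        e_out=(e_out[0, sl], e_out[1, sl]),
        e_total=e_total,
        i_total=i_total,
        rate=rate,
        dt=dt,
        baseline_e=baseline_e,
    )


def run_paired_pulse(
    p: DynamicSynapseParams,
    filters: tuple[TemporalFilter, TemporalFilter],
    pulse_contrast: float = -0.9,
    pulse_duration: float = 0.3,
    interval_contrast: float = 0.0,
    interval_duration: float = 0.5,
    pre: float = 0.5,
    post: float = 1.0,
    dt: float = 1.0 / 600,
    substeps: int = 4,
):
    """Paired-pulse protocol on the two-hemifield model (uniform stimulus).

    Two identical contrast pulses separated by an intervening contrast step;
    returns ``(traces, ppr)`` where ``ppr`` is the pulse-2 / pulse-1 ratio of
    baseline-subtracted peak excitatory output (baseline = mean over the final
    100 ms before pulse 1).
    """
    from .metrics import paired_pulse_ratio

    def seg(dur, c):
        return np.full(int(round(dur / dt)), float(c))

    s = np.concatenate([
        seg(pre, 0.0),
        seg(pulse_duration, pulse_contrast),
        seg(interval_duration, interval_contrast),
        seg(pulse_duration, pulse_contrast),
        seg(post, 0.0),
    ])
    traces = simulate_hemifield(s, s, filters, p, dt, substeps=substeps)
    t1 = pre
    t2 = pre + pulse_duration + interval_duration
    # peak search window: pulse plus a filter-delay margin
    win = pulse_duration + 0.2
    ppr = paired_pulse_ratio(
        traces.e_total,
        dt=dt,
        pulse1_window=(t1, win),
        pulse2_window=(t2, win),
        baseline_window=(t1 - 0.1, 0.1),
    )
    return traces, ppr
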