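"""Parametric biphasic temporal filters.

The temporal kernels of both pathways are modelled as a difference of two
low-pass cascades (gamma-like lobes), the standard parametric form for
transient retinal impulse responses.  The kernel is normalised so that the
peak of its unit-contrast step response equals ``gain``: a full-contrast
step therefore produces a drive excursion of ``gain`` in drive units.

Off-pathway polarity is ``polarity=-1``: a negative (dark) contrast step
produces a positive drive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

__all__ = ["TemporalFilter", "apply_filter"]


def _lowpass_cascade(t: np.ndarray, tau: float, n_stages: int) -> np.ndarray:
    """Impulse response of ``n_stages`` identical first-order stages, unit area."""
    from scipy.special import gammaln

    tt = np.clip(t, 0.0, None)
    log_k = (n_stages - 1) * np.log(np.where(tt > 0, tt, 1.0)) - tt / tau
    log_norm = n_stages * np.log(tau) + gammaln(n_stages)
    out = np.exp(log_k - log_norm)
    out[tt <= 0] = 0.0
    if n_stages == 1:
        out[t >= 0] = np.exp(-np.clip(t[t >= 0], 0, None) / tau) / tau
    return out


@dataclass(frozen=True)
class TemporalFilter:
    """Biphasic difference-of-low-pass-cascades temporal kernel.

    Parameters
    ----------
    tau_rise : float
        Time constant (s) of the positive lobe's low-pass cascade.
    tau_decay : float
        Time constant (s) of the delayed negative (undershoot) lobe.
    undershoot : float
        Relative weight of the undershoot lobe (0 = monophasic).
    gain : float
        Peak drive produced by a unit-contrast step.
    polarity : int
        +1 for On-sign, -1 for Off-sign (dark contrast -> positive drive).
    delay : float
        Pure transport delay (s) prepended to the kernel.
    n_stages : int
        Number of low-pass stages per lobe (sets kernel smoothness).
    adapt_strength : float
        Slow-adaptation depth in [0, 1): fraction by which the sustained
        step response sags over ``adapt_tau`` seconds (0 = no adaptation).
    adapt_tau : float
        Time constant (s) of the slow sag.
    """

    tau_rise: float = 0.030
    tau_decay: float = 0.080
    undershoot: float = 0.3
    gain: float = 1.0
    polarity: int = -1
    delay: float = 0.0
    n_stages: int = 3
    adapt_strength: float = 0.0
    adapt_tau: float = 2.0
    kernel_length: float = field(default=0.0)

    def __post_init__(self):
        if self.tau_rise <= 0 or self.tau_decay <= 0:
            raise ValueError("filter time constants must be positive")
        if not 0 <= self.undershoot < 1:
            raise ValueError("undershoot must lie in [0, 1)")
        if not 0 <= self.adapt_strength < 1:
            raise ValueError("adapt_strength must lie in [0, 1)")
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be +1 or -1")
        if self.kernel_length == 0.0:
            length = self.delay + self.n_stages * (4.0 * self.tau_rise + 6.0 * self.tau_decay)
            if self.adapt_strength > 0:
                length += 6.0 * self.adapt_tau
            object.__setattr__(self, "kernel_length", length)

    def kernel(self, dt: float) -> np.ndarray:
        """Discrete kernel sampled at ``dt``; convolve with a contrast series
        and multiply by ``dt`` to obtain drive (see :func:`apply_filter`)."""
        n = int(np.ceil(self.kernel_length / dt)) + 1
        t = np.arange(n) * dt - self.delay
        k = _lowpass_cascade(t, self.tau_rise, self.n_stages)
        if self.undershoot > 0:
            k = k - self.undershoot * _lowpass_cascade(t, self.tau_decay, self.n_stages)
        if self.adapt_strength > 0:
            # high-pass sag: subtract a slow low-passed copy of the kernel
            slow = _lowpass_cascade(t, self.adapt_tau, 1)
            k = k - self.adapt_strength * fftconvolve(k, slow)[: k.size] * dt
        step = np.cumsum(k) * dt
        peak = np.max(np.abs(step))
        if peak <= 0:
            raise ValueError("degenerate kernel: flat step response")
        k = k * (self.gain / peak) * self.polarity
        tail = np.max(np.abs(k[-max(2, n // 50):]))
        if tail > 1e-4 * np.max(np.abs(k)):
            raise ValueError("kernel_length too short: kernel has not decayed")
        return k

    def step_response(self, dt: float, duration: float) -> np.ndarray:
        """Drive produced by a unit-contrast step held for ``duration``."""
        nt = int(round(duration / dt))
        return apply_filter(self, np.ones(nt), dt)[:nt]


def apply_filter(filt: TemporalFilter, series: np.ndarray, dt: float) -> np.ndarray:
    """Causal convolution of a contrast series with the filter kernel.

    ``series`` may be 1-D (time) or 2-D (units x time); filtering acts along
    the last axis and the output is truncated to the input length.
    """
    k = filt.kernel(dt)
    x = np.atleast_2d(np.asarray(series, dtype=float))
    out = fftconvolve(x, k[None, :], axes=1)[:, : x.shape[1]] * dt
    return out[0] if np.ndim(series) == 1 else out
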