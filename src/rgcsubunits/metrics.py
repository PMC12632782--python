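"""Summary statistics for simulated and recorded responses.

Nonlinearity index (NLI), paired-pulse ratio, frequency-doubled (F2)
amplitude, excitation-inhibition temporal offset, charge transfer and I/E
ratio — the quantities used to characterise nonlinear spatial integration
and short-term synaptic dynamics in alpha retinal ganglion cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ResponseWindow",
    "nli",
    "offset_nli_with_exclusion",
    "paired_pulse_ratio",
    "f2_amplitude",
    "ei_temporal_offset",
    "charge_transfer",
    "ie_ratio",
]


@dataclass(frozen=True)
class ResponseWindow:
    """A (start, duration) analysis window with its baseline window, in seconds."""

    start: float
    duration: float
    baseline_start: float = 0.0
    baseline_duration: float = 0.0

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("window duration must be positive")
        b_end = self.baseline_start + self.baseline_duration
        if self.baseline_duration > 0 and self.baseline_start < self.start + self.duration and b_end > self.start:
            raise ValueError("baseline window overlaps the response window")

    def slice(self, dt: float) -> slice:
        i0 = int(round(self.start / dt))
        return slice(i0, i0 + int(round(self.duration / dt)))


def _window_slice(window, dt):
    start, duration = window
    i0 = int(round(start / dt))
    i1 = i0 + int(round(duration / dt))
    return slice(i0, i1)


def nli(r_image: float, r_disc: float) -> float:
    """Nonlinearity index (r_image - r_disc) / (r_image + r_disc).

    Positive: stronger response to the structured image; negative: stronger
    response to its linear-equivalent disc.  Defined as 0 when both responses
    are zero.
    """
    if r_image < 0 or r_disc < 0:
        raise ValueError("responses must be non-negative")
    total = r_image + r_disc
    if total == 0:
        return 0.0
    return (r_image - r_disc) / total


def offset_nli_with_exclusion(
    r_image_off: float, r_disc_off: float, threshold: float = 3.0
) -> tuple[float, bool]:
    """Offset NLI with the weak-response exclusion rule.

    When the offset response is below ``threshold`` (3 spikes by default) for
    *both* the image and the disc, the offset NLI is set to 0 and flagged as
    excluded; if either response clears the threshold the plain NLI applies.
    """
    if r_image_off < 0 or r_disc_off < 0:
        raise ValueError("responses must be non-negative")
    if r_image_off < threshold and r_disc_off < threshold:
        return 0.0, True
    return nli(r_image_off, r_disc_off), False


def paired_pulse_ratio(
    trace: np.ndarray,
    dt: float,
    pulse1_window: tuple[float, float],
    pulse2_window: tuple[float, float],
    baseline_window: tuple[float, float],
) -> float:
    """Pulse-2 / pulse-1 ratio of baseline-subtracted peak amplitudes.

    Windows are (start, duration) in seconds relative to the trace origin.
    Raises if the pulse-1 peak does not rise above baseline (ratio undefined).
    """
    trace = np.asarray(trace, dtype=float)
    base = float(np.mean(trace[_window_slice(baseline_window, dt)]))
    p1 = float(np.max(trace[_window_slice(pulse1_window, dt)])) - base
    p2 = float(np.max(trace[_window_slice(pulse2_window, dt)])) - base
    if p1 <= 0:
        raise ValueError("pulse-1 peak does not exceed baseline; PPR undefined")
    return p2 / p1


def f2_amplitude(trace: np.ndarray, fundamental: float, dt: float) -> float:
    """Fourier amplitude at twice the fundamental over an integer cycle count.

    A pure sinusoid A*sin(2*pi*(2*fundamental)*t) returns A.  The trace is
    truncated to whole cycles of the fundamental; at least two are required.
    """
    trace = np.asarray(trace, dtype=float)
    per = 1.0 / fundamental
    n_cycles = int(np.floor(trace.size * dt / per + 1e-9))
    if n_cycles < 2:
        raise ValueError("trace must span at least two full cycles")
    n = int(round(n_cycles * per / dt))
    x = trace[:n]
    t = np.arange(n) * dt
    c = np.sum(x * np.exp(-2j * np.pi * (2.0 * fundamental) * t))
    return float(2.0 * np.abs(c) / n)


def _com_phase(x: np.ndarray, cycle_len: int) -> float:
    """Circular centre of mass (in cycles) of a non-negative cyclic profile."""
    ph = 2 * np.pi * np.arange(cycle_len) / cycle_len
    z = np.sum(x * np.exp(1j * ph))
    if np.abs(z) == 0:
        raise ValueError("flat trace: centre of mass undefined")
    return float(np.angle(z) / (2 * np.pi))


def ei_temporal_offset(
    exc: np.ndarray,
    inh: np.ndarray,
    cycle: float,
    dt: float,
    method: str = "xcorr",
) -> float:
    """Normalised timing offset between excitation and inhibition, in cycles.

    Positive values mean inhibition leads excitation.  ``method='xcorr'`` uses
    the argmax of the circular cross-correlation; ``method='com'`` compares
    per-cycle centres of mass of the baseline-subtracted, floored traces.
    Both series must span an integer number of cycles; the result is wrapped
    into (-0.5, 0.5], so a half-cycle shift reports +0.5.
    """
    exc = np.asarray(exc, dtype=float)
    inh = np.asarray(inh, dtype=float)
    cl = int(round(cycle / dt))
    if exc.size != inh.size or exc.size % cl or exc.size == 0:
        raise ValueError("series must share an integer number of cycles")
    if np.ptp(exc) == 0 or np.ptp(inh) == 0:
        raise ValueError("flat trace: lag undefined")
    if method == "xcorr":
        e = (exc - exc.mean()).reshape(-1, cl).mean(axis=0)
        i = (inh - inh.mean()).reshape(-1, cl).mean(axis=0)
        # corr[k] = sum_t e[t] * i[t - k]; peak at the lead of inhibition
        corr = np.real(np.fft.ifft(np.fft.fft(e) * np.conj(np.fft.fft(i))))
        lag = int(np.argmax(corr))
        frac = lag / cl
    elif method == "com":
        def fold(x):
            y = np.maximum(0.0, x - x.min()).reshape(-1, cl).mean(axis=0)
            return y
        frac = _com_phase(fold(exc), cl) - _com_phase(fold(inh), cl)
    else:
        raise ValueError(f"unknown method {method!r}")
    frac = frac - np.round(frac)  # wrap to [-0.5, 0.5)
    if frac <= -0.5 + 1e-12:
        frac += 1.0
    return float(frac)


def charge_transfer(
    trace: np.ndarray,
    dt: float,
    window: tuple[float, float],
    baseline_window: tuple[float, float] | None = None,
    baseline: float | None = None,
) -> float:
    """Baseline-subtracted trapezoidal integral of a current-like trace."""
    trace = np.asarray(trace, dtype=float)
    if baseline is None:
        baseline = float(np.mean(trace[_window_slice(baseline_window, dt)])) if baseline_window else 0.0
    seg = trace[_window_slice(window, dt)] - baseline
    return float(np.trapezoid(seg, dx=dt))


def ie_ratio(exc_response: float, inh_response: float) -> float:
    """Inhibitory-to-excitatory response ratio."""
    if exc_response <= 0:
        raise ValueError("excitatory response must be positive")
    return inh_response / exc_response
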