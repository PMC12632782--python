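"""Frequency-doubled (F2) responses of rectified subunit arrays.

Linear spatial integration cancels the bright and dark bars of a
contrast-reversing grating, so a purely linear receptive field produces no
modulated response.  Rectified subunits respond to each reversal regardless
of its sign, producing output at twice the reversal frequency — the F2
signature.  Centre-surround antagonism within each subunit suppresses its
drive once a bar covers both centre and (local, strong) surround, so the F2
amplitude of surround-bearing subunit arrays declines at large bar widths,
while pure-Gaussian (excitatory-like) arrays plateau.
"""

from __future__ import annotations

import numpy as np

from .metrics import f2_amplitude
from .stimuli import grid_coords
from .subunits import SubunitGrid, SubunitRFParams, subunit_weight_matrix

__all__ = ["f2_curve"]


def f2_curve(
    bar_widths,
    p: SubunitRFParams,
    grid: SubunitGrid | None = None,
    rectify: bool = True,
    temporal_freq: float = 2.0,
    contrast: float = 0.9,
    n_phase_shifts: int = 8,
    n_cycles: int = 4,
    dt: float = 1.0 / 60,
    dx: float = 2.0,
    normalize: bool = False,
    phase_offset: float = 0.0,
) -> np.ndarray:
    """F2 amplitude of the pooled subunit array versus grating bar width.

    For each bar width the contrast-reversing grating is simulated over
    ``n_cycles`` (the first cycle is discarded as transient), the per-subunit
    drive is half-wave rectified (when ``rectify``), pooled with the grid's
    Gaussian position weights, and the Fourier amplitude at twice the
    reversal frequency extracted; amplitudes are averaged over evenly spaced
    circular phase shifts of the grating.  ``normalize`` scales the curve to
    its maximum.
    """
    bar_widths = np.atleast_1d(np.asarray(bar_widths, dtype=float))
    if np.any(bar_widths <= 0):
        raise ValueError("bar widths must be positive")
    if n_phase_shifts < 1:
        raise ValueError("need at least one phase shift")
    if n_cycles < 3:
        raise ValueError("need >= 3 cycles (one discarded as transient)")
    if grid is None:
        grid = SubunitGrid.make_1d()

    extent = 2 * (np.max(np.abs(grid.positions)) + 3.0 * p.sigma_surround) + 4 * np.max(bar_widths)
    nx = int(np.ceil(extent / dx))
    x = grid_coords(nx, dx)
    w = subunit_weight_matrix(x, grid, p, dx)
    pool = grid.pooling_weights

    nt = int(round(n_cycles / temporal_freq / dt))
    t = (np.arange(nt) + 0.5) * dt
    # sinusoidal reversal: the static (filterless) model needs a graded
    # modulation to expose the frequency-doubled component; a square-wave
    # reversal makes the rectified-pooled output piecewise constant, which
    # carries power only at odd harmonics of the reversal frequency
    mod = np.sin(2 * np.pi * temporal_freq * t)
    n_skip = int(round(1.0 / temporal_freq / dt))  # first cycle = transient

    out = np.empty(bar_widths.size)
    for i, bw in enumerate(bar_widths):
        amps = []
        for k in range(n_phase_shifts):
            phase = phase_offset + 2 * bw * k / n_phase_shifts
            idx = np.floor((x - phase) / bw).astype(int)
            pattern = contrast * np.where(idx % 2 == 0, 1.0, -1.0)
            drive = (w @ pattern)[:, None] * mod[None, :]
            resp = np.maximum(0.0, drive) if rectify else drive
            pooled = pool @ resp
            amps.append(f2_amplitude(pooled[n_skip:], temporal_freq, dt))
        out[i] = np.mean(amps)
    if normalize:
        peak = out.max()
        out = out / peak if peak > 0 else out
    return out
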