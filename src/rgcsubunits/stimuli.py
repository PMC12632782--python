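"""Visual stimulus generation on a common space-time grid.

All stimuli are expressed as Weber contrast relative to a mean-luminance
background: ``c = (I - I_bg) / I_bg``, so "-90% contrast" is -0.9 and the
background is 0.  Spatial units are micrometres on the retina, time in
seconds.  Every generator is deterministic given its arguments (and seed,
where randomness is involved).

Protocols covered: flashed square-wave gratings, contrast-reversing
gratings, paired dark pulses with an intervening contrast step, uniform
spots of varying diameter, and seeded synthetic image patches spanning a
spectrum from spatially uniform to highly structured, each paired with its
linear-equivalent disc intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulusField",
    "ProtocolSpec",
    "PatchPair",
    "grid_coords",
    "make_flashed_grating",
    "make_contrast_reversing_grating",
    "make_paired_pulse",
    "paired_pulse_protocol",
    "protocol_to_series",
    "make_spot",
    "make_synthetic_patch",
    "patch_structure_score",
]

#: default spatial step for 1-D protocols (um)
DEFAULT_DX = 2.0
#: retinal scale of 2-D image patches (um / pixel)
PATCH_SCALE = 6.6
#: monitor frame interval (s)
DEFAULT_DT = 1.0 / 60
#: default 1-D field extent (um), covering the RF centre and surround
DEFAULT_EXTENT = 800.0


def grid_coords(n: int, dx: float) -> np.ndarray:
    """Cell-centre coordinates of an ``n``-point grid centred on 0."""
    return (np.arange(n) - (n - 1) / 2.0) * dx


@dataclass
class StimulusField:
    """A luminance-contrast field over (space, time) or (y, x, time).

    ``values`` has shape (nx, nt) for one spatial dimension or
    (ny, nx, nt) for two; contrast is bounded below by -1 (zero luminance).
    """

    values: np.ndarray
    dx: float
    dt: float
    background: float = 1.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim not in (2, 3):
            raise ValueError("values must be (space, time) or (y, x, time)")
        if self.dx <= 0 or self.dt <= 0:
            raise ValueError("grid steps must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("stimulus contains non-finite values")
        if np.min(self.values) < -1 - 1e-12:
            raise ValueError("contrast below -1 (negative luminance)")

    @property
    def dims(self) -> int:
        return self.values.ndim - 1

    @property
    def n_time(self) -> int:
        return self.values.shape[-1]

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n_time) * self.dt

    @property
    def x(self) -> np.ndarray:
        return grid_coords(self.values.shape[-2], self.dx)

    @property
    def y(self) -> np.ndarray:
        if self.dims != 2:
            raise AttributeError("1-D field has no y axis")
        return grid_coords(self.values.shape[0], self.dx)


@dataclass(frozen=True)
class ProtocolSpec:
    """An ordered list of (duration_s, contrast) segments with baselines."""

    name: str
    segments: tuple[tuple[float, float], ...]
    pre: float = 0.5
    post: float = 1.0

    def __post_init__(self):
        if any(d <= 0 for d, _ in self.segments) or self.pre < 0 or self.post < 0:
            raise ValueError("segment durations must be positive")
        if any(c < -1 for _, c in self.segments):
            raise ValueError("contrast below -1")

    @property
    def duration(self) -> float:
        return self.pre + sum(d for d, _ in self.segments) + self.post


def protocol_to_series(protocol: ProtocolSpec, dt: float) -> np.ndarray:
    """Render a protocol as a uniform-field contrast time series."""
    parts = [np.zeros(int(round(protocol.pre / dt)))]
    parts += [np.full(int(round(d / dt)), c) for d, c in protocol.segments]
    parts.append(np.zeros(int(round(protocol.post / dt))))
    return np.concatenate(parts)


@dataclass(frozen=True)
class PatchPair:
    """A 2-D image patch and its linear-equivalent disc intensity."""

    patch: np.ndarray
    disc_intensity: float
    structure_score: float
    seed: int | None
    dx: float = PATCH_SCALE

    def __post_init__(self):
        if self.structure_score < 0:
            raise ValueError("structure score must be non-negative")


def _square_bars(x: np.ndarray, bar_width: float, phase: float = 0.0) -> np.ndarray:
    """+1/-1 square-wave bar pattern; bars switch sign every ``bar_width``."""
    idx = np.floor((x - phase) / bar_width).astype(int)
    return np.where(idx % 2 == 0, 1.0, -1.0)


def make_flashed_grating(
    bar_width: float,
    contrast: float,
    flash_duration: float,
    baseline: float = 0.5,
    field_extent: float = DEFAULT_EXTENT,
    post_baseline: float | None = None,
    phase: float = 0.0,
    dx: float = DEFAULT_DX,
    dt: float = DEFAULT_DT,
) -> StimulusField:
    """Square-wave grating of equal bright/dark bars flashed on a background.

    With the default centred phase and an extent holding an even bar count,
    the spatial mean contrast during the flash is zero.
    """
    if bar_width <= 0:
        raise ValueError("bar width must be positive")
    if abs(contrast) > 1:
        raise ValueError("|contrast| must be <= 1")
    if field_extent < 2 * bar_width:
        raise ValueError("field extent must hold at least one bar pair")
    if post_baseline is None:
        post_baseline = baseline
    nx = int(round(field_extent / dx))
    x = grid_coords(nx, dx)
    pattern = contrast * _square_bars(x, bar_width, phase=phase)
    n_pre = int(round(baseline / dt))
    n_flash = int(round(flash_duration / dt))
    n_post = int(round(post_baseline / dt))
    values = np.zeros((nx, n_pre + n_flash + n_post))
    values[:, n_pre:n_pre + n_flash] = pattern[:, None]
    return StimulusField(values, dx=dx, dt=dt)


def make_contrast_reversing_grating(
    bar_width: float,
    temporal_freq: float = 2.0,
    contrast: float = 0.9,
    duration: float = 2.0,
    field_extent: float = DEFAULT_EXTENT,
    waveform: str = "square",
    phase: float = 0.0,
    dx: float = DEFAULT_DX,
    dt: float = DEFAULT_DT,
) -> StimulusField:
    """Contrast-reversing grating: bar pattern x temporal modulation.

    The temporal modulation reverses at ``temporal_freq`` (square by default,
    ``waveform='sine'`` for analytic tests); every pixel's temporal mean over
    integer cycles is the background.
    """
    if temporal_freq <= 0:
        raise ValueError("temporal frequency must be positive")
    if duration < 2.0 / temporal_freq:
        raise ValueError("duration must cover at least two full cycles")
    nx = int(round(field_extent / dx))
    x = grid_coords(nx, dx)
    pattern = contrast * _square_bars(x, bar_width, phase=phase)
    nt = int(round(duration / dt))
    # sample at bin centres so square-wave reversal never lands on an edge
    t = (np.arange(nt) + 0.5) * dt
    if waveform == "square":
        mod = np.where((t * temporal_freq) % 1.0 < 0.5, 1.0, -1.0)
    elif waveform == "sine":
        mod = np.sin(2 * np.pi * temporal_freq * t)
    else:
        raise ValueError(f"unknown waveform {waveform!r}")
    return StimulusField(pattern[:, None] * mod[None, :], dx=dx, dt=dt)


def paired_pulse_protocol(
    pulse_contrast: float = -0.9,
    pulse_duration: float = 0.3,
    interval_contrast: float = 0.0,
    interval_duration: float = 0.5,
    pre: float = 0.5,
    post: float = 1.0,
) -> ProtocolSpec:
    """Two identical contrast pulses separated by an intervening step."""
    if pulse_duration <= 0 or interval_duration <= 0:
        raise ValueError("durations must be positive")
    return ProtocolSpec(
        name="paired-pulse",
        segments=(
            (pulse_duration, pulse_contrast),
            (interval_duration, interval_contrast),
            (pulse_duration, pulse_contrast),
        ),
        pre=pre,
        post=post,
    )


def make_paired_pulse(
    pulse_contrast: float = -0.9,
    pulse_duration: float = 0.3,
    interval_contrast: float = 0.0,
    interval_duration: float = 0.5,
    pre: float = 0.5,
    post: float = 1.0,
    dx: float = DEFAULT_DX,
    dt: float = DEFAULT_DT,
    n_space: int = 1,
) -> StimulusField:
    """Spatially uniform paired-pulse stimulus (see :func:`paired_pulse_protocol`)."""
    proto = paired_pulse_protocol(
        pulse_contrast, pulse_duration, interval_contrast, interval_duration, pre, post
    )
    series = protocol_to_series(proto, dt)
    return StimulusField(np.tile(series, (n_space, 1)), dx=dx, dt=dt)


def make_spot(
    diameter: float,
    contrast: float,
    duration: float,
    pre: float = 0.5,
    post: float = 0.5,
    field_extent: float = DEFAULT_EXTENT,
    dx: float = PATCH_SCALE,
    dt: float = DEFAULT_DT,
) -> StimulusField:
    """Uniform disc of given diameter flashed at the grid centre (2-D)."""
    if diameter < 0:
        raise ValueError("diameter must be non-negative")
    n = int(round(field_extent / dx))
    c = grid_coords(n, dx)
    yy, xx = np.meshgrid(c, c, indexing="ij")
    if diameter == 0:
        disc = np.zeros((n, n))
    else:
        disc = (xx**2 + yy**2 <= (diameter / 2.0) ** 2).astype(float) * contrast
    n_pre, n_on, n_post = (int(round(d / dt)) for d in (pre, duration, post))
    values = np.zeros((n, n, n_pre + n_on + n_post))
    values[:, :, n_pre:n_pre + n_on] = disc[:, :, None]
    return StimulusField(values, dx=dx, dt=dt)


def _power_law_texture(shape: tuple[int, int], exponent: float, rng) -> np.ndarray:
    """Unit-variance Gaussian random field with |f|^exponent amplitude spectrum."""
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    f = np.hypot(fy, fx)
    amp = np.zeros_like(f)
    amp[f > 0] = f[f > 0] ** exponent
    spec = amp * np.exp(2j * np.pi * rng.random(shape))
    tex = np.real(np.fft.ifft2(spec))
    sd = tex.std()
    return tex / sd if sd > 0 else tex


def make_synthetic_patch(
    structure_level: float,
    mean_contrast: float = 0.0,
    seed: int | None = None,
    scale: float = PATCH_SCALE,
    extent: float = 300.0,
    rf=None,
    spectrum_exponent: float = -1.0,
    base_amplitude: float = 0.35,
) -> PatchPair:
    """Seeded 2-D texture emulating a natural-image patch, plus its disc.

    The patch is spatially correlated noise with a power-law (1/f by default)
    spatial spectrum, with pixel standard deviation proportional to
    ``structure_level`` and RF-Gaussian-weighted mean pinned exactly to
    ``mean_contrast`` — so the linear-equivalent disc of the pair is
    ``mean_contrast`` by construction.  ``structure_level=0`` yields a
    uniform patch identical to its disc.
    """
    from .receptive_field import GaussianRFParams, linear_equivalent_intensity, rf_weights

    if not 0 <= structure_level <= 1:
        raise ValueError("structure_level must lie in [0, 1]")
    if structure_level > 0 and seed is None:
        raise ValueError("a seed is required for structured patches")
    if rf is None:
        rf = GaussianRFParams(sigma_center=50.0)
    n = int(round(extent / scale))
    if structure_level == 0:
        patch = np.full((n, n), float(mean_contrast))
        return PatchPair(patch, float(mean_contrast), 0.0, seed, dx=scale)
    rng = np.random.default_rng(seed)
    fluct = _power_law_texture((n, n), spectrum_exponent, rng)
    fluct *= base_amplitude * structure_level
    coords = grid_coords(n, scale)
    w = rf_weights((coords, coords), rf)
    fluct -= float(np.sum(w * fluct))  # zero RF-weighted mean, std unchanged
    patch = mean_contrast + fluct
    lo = float(patch.min())
    if lo < -1:
        # rescale fluctuations about the mean to respect the luminance floor
        s = 0.999 * (1.0 + mean_contrast) / (mean_contrast - lo)
        patch = mean_contrast + s * fluct
    disc = linear_equivalent_intensity(patch, rf, dx=scale)
    score = float(np.std(patch))
    return PatchPair(patch, float(disc), score, seed, dx=scale)


def patch_structure_score(patch: np.ndarray, rf, subunits, spacing: float = 20.0,
                          dx: float = PATCH_SCALE) -> float:
    """Deviation-from-linearity drive of a patch.

    Pools, under the RF Gaussian, the rectified responses of a grid of
    subunits to the patch's deviation from its RF-weighted mean (the
    linear-RF prediction).  Zero for spatially uniform patches; strictly
    positive for patches with structure inside the RF; exactly invariant to
    adding a spatially uniform offset, which shifts both model responses
    identically.
    """
    from .receptive_field import linear_equivalent_intensity, rf_weights
    from .subunits import SubunitGrid, subunit_weight_matrix

    patch = np.asarray(patch, dtype=float)
    if patch.ndim != 2:
        raise ValueError("patch must be a 2-D frame")
    n = patch.shape[0]
    coords = grid_coords(n, dx)
    m = linear_equivalent_intensity(patch, rf, dx=dx)
    grid = SubunitGrid.make_2d(spacing=spacing, pooling_sigma=rf.sigma_center)
    w = subunit_weight_matrix(coords, grid, subunits, dx=dx, normalize="center")
    drives = w @ (patch - m).ravel()
    return float(np.sum(grid.pooling_weights * np.abs(drives)))
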