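"""Whole-cell receptive-field machinery.

The receptive-field centre size of a ganglion cell is estimated from an
area-summation curve — responses to concentric spots of increasing radius —
with a difference-of-Gaussians (DoG) model:

    R(r) = Kc * (1 - exp(-r^2 / (2 sigma_c^2)))
         - Ks * (1 - exp(-r^2 / (2 sigma_s^2))) + R0

Gaussian RF weights (truncated at an aperture equal to the Gaussian's
two-standard-deviation span, then renormalised) turn an image patch into its
"linear-equivalent disc": the uniform stimulus carrying the RF-weighted mean
intensity of the patch.  Equal responses to a patch and its disc are the
signature of linear spatial integration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "GaussianRFParams",
    "DoGAreaParams",
    "IdentifiabilityError",
    "area_summation_response",
    "fit_area_summation",
    "rf_weights",
    "linear_equivalent_intensity",
]


class IdentifiabilityError(RuntimeError):
    """Raised when an area-summation curve cannot constrain the DoG fit."""


@dataclass(frozen=True)
class GaussianRFParams:
    """Circular Gaussian RF weighting for linear-equivalent-disc construction.

    The aperture diameter defaults to twice the Gaussian's two-SD span
    (i.e. 4 sigma), the convention used to match the aperture to the
    measured RF-centre size.
    """

    sigma_center: float = 50.0
    center: tuple[float, float] = (0.0, 0.0)
    aperture_diameter: float | None = None

    def __post_init__(self):
        if self.sigma_center <= 0:
            raise ValueError("sigma_center must be positive")
        if self.aperture_diameter is None:
            object.__setattr__(self, "aperture_diameter", 4.0 * self.sigma_center)
        if self.aperture_diameter <= 0:
            raise ValueError("aperture diameter must be positive")


@dataclass(frozen=True)
class DoGAreaParams:
    """Difference-of-Gaussians area-summation parameters."""

    kc: float
    ks: float
    sigma_c: float
    sigma_s: float
    r0: float = 0.0

    def __post_init__(self):
        if self.kc < 0 or self.ks < 0:
            raise ValueError("component strengths must be non-negative")
        if not 0 < self.sigma_c < self.sigma_s:
            raise ValueError("need sigma_s > sigma_c > 0")


def area_summation_response(r, p: DoGAreaParams):
    """DoG area-summation response at spot radius ``r`` (um).

    R(0) = R0 and R(inf) = Kc - Ks + R0.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("spot radius must be non-negative")
    center = p.kc * (1.0 - np.exp(-(r**2) / (2.0 * p.sigma_c**2)))
    surround = p.ks * (1.0 - np.exp(-(r**2) / (2.0 * p.sigma_s**2)))
    out = center - surround + p.r0
    return float(out) if out.ndim == 0 else out


def _dog_residuals(theta, radii, responses):
    kc, ks, sc, ratio, r0 = theta
    p = DoGAreaParams(kc=kc, ks=ks, sigma_c=sc, sigma_s=sc * ratio, r0=r0)
    return area_summation_response(radii, p) - responses


def fit_area_summation(
    radii,
    responses,
    init: DoGAreaParams | None = None,
    n_starts: int = 3,
    seed: int = 0,
) -> DoGAreaParams:
    """Bounded nonlinear least-squares fit of the DoG area-summation model.

    The surround width is parameterised as ``sigma_s = ratio * sigma_c`` with
    ``ratio > 1`` so the fit cannot cross the sigma_s > sigma_c invariant.
    Multi-start (jittered initial points) guards against the Kc/Ks
    degeneracy.  Raises :class:`IdentifiabilityError` for flat curves.
    """
    radii = np.asarray(radii, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if radii.size != responses.size or np.unique(radii).size < 5:
        raise ValueError("need responses at >= 5 distinct radii")
    span = np.ptp(responses)
    if span <= 1e-12 * max(1.0, np.max(np.abs(responses))):
        raise IdentifiabilityError("flat area-summation curve: DoG parameters unidentifiable")

    rmax = float(np.max(radii))
    if init is not None:
        starts = [np.array([init.kc, init.ks, init.sigma_c, init.sigma_s / init.sigma_c, init.r0])]
    else:
        starts = [np.array([span, span / 2.0, rmax / 4.0, 3.0, float(responses[np.argmin(radii)])])]
    rng = np.random.default_rng(seed)
    while len(starts) < n_starts:
        jitter = np.exp(rng.normal(0.0, 0.4, size=4))
        base = starts[0]
        starts.append(np.array([base[0] * jitter[0], base[1] * jitter[1],
                                base[2] * jitter[2], 1.0 + (base[3] - 1.0) * jitter[3], base[4]]))

    lo = [0.0, 0.0, 1e-3, 1.0 + 1e-6, -np.inf]
    hi = [np.inf, np.inf, 10.0 * rmax, 1e3, np.inf]
    best = None
    for x0 in starts:
        x0 = np.clip(x0, lo, hi)
        try:
            sol = least_squares(_dog_residuals, x0, args=(radii, responses), bounds=(lo, hi))
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise IdentifiabilityError("area-summation fit failed from every start")
    if init is not None:
        init_cost = 0.5 * np.sum(_dog_residuals(starts[0], radii, responses) ** 2)
        if best.cost > init_cost + 1e-12:
            raise IdentifiabilityError("fit did not improve on the supplied initial parameters")
    kc, ks, sc, ratio, r0 = best.x
    return DoGAreaParams(kc=kc, ks=ks, sigma_c=sc, sigma_s=sc * ratio, r0=r0)


def rf_weights(coords, rf: GaussianRFParams) -> np.ndarray:
    """Normalised Gaussian RF weights on a grid, truncated at the aperture.

    ``coords`` is a tuple of cell-centre coordinate arrays: ``(x,)`` for 1-D
    or ``(y, x)`` for 2-D.  Weights are zero outside the aperture radius and
    renormalised to sum to one, so a uniform patch maps to its own contrast.
    """
    if isinstance(coords, np.ndarray):
        coords = (coords,)
    if len(coords) == 1:
        (x,) = coords
        d2 = (x - rf.center[0]) ** 2
    elif len(coords) == 2:
        y, x = coords
        d2 = ((y - rf.center[1]) ** 2)[:, None] + ((x - rf.center[0]) ** 2)[None, :]
    else:
        raise ValueError("coords must be (x,) or (y, x)")
    radius = rf.aperture_diameter / 2.0
    for c in coords:
        if radius > np.max(np.abs(c)) + 1e-9:
            raise ValueError("aperture exceeds the stimulus grid")
    w = np.exp(-d2 / (2.0 * rf.sigma_center**2))
    w[d2 > radius**2] = 0.0
    total = w.sum()
    if total <= 0:
        raise ValueError("empty aperture: no grid points inside")
    return w / total


def linear_equivalent_intensity(patch: np.ndarray, rf: GaussianRFParams, dx: float) -> float:
    """RF-Gaussian-weighted mean intensity of a patch (its equivalent disc).

    Linear in the patch; returns the patch value itself for uniform patches.
    """
    from .stimuli import grid_coords

    patch = np.asarray(patch, dtype=float)
    if patch.ndim == 1:
        coords = (grid_coords(patch.size, dx),)
    elif patch.ndim == 2:
        coords = (grid_coords(patch.shape[0], dx), grid_coords(patch.shape[1], dx))
    else:
        raise ValueError("patch must be 1-D or 2-D")
    w = rf_weights(coords, rf)
    return float(np.sum(w * patch))
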