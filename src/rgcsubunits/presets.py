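"""Calibration preset and configuration validation.

The model's rate constants and temporal-filter parameters are not tied to a
single published table; the values here form the package's documented
calibration preset (see docs/methods.md), chosen once to place the model in
the regime characteristic of Off-transient alpha cells: tonically active,
strongly depressed excitatory synapses (resting occupancy ~0.12), fast
transient Off excitation, and strong On-sign glycinergic inhibition whose
divisive action on vesicle release produces paired-pulse facilitation and
offset rebound.

All experiment presets and the command-line tools resolve their parameters
from this module; every value can be overridden through a config mapping.
"""

from __future__ import annotations

import copy

from .filters import TemporalFilter
from .synapse import DynamicSynapseParams

__all__ = [
    "CALIBRATION",
    "ALPHA_GRID",
    "BETA_GRID",
    "DELTA_GRID",
    "SIZE_RATIO_GRID",
    "PPR_INTERVALS",
    "ConfigError",
    "make_patch_ensemble",
    "calibration_synapse",
    "calibration_filters",
    "validate_config",
]

#: presynaptic inhibition strengths used in the sweep experiments
ALPHA_GRID = (0.1, 0.4, 0.8)
#: inhibition-sensitivity values used in the sweep experiments
BETA_GRID = (1.0, 4.0, 8.0)
#: subunit surround strengths (weak / moderate / strong)
DELTA_GRID = (0.2, 0.5, 0.9)
#: inhibitory/excitatory subunit size ratios
SIZE_RATIO_GRID = (0.8, 2.0, 4.0)
#: paired-pulse interval durations (s)
PPR_INTERVALS = (0.2, 0.5, 2.0, 5.0)

CALIBRATION: dict = {
    "synapse": {
        # vesicle pool: recovery 8/s (tau ~125 ms), release constant 12/s,
        # unit release gain; resting occupancy n0 = 0.12 fixes the tonic
        # drive e0 = krec*(1/n0 - 1)/(b*krel).
        "krec": 8.0,
        "krel": 12.0,
        "b": 1.0,
        "gamma": 0.5,
        "n0": 0.12,
        "r0": 0.05,
        "alpha": 0.4,
        "beta": 4.0,
    },
    "exc_filter": {
        # transient Off-pathway kernel: dark contrast -> positive drive
        "tau_rise": 0.025,
        "tau_decay": 0.06,
        "undershoot": 0.4,
        "gain": 1.5,
        "polarity": -1,
        "delay": 0.0,
        "n_stages": 3,
        "adapt_strength": 0.0,
        "adapt_tau": 1.5,
    },
    "inh_filter": {
        # On-sign glycinergic pathway (AII amacrine route): brightening ->
        # inhibition; one extra synapse adds a 15 ms lag; a small slow sag
        # (6% over 1.5 s) captures the gradual relaxation of sustained
        # inhibition
        "tau_rise": 0.04,
        "tau_decay": 0.08,
        "undershoot": 0.5,
        "gain": 10.0,
        "polarity": 1,
        "delay": 0.015,
        "n_stages": 2,
        "adapt_strength": 0.06,
        "adapt_tau": 1.5,
    },
    "simulation": {
        "dt": 1.0 / 600,      # temporal (hemifield) model step
        "dt_spatial": 1.0 / 120,  # spatiotemporal model step
        "substeps": 4,
        "readout_gain": 3.0,
    },
    "spatial": {
        # subunit layout for the image experiments (um)
        "exc_sigma": 20.0,
        "inh_sigma": 25.0,
        "inh_surround_ratio": 1.4,
        "inh_delta": 0.0,
        "exc_spacing": 20.0,
        "inh_spacing": 20.0,
        "pooling_sigma": 50.0,
        "flash_duration": 0.2,
        # the spatial model's drives are locally pooled spatial signals, far
        # smaller per unit contrast than the hemifield model's full-field
        # input; both pathway gains are calibrated separately
        "exc_gain": 1.5,
        "inh_gain": 300.0,
        # the spatial model keeps a shallower release-inhibition coupling than
        # the hemifield default; see docs/methods.md
        "beta": 2.0,
    },
    "patch_ensemble": {
        # synthetic natural-patch ensemble: net-dark means with fluctuations
        # large enough to carry bright (above-background) regions
        "mean_contrast_range": [-0.45, -0.15],
        "structure_range": [0.3, 1.0],
        "base_amplitude": 0.7,
        "extent": 400.0,
        "rf_sigma": 50.0,
    },
}


class ConfigError(ValueError):
    """A configuration value violates a model invariant."""


def _merged(overrides: dict | None) -> dict:
    cfg = copy.deepcopy(CALIBRATION)
    if overrides:
        for section, vals in overrides.items():
            if section not in cfg:
                raise ConfigError(f"unknown config section {section!r}")
            if not isinstance(vals, dict):
                raise ConfigError(f"section {section!r} must be a mapping")
            for key, v in vals.items():
                if key not in cfg[section]:
                    raise ConfigError(f"unknown key {section}.{key}")
                cfg[section][key] = v
    return cfg


def validate_config(overrides: dict | None = None) -> dict:
    """Merge overrides into the calibration preset and check invariants.

    Returns the fully resolved configuration; raises :class:`ConfigError`
    naming the offending key for each violated invariant.
    """
    cfg = _merged(overrides)
    s = cfg["synapse"]
    checks = [
        (s["krec"] > 0, "synapse.krec must be positive"),
        (s["krel"] > 0, "synapse.krel must be positive"),
        (s["b"] > 0, "synapse.b must be positive"),
        (0 < s["gamma"] <= 1, "synapse.gamma must lie in (0, 1]"),
        (0 < s["n0"] <= 1, "synapse.n0 must lie in (0, 1]"),
        (s["r0"] >= 0, "synapse.r0 must be non-negative"),
        (s["alpha"] >= 0, "synapse.alpha must be non-negative"),
        (s["beta"] >= 0, "synapse.beta must be non-negative"),
        (cfg["spatial"]["inh_surround_ratio"] > 1, "spatial.inh_surround_ratio must exceed 1"),
        (0 <= cfg["spatial"]["inh_delta"] <= 1, "spatial.inh_delta must lie in [0, 1]"),
        (cfg["simulation"]["dt"] > 0, "simulation.dt must be positive"),
    ]
    errors = [msg for ok, msg in checks if not ok]
    for fsec in ("exc_filter", "inh_filter"):
        try:
            TemporalFilter(**cfg[fsec])
        except ValueError as e:
            errors.append(f"{fsec}: {e}")
    if errors:
        raise ConfigError("; ".join(errors))
    return cfg


def calibration_synapse(alpha: float | None = None, beta: float | None = None,
                        overrides: dict | None = None, **extra) -> DynamicSynapseParams:
    """Synapse parameters of the calibration preset, with optional overrides."""
    cfg = validate_config(overrides)["synapse"]
    cfg.update(extra)
    if alpha is not None:
        cfg["alpha"] = alpha
    if beta is not None:
        cfg["beta"] = beta
    n0 = cfg.pop("n0")
    e0 = cfg["krec"] * (1.0 / n0 - 1.0) / (cfg["b"] * cfg["krel"])
    return DynamicSynapseParams(e0=e0, **cfg)


def calibration_filters(overrides: dict | None = None) -> tuple[TemporalFilter, TemporalFilter]:
    """(excitatory, inhibitory) temporal filters of the calibration preset."""
    cfg = validate_config(overrides)
    return TemporalFilter(**cfg["exc_filter"]), TemporalFilter(**cfg["inh_filter"])


def make_patch_ensemble(n: int, seed: int, overrides: dict | None = None) -> list:
    """Seeded synthetic patch/disc ensemble spanning uniform to structured.

    Structure level and mean contrast are drawn uniformly from the
    calibrated ranges; each patch gets its own child seed, so the ensemble
    is reproducible from (n, seed) alone.
    """
    import numpy as np

    from .receptive_field import GaussianRFParams
    from .stimuli import make_synthetic_patch

    pe = validate_config(overrides)["patch_ensemble"]
    rng = np.random.default_rng(seed)
    rf = GaussianRFParams(pe["rf_sigma"])
    pairs = []
    for _ in range(n):
        s = float(rng.uniform(*pe["structure_range"]))
        m = float(rng.uniform(*pe["mean_contrast_range"]))
        pairs.append(make_synthetic_patch(
            s, m, seed=int(rng.integers(2**31)), extent=pe["extent"], rf=rf,
            base_amplitude=pe["base_amplitude"],
        ))
    return pairs
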