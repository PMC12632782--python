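# Model and methods

## The circuit model

`rgcsubunits` implements a hybrid linear–nonlinear (LN) model of the
excitatory and inhibitory synaptic drive to an Off-transient alpha retinal
ganglion cell (OffT αRGC), built to study why these cells prefer spatially
homogeneous stimuli over structured ones.

**Inhibitory pathway (static LN).** Each inhibitory subunit j at position
y_j applies a spatial profile and a temporal filter to the stimulus
contrast S(x, t) and half-wave rectifies the result:

    I_j(t) = [ ∫∫ R_inh(x − y_j) T_inh(τ) S(x, t − τ) dx dτ ]₊

The spatial profile is a difference of Gaussians
R(x) = exp(−x²/2σ_c²) − δ·exp(−x²/2σ_s²) with relative surround strength
δ ∈ [0, 1]. The temporal filter is **On-sign**: brightening drives
inhibition. This polarity is what the physiology of the glycinergic (AII
amacrine) route implies, and it is load-bearing three times over: it makes
bright interludes between dark pulses facilitate the second response, it
places inhibition roughly half a frequency-doubled cycle before excitation
under a contrast-reversing grating, and it lets dark linear-equivalent
discs escape inhibition entirely while structured patches (whose bright
regions exceed the background) recruit it.

**Excitatory pathway (dynamic LN).** Each excitatory subunit i has a
Gaussian spatial profile and an Off-sign temporal filter producing a raw
drive E_raw_i(t) on top of a tonic drive e₀. Presynaptic inhibition is
pooled from nearby inhibitory subunits with Gaussian weights
w(x_i, y_j) = exp(−(x_i−y_j)²/2σ_inh²) (normalised to sum to one per
excitatory subunit so the pooled drive is independent of grid density) and
scaled by the global inhibition strength α:

    I_eff_i(t) = α · Σ_j w(x_i, y_j) I_j(t)

The drive passes a piecewise-linear nonlinearity Φ(u) = γ·u for u < 0,
u for u ≥ 0 (rectification ratio γ), and the positive part is scaled by the
vesicle occupancy n_i(t) ∈ [0, 1] of a depletion-and-recovery pool:

    E_i = Φ(E_raw_i − I_eff_i)
    Ẽ_i = n_i · max(0, E_i) + R₀
    dn_i/dt = (1 − n_i)·K_rec − b·K_rel·m(I_eff_i)·n_i·Ẽ_i

Because max(0, Φ(u)) = max(0, u), γ does not influence Ẽ; it shapes only
the diagnostic subthreshold drive E_i and is retained for completeness.

**Release–inhibition coupling.** Besides subtracting from the drive,
inhibition divisively reduces the release rate through
m(I) = 1/(1 + β·I): β sets how strongly inhibition couples to the vesicle
dynamics, and β = 0 recovers the bare depletion ODE. The divisive form is
our choice — the coupling is not constrained beyond being monotone,
bounded, and inactive at zero inhibition.

**Resting state.** With zero baseline inhibition, constant release drive e₀
gives the closed-form resting occupancy n₀ = 1/(1 + b·e₀·K_rel/K_rec).
Because the release drive in the ODE is the output Ẽ = n·e₀ + R₀ rather
than e₀ itself, the coupled resting point solves a quadratic instead; when
R₀ is left unset it defaults to e₀(1 − n₀), which makes the closed form and
the coupled fixed point coincide exactly. The calibration preset sets a
small explicit R₀ (see below), so its resting occupancy comes from the
quadratic (≈ 0.30 for the preset) while the printed n₀ formula remains the
fixed point of the bare ODE.

**Readouts.** The two-hemifield (temporal-only) reduction collapses space:
one excitatory and one inhibitory subunit per hemifield, each excitatory
subunit receiving the combined inhibition I_eff = α(I_L + I_R); totals are
hemifield averages. The spatiotemporal model pools with Gaussian weights
over subunit positions (σ = 50 μm) and reads out a spike-rate proxy

    rate = [ g·E_total − α·I_total − θ ]₊ ,   g = 3.

α scales the direct (readout) inhibition as well as the presynaptic route:
it models the overall strength of glycinergic transmission, so α = 0
corresponds to a complete block (the strychnine condition). θ is a spike
threshold chosen so the resting drive maps to a small spontaneous rate
(0.5 rate units); windowed integrals of the rate then behave like spike
counts instead of riding on the tonic-drive pedestal.

## Why the model prefers homogeneity

Tonic release holds the pool at low occupancy (low gain). A structured
stimulus recruits inhibition: subtractively it suppresses the excitatory
drive at onset (and the readout rate with it), and divisively it halts
release, letting the pool refill. When the structure disappears — at
stimulus offset, or at the second of two dark pulses — the refilled pool
meets a recovered drive and produces a large transient. A homogeneous dark
disc recruits no inhibition, responds strongly at onset, depletes, and has
nothing in reserve at offset. The onset/offset nonlinearity indices
(NLI = (r_img − r_disc)/(r_img + r_disc)) therefore come out negative at
onset and positive at offset, most strongly at large α.

## Calibration preset

The rate constants and filter parameters are a documented calibration, not
published values; they were chosen once to place the model in the regime
the physiology describes (tonically active, strongly depressed synapses;
facilitation up to several-fold at a 500 ms interval, decaying over
seconds; suppression then rebound for flashed gratings at α ≥ 0.4) and are
used unchanged by every experiment, test and the acceptance script.

| parameter | value | meaning |
|---|---|---|
| K_rec | 8 s⁻¹ | vesicle recovery rate (τ ≈ 125 ms) |
| K_rel | 12 s⁻¹ | release rate constant |
| b | 1 | release gain |
| γ | 0.5 | rectification ratio (inert in Ẽ, see above) |
| n₀ | 0.12 | nominal resting occupancy; fixes e₀ = K_rec(1/n₀ − 1)/(b·K_rel) ≈ 4.89 |
| R₀ | 0.05 | tonic additive output offset |
| α default | 0.4 | presynaptic/global inhibition strength |
| β default | 4 (hemifield), 2 (spatial) | release–inhibition coupling |
| exc filter | τ_rise 25 ms, τ_decay 60 ms, undershoot 0.4, 3 stages, gain 1.5, Off-sign | transient Off drive |
| inh filter | τ_rise 40 ms, τ_decay 80 ms, undershoot 0.5, 2 stages, 15 ms lag, On-sign | glycinergic route (extra synapse) |
| inh slow sag | 6 % over 1.5 s | slow relaxation of sustained inhibition |
| inh gain | 10 (hemifield), 300 (spatial) | pathway gain, per model (units differ, below) |
| spatial exc gain | 1.5 | excitatory pathway gain in the spatial model |

The hemifield model feeds full-field Weber contrast (order 1) straight into
its temporal filters; the spatial model feeds locally pooled spatial drives
that are an order of magnitude smaller for textured input. The two
reductions therefore carry separately calibrated pathway gains — a single
gain cannot put both models in the physiological operating regime.

The small slow sag on the inhibitory kernel gives the paired-pulse ratio
its gradual decay toward the plateau across 0.2–5 s intervals; without it
the facilitated state relaxes within ~0.3 s and the 2 s and 5 s intervals
are indistinguishable.

Spatial layout (image experiments): excitatory subunits σ = 20 μm,
inhibitory σ = 25 μm (pure Gaussian, δ = 0, by default; δ and the surround
ratio are configurable), both on 20 μm grids covering ±1.6 pooling σ;
presynaptic pooling σ equals the inhibitory subunit σ and scales with it in
the size-ratio sweep; flashes last 200 ms with onset/offset analysis
windows of the same length.

The static frequency-doubling (F2) analysis of rectified subunit arrays
uses its own inhibitory-subunit geometry: a strong, *local* surround
(σ_s/σ_c = 1.1) whose near-cancellation of wide uniform bars produces the
declining F2 at large bar widths; δ is swept over {0.2, 0.5, 0.9}. The
grating there reverses sinusoidally: a square-wave reversal makes the
static (filterless) rectified-pooled response piecewise constant, which has
no power at twice the reversal frequency.

## Synthetic stimuli

All stimuli are Weber contrast on a mean-luminance background ("−90 %
contrast" = −0.9), on grids of 2 μm (1-D protocols) or 6.6 μm/pixel (2-D
patches) at 60 Hz frame resolution, with model integration typically at
1/600 s (hemifield) or 1/120 s (spatial).

The synthetic image patches emulate natural-image patches: Gaussian random
fields with a power-law (1/f) spatial amplitude spectrum, pixel standard
deviation proportional to a structure level, and the RF-Gaussian-weighted
mean pinned exactly to a requested mean contrast, so each patch's
linear-equivalent disc is known by construction. Darkness is bounded by the
luminance floor (contrast ≥ −1): for dark means, fluctuations are rescaled
to respect the floor, which caps the effective amplitude of strongly
structured dark patches. The experiment ensemble draws mean contrast
uniformly from (−0.45, −0.15) and structure from (0.3, 1): net-dark patches
that drive Off excitation whose bright regions exceed the background —
emulating the balanced sampling of patches across the linear-to-nonlinear
spectrum used to probe these cells.

What the generator does not reproduce: natural images' phase structure
(edges, objects), luminance-contrast correlations, and the photoreceptor
adaptation that precedes the retinal circuit. Passing tests therefore show
that the *mechanism* produces the reported selectivity on contrast-matched
synthetic scenes, not that the exact NLI distributions of the recordings
are reproduced.

## Numerics

* Occupancy ODE: per-sample exponential relaxation toward the
  self-consistent equilibrium of that sample's drive, with the rate
  linearised at the equilibrium (4 substeps per stimulus step, step-halving
  convergence guard). The scheme is exact for constant drive, bounded in
  [0, 1] unconditionally, and remains exact in the stiff instant-recovery
  limit. The quadratic equilibrium uses the conjugate root form to avoid
  cancellation when release ≪ recovery.
* With exogenous drive (`vesicle_integrate`) the ODE is linear in n and the
  per-sample exponential update is exact for zero-order-hold drive; it
  matches a 100×-finer Euler oracle to <1e−4.
* Temporal kernels are difference-of-low-pass-cascade forms normalised so a
  unit-contrast step peaks at `gain`; kernels must decay below 1e−4 of
  their peak within their length (validated at construction).
* Zero-contrast history is exact: convolutions implicitly assume background
  before t = 0, so simulations start at the resting fixed point without a
  settling transient; the hemifield driver still prepends 3/K_rec of
  baseline and verifies stationarity.
* DoG area-summation fits run bounded least squares with σ_s parameterised
  as ratio × σ_c (ratio > 1) and three jittered starts; flat curves raise an
  identifiability error. The printed exponent is read as −r²/(2σ²) — the
  dimensionally consistent Gaussian form.
* NLI conventions: NLI(0, 0) = 0; the three-spike offset exclusion rule
  applies to spike-count data (for model rate integrals it is disabled by
  default but wired through `offset_exclusion_threshold`).

## Known limitations

* The paired-pulse facilitation peaks at the shortest interval and decays
  with a single dominant timescale; the recorded decay spans a wider range
  of timescales than one vesicle pool plus one sag can produce.
* NLI magnitudes depend on the spike-threshold convention; only their signs
  and orderings across α and subunit-size ratios are calibrated behaviour.
* The model output is a rectified rate proxy — no spike generation, no
  conductance interactions, no light-level adaptation mechanism (different
  light levels can only be emulated as parameter regimes).
* 2-D simulations assume isotropic, separable Gaussian/DoG profiles and
  square patches.
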