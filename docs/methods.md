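# Methods

This note records the physical model behind `codexsim`, the conventions and
numerical choices it makes, the design decisions that were genuinely open,
and the limits of what the simulator can show about real samples.

## 1. Model

The simulator treats an isolated spin pair: an observed spin S (e.g. ¹⁵N or
¹³C) carrying a chemical-shift-anisotropy (CSA) tensor, dipolar-coupled to
one or more I spins (¹H-like with I = 1/2, ²H-like with I = 1).  Everything
is first-order average Hamiltonian under magic-angle spinning: the
instantaneous anisotropic frequency of each interaction is the laboratory
zz component of its traceless tensor, a trigonometric polynomial in the
rotor phase with harmonics 1 and 2 that averages to zero over a rotor
period.  Rotor-synchronized π pulses with half-rotor-period spacing toggle
the sign of the integrand and thereby recouple the interaction; the phase
acquired over one de(re)phasing period of N rotor cycles is obtained by
exact closed-form integration of the band-limited trajectory between
toggles (no time stepping; a 10⁴-step Riemann sum agrees to < 10⁻⁶ rad).

Two pulse-train variants are built in:

* **CSA recoupling** — π pulses on the S channel every half rotor period.
  These invert both the CSA and the dipolar term, so a residual dipolar
  coupling is recoupled alongside the CSA.  Imperfect heteronuclear
  decoupling is represented by a single multiplicative `residual_scale`
  λ ∈ [0, 1] on the coupling constant; no decoupling sequence is simulated.
* **dipolar recoupling** — π pulses on the I channel every half rotor
  period plus a single S-channel π pulse at the period midpoint (N even).
  The midpoint pulse refocuses the CSA exactly; the recoupled CSA phase is
  zero to machine precision.

Pulses are ideal instantaneous inversions.  Homonuclear I–I couplings never
enter the coherent evolution; they act only through stochastic flip rates.

### Coherence bookkeeping

The S-spin coherence is tracked in the four-operator basis
{Sx, Sy, 2SxIz, 2SyIz}.  One de(re)phasing period applies the composition
of two commuting rotations: a transverse rotation by the recoupled CSA
phase Φ_C and an in-phase/anti-phase mixing rotation by the recoupled
dipolar phase Φ_D.  The 4×4 matrix is orthogonal for all phases
(norm-conserving; property-tested).  Cross polarization leaves an in-phase
amplitude (1 − a) on Sx and an anti-phase amplitude −a on 2SyIz, with
a ∈ [0, 1] a free parameter standing in for the empirical dependence on CP
contact time.  The Z filter stores the in-phase part longitudinally
(decaying with T1 of S) while transverse/anti-phase pathways decay with T2
and vanish for delays long on the T2 scale.

### Component selection and the two quadrature conventions

Between dephasing and mixing, one transverse family is stored
longitudinally: COS keeps {Sx, 2SxIz}, SIN keeps {Sy, 2SyIz}.  After
mixing, the readout pulse re-excites the stored amplitudes along the axis
fixed by its own phase — the *same* axis for both components.  The SIN
branch therefore accumulates the sine quadrature during rephasing, and the
detected in-phase signals are cos Φ₁·cos Φ₂ (COS) and sin Φ₁·sin Φ₂ (SIN).
This storage/readout transport (`reinsert_after_mixing`) was validated
against an exact two-spin density-matrix propagation of the pulse sequence
with ideal pulses; it is what makes the stimulated-echo identity
COS + SIN = cos(ΔΦ) hold, and with it the exchange diagnostic.

A second convention appears in the product-operator literature: evolve the
stored family through the rephasing period *without* the transport and
read the same in-phase operator.  Within one component this "stored-family
bookkeeping" is the standard shorthand, and it is what the closed-form
RIDER ratios of `analytic_rider_ratios` and `antiphase_amplitude_ratio`
are defined in: the anti-phase/in-phase amplitude ratio of the SIN
component is tan(2Φ_D) ≈ 2·tan(Φ_D) at small Φ_D (twice the COS value —
the reason SIN is more artifact-prone), and under I = 1/2 flips the
anti-phase pathway plateaus at S∞/S₀ = 1/2 for SIN and
cos²Φ_C/(cos²Φ_C − sin²Φ_C) for COS.  The two conventions are the two
receiver quadratures of the same acquisition and cannot both be detected
at once; the density-matrix oracle shows the full-experiment SIN
anti-phase plateau is −sin²Φ_C/cos 2Φ_C under the echo-proper quadrature.
`codexsim` exposes both deliberately: the **engine operations and the
closed-form calculators follow the stored-family bookkeeping** (the
shorthand in which the published RIDER ratios are stated), while the
**full experiment simulator applies the physical storage/readout
transport** (without which the COS/SIN exchange identity — the basis of
the diagnostic — would fail).  Either way the COS component is identical,
and "cos 2Φ" in the plateau formulas means cos²Φ − sin²Φ with squared
component amplitudes, as fixed by direct propagation.

### Powder behaviour of the anti-phase pathway

The anti-phase amplitude created by CP is odd in the heteronuclear
coupling (the transfer oscillates at the coupling frequency), so in a
powder its sign is correlated with the orientation-dependent coupling.
The simulator seeds the anti-phase term with the sign of the recoupled
dipolar phase of each crystallite; without this correlation the pathway
cancels exactly between crystallites related by rotor-phase inversion and
no powder RIDER would survive.  The overall sign is fixed so the
interference appears as the observed fast *decay*.  The COS/SIN asymmetry
of the isolated-pair model additionally requires the recoupled CSA phase
not to be fully phase-wrapped across the powder (terms weighted by
cos 2Φ_C survive only then); the qualitative demonstrations therefore use
a small CSA (1.2 kHz ≈ 20 ppm at 60.8 MHz) and an 8-rotor-cycle period,
giving rms Φ_C ≈ 0.7 rad.  Real multi-spin systems show the asymmetry
under broader conditions.

## 2. Stochastic dynamics

Spin-lattice flips and flip-flops of each I species are merged into one
continuous-time Markov jump process at the summed rate 1/T1 + 1/τ_ff; the
channels differ only by their configured timescales.  For I = 1/2 each
jump inverts the level; for I = 1 jumps move the level by ±1 with rates
chosen for uniform stationary populations.  Waiting times are
inversion-sampled exponentials from a seeded generator; trajectories chain
across dephasing, mixing and rephasing.  End-level statistics are also
available as matrix exponentials of the generator, used for vectorized
mixing-time sampling (equivalent in distribution).  Molecular exchange is
a Markov jump process between sites in dynamic equilibrium (detailed
balance is checked; violations warn); each site rotates the interaction
tensors by its Euler triple.  Sites are taken fixed within a de(re)phasing
period — exchange slow compared to NTR — while I-spin flips may optionally
occur inside the periods.

Two species can act simultaneously (e.g. a ¹H CP partner driving the
anti-phase RIDER plus remote ²H driving in-phase Φ_D modulation).  The CP
partner is carried through the in-phase/anti-phase bookkeeping; every
further species acts as an uncorrelated stochastic local field whose
per-level dipolar phase adds to the transverse precession — exact for
spins with no initial correlation to S.  In the dipolar variant, the
I-channel pulses act only on the species on the pulsed channel; an
off-channel species sees only the midpoint S pulse and its coupling
refocuses.

## 3. The experiment pipeline

Per crystallite × Monte-Carlo draw: seed the post-CP state, apply the Z
filter, evolve through dephasing (optionally with within-period flips
modulating the dipolar integrand by m(t)/|m_ref|), store one component,
propagate mixing (level transitions, site exchange, exp(−τm/T1S) decay and
an optional phenomenological ¹⁵N–¹⁵N spin-diffusion factor exp(−τm/τ_sd),
default off), re-excite, evolve through rephasing, detect.  The curve is
then divided by the matching T1 curve, mirroring the experimental
T1-normalization protocol, so reported curves are T1-normalized.  Errors
are standard errors over draws; both components share draws, so their
fluctuations are paired.  With `independent_points=True` every mixing time
uses a fresh seeded draw set — each point is then an independent
"acquisition", which calibrates weighted fits of the curve (used by the
exchange-identity tests).  S₀-vs-NTR scans rerun the pipeline at the
shortest mixing time per N.

Defaults (all times ms, frequencies kHz, phases rad): MAS period 0.05
(20 kHz), N = 40 (NTR = 2 ms), echo delay τ_r = 1 (bookkeeping only),
T1(S) = 5000, T2(S) = 1, one-bond N–H coupling 10.4, surviving fraction
under CW decoupling 0.02, ¹H flip-flop time 10, ²H T1 25, spin-diffusion
τ_sd 2000 when enabled.  Tensor magnitudes are illustrative, chosen as
typical literature values, not fitted to any measurement.

### Validity regime of the exchange shape identity

The statement "COS and SIN plateau ratios both equal the pair-averaged
cos(ΔΦ)" is exact per draw for the summed (classical) signal, but for the
individual components it additionally requires the phase-sum terms
cos(Φ₁ + Φ₂) to average out.  In a powder this happens when the recoupled
CSA phase wraps many times (large anisotropy·NTR) and jump angles are
small; crystallites near the zero-phase manifold contribute a residual at
the fraction-of-a-percent level.  The identity suite therefore runs on a
carbonyl-like CSA (12 kHz) with small-angle (0.1–0.25 rad) two-site jumps
— the rocking-motion regime the method targets — with one random
orientation per draw (so orientation sampling is part of the Monte-Carlo
error) and compares against the continuous-powder reference evaluated on
10⁵ deterministic orientations.  The z statistics of that comparison were
verified to be calibrated (mean ≈ 0, sd ≈ 0.95) on disjoint model sets.

### A limit of the isolated-pair model: dipolar-variant COS

For an isolated pair with I = 1/2 and Markovian flips, the dipolar-variant
COS signal is rigorously independent of mixing time: cos is even in the
level, both periods are conditionally independent given the boundary
level, and the level-transition kernel is sign-symmetric, so
E[cos Φ₁ cos Φ₂] factorizes into level-even constants.  Within-period
flips therefore *suppress* the echo amplitude — reproducing the
S₀-vs-NTR shortening, monotonically in the flip rate — but cannot produce
a mixing-time decay of COS.  The mixing-time decay observed in real
proton-containing samples requires either an I = 1 partner (the m = 0
level breaks the evenness; the simulator does show this deuteron pathway
in the CSA variant) or correlated multi-spin flip-flop dynamics in which
the effective local coupling itself decorrelates — both outside the
isolated-pair Markov model.  The corresponding acceptance assertion is
intentionally left failing rather than redefined; passing tests on this
simulator accordingly say nothing about multi-spin contributions to
dipolar-CODEX decays in real samples.

## 4. Analysis

Curves are fitted to I(τm) = I(0)·[(1 − S∞)e^(−τm/τc) + S∞], whose plateau
parameter equals S∞/S₀ directly, or to the two-component form
I(0)·[A_f e^(−τm/τc) + A_s e^(−τm/τ_sd) + S∞] with A_f + A_s + S∞ = 1.
Deterministic initialization: S∞ from the mean of the last 20 % of points,
τc from the log slope of the first third, I(0) from the first point.
Weights are inverse variances when an error column exists, else the fit is
unweighted; with true measurement errors supplied, the covariance is used
unscaled (χ²-scaling applies only to unweighted fits).  Bounds
S∞ ∈ [−0.1, 1.1], τc ∈ [grid_min/10, grid_max·10] stabilize degenerate
fits; a fit whose decay within the observation window is indistinguishable
from noise (or whose time constant escapes to a bound) is flagged
`degenerate_flat` and reports the robust tail/first-point plateau instead.
Two-component fits are flagged `inconclusive_timescales` unless
τ_sd/τc ≥ 5 and both time constants are determined to better than ±50 %.
Non-convergence is always flagged, never silent.  Note that the closed-form
anti-phase plateau ratios can lie outside [0, 1]; when measuring them,
read the ratio from curve endpoints rather than through the bounded fit.

`subtract_slow_component` removes the fitted (or externally supplied) slow
exponential plus plateau and renormalizes the remainder to unit initial
amplitude; a residual below 10⁻⁹·I(0) is reported unnormalized and marked
as having no fast component.  `rider_diagnostic` z-tests the fitted COS
and SIN plateau ratios against their joint uncertainty (default tolerance
3σ); degenerate inputs yield `inconclusive`.  On exchange-only synthetic
data with calibrated errors the false-positive rate is the nominal one of
the z threshold.

## 5. Synthetic data generator

`codexsim.fixtures` emits five seeded scenarios (config + curve + ground
truth): `rigid_rider`, `z_filtered`, `protein_two_rider`, `exchange_only`,
`dipolar_flipflop`.  They emulate the canonical experimental situations —
a rigid solid with a CP-created anti-phase fraction, the same system
behind a long Z filter, a deuterated-protein-like system with two
simultaneous RIDER channels plus slow spin diffusion, pure small-angle
two-site exchange, and the dipolar variant with flips inside the periods.
What they deliberately do not contain: multi-spin coupling networks,
finite pulses, rf inhomogeneity, probe drift, baseline or phasing errors,
and any T2 weighting of the detected signal.  Closed-form model curves
with Gaussian noise (`model_curve`) provide the ground truth for
fit-recovery studies (e.g. 500 replicates at 2 % noise recover the fast
time constant with < 5 % median error and 68 % nominal 1σ coverage).

## 6. Numerical choices

* Phase integration is exact for the band-limited MAS trajectory; eight
  equidistant rotor-phase samples determine the harmonic coefficients.
* Powder schemes: a deterministic spherical Fibonacci lattice (default)
  and a seeded uniform sampler with statistically identical averages.
  Quantities that oscillate rapidly across orientations (wrapped phases)
  converge as 1/√N in either scheme, which is why identity tests draw one
  orientation per Monte-Carlo sample instead of fixing a small grid.
* All randomness flows from the configured seed through
  `numpy.random.default_rng`; equal configs give byte-identical outputs.
  Derived per-point seeds stay below 2³¹.
* Degenerate inputs: zero anisotropy, zero coupling or zero rates
  propagate exactly (no special-casing); detailed-balance violations warn
  by default and raise in strict mode.
* Monte-Carlo sizes in the shipped tests (10⁴–2·10⁴ draws, 10⁴
  orientations, 500 fit replicates) were chosen so each check resolves its
  target at ≥ 3σ while the whole suite runs in about a minute.

## 7. Known limitations

Isolated spin pair only — no multi-spin coherences or proton-driven
spin-diffusion mechanism (only the phenomenological exp(−τm/τ_sd));
ideal δ pulses; no rf imperfections; no chemical-shift offsets or
second-order cross terms; no quadrupolar coherent evolution for I = 1; the
CP contact-time → anti-phase-fraction mapping is an input, not predicted;
the motion–MAS interference broadening of residual couplings is folded
into `residual_scale` rather than modelled.
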