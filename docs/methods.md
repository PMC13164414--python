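# Methods

This note records the models implemented in `mcrkin`, the assumptions they
make, the defaults they ship with, and the places where a design was
genuinely open and a choice had to be made.

## The bilinear model and MCR-ALS

A time-resolved powder diffraction experiment is stored as a matrix
**D** (m frames × n 2θ channels) and modelled bilinearly,

    D ≈ C Sᵀ,      C: m × q concentration profiles,  S: n × q pure patterns,

with q the number of resolvable crystalline phases.  `mcr.als_fit`
alternates exact constrained least-squares half-steps: every frame's
concentration row solves `min ‖S c − d_i‖` and every channel's pure-profile
row solves `min ‖C s − d_j‖`, each under non-negativity via the Lawson–Hanson
active-set NNLS.  Because both half-steps are exact constrained minimisers,
the lack of fit

    LOF = 100 · sqrt( Σ (d_ij − (CSᵀ)_ij)² / Σ d_ij² )

can never increase between iterations; that monotonicity is asserted in the
test suite rather than assumed.  Clip-after-solve would be cheaper but void
the guarantee, which is why it is not offered.

Scale and permutation ambiguity are intrinsic to bilinear factorisation.  The
default normalisation scales every pure profile to unit maximum (`max1`) and
moves the compensating factor into C, so resolved patterns are directly
comparable to reference diffractograms.  Closure (fixed row sums of C) is
available but off by default: diffraction intensities are in arbitrary units
and per-phase scattering power is unknown, so enforcing closure on raw C
would be physically unjustified.  All comparisons against ground truth go
through `match_components`, a Hungarian assignment on cosine similarity,
which removes both ambiguities.

Convergence: |ΔLOF| < 1e-8 between iterations, at most 200 iterations by
default.  These are practical settings for ~160×1500 matrices; the noiseless
factorisation tests push tolerance to 1e-12 to demonstrate exactness.

## SIMPLISMA initial estimates

ALS needs a starting point.  `chemcore.simplisma` ranks candidate vectors
(frames, or 2θ channels) by purity p_j = σ_j/(μ_j + δ), δ = α·max μ, and from
the second pick onward weights purity by the Gram determinant of the
length-normalised already-selected vectors augmented with the candidate
(correlation around the origin — appropriate for non-negative signals;
mean-centred correlation would treat an offset pattern as informative).
Collinear candidates get weight 0, so no variable is ever picked twice.

Both orientations are provided because sharp diffraction peaks make *both*
the purest-frame and purest-channel readings plausible: `frames` mode stacks
the selected frame patterns into S₀ (the default), `channels` mode stacks
channel time-traces into C₀.  The noise offset defaults to α = 0.03,
mid-range of the customary 1–5%.

Rank estimation reports two readings: the count of singular values above a
relative threshold (1e-10; meaningful for noiseless matrices) and the largest
gap in log σ (the noise-aware elbow).  The elbow reading is what the pipeline
compares against the number of generating phases to flag rank deficiency.

## Kinetic constraint (soft-hard modelling)

Reaction networks are lists of mass-transfer steps over named species: plain
first order (X → Y, rate k[X]), autocatalytic (X + Y → 2Y, rate k[X][Y], the
Finke–Watzky growth step), and lag-activated first order (X → Y active for
t ≥ τ).  The lag is implemented as a rate switched on at t = τ acting on the
*current* precursor amount, not as a delay-differential equation on
historical state: this preserves mass and non-negativity, matches the
observed phenomenology (no growth, then ordinary first-order growth), and
keeps the system ODE-solvable.  Integration splits at the known switch times
instead of using event detection; relative tolerance 1e-9.  Closed forms
(Bateman cascade; the logistic Finke–Watzky solution, verified against a
brute-force RK4 integrator in the tests) serve as independent oracles.

`kinetic_mcr.mcr_kinetic_fit` embeds the network into ALS.  Each iteration:

1. soft C-update (NNLS);
2. `fit_rates`: bounded nonlinear least squares over rates and lags
   minimising Σᵢ ‖C[:,i] − aᵢ·yᵢ(θ)‖², with per-component scales aᵢ
   eliminated in closed form (ratio of inner products) at every residual
   evaluation, multi-start (θ₀, θ₀/3, 3θ₀) on the first iteration, warm
   starts afterwards;
3. blend C[:,i] ← (1−λᵢ)·C_soft[:,i] + λᵢ·aᵢ·yᵢ(θ*); λᵢ = 1 is the hard
   constraint (default), λᵢ = 0 disables it bit-exactly;
4. S-update as usual.

When every component is constrained with λ = 1 the loop is followed by a
*data-space refinement*: alternating bounded least squares over (θ, a)
against **D** itself (with C ≡ model curves) and NNLS updates of S — the
classical hard-modelling MCR formulation.  The reason is statistical: the
column-space objective inherits the bias of the soft C estimate, which under
a detector-floor noise model (see below) is itself biased for short-lived
components; fitting θ against the data matrix removes most of that bias.
The refinement's fixed point defines the reported θ*, and the returned
constrained columns equal aᵢ·yᵢ(θ*) exactly, which is asserted as the
model-consistency check.  Defaults: tol 1e-7 on ΔLOF, 15 ALS iterations,
≤ 8 refinement rounds — rate estimates plateau well before that on the
synthetic study conditions.

## Synthetic study conditions

The generator emulates three liquid-assisted-grinding experiments (30, 60,
90 µL of additive).  Phases: reagents R, early 1:2 cocrystal A, Form I B,
a transient unknown phase C (60/90 µL only), the 2:1/1:2 cocrystal mixture
D, product Form II P.  Frames every 0.5 min; the first usable frame is at
t = 0.5 min (acquisition dead time — the mill runs before the detector
reads), 161 frames to 80.5 min; 1500 channels over 5–35° 2θ.

Concentration profiles come from condition-specific networks:

* 30 µL: R→A→B, lag-activated B→D (τ = 15 min), then the Finke–Watzky pair
  D→P and D+P→2P.
* 60 µL: fast R→A (120 min⁻¹ — two orders of magnitude above the frame
  rate), A→B→C, lag-activated C→D plus autocatalytic C+D→2D, D→P, D+P→2P.
* 90 µL: fast R→A, A→B→C, branching C→P (main) and slow C→D (secondary),
  D→P, D+P→2P.

Because R is consumed before the first frame at 60/90 µL, its concentration
column is numerically zero: the generated matrix has rank 5 against 6
generating species.  This reproduces, by construction, the merged-component
rank deficiency that the analysis presets handle by modelling a single RA
species.  Default rate values (0.02–2 min⁻¹ scale) were placed so the
transition windows match the qualitative milling timeline — reagents gone
within ~15 min and product complete near ~55 min at 30 µL, completion ~15–20
min earlier at 90 µL; they are synthetic defaults, not literature values.

Pure patterns are fictional pseudo-Voigt peak lists (5–8 peaks per phase,
η = 0.5, FWHM 0.18–0.30°), height-normalised so an on-grid peak evaluates to
its amplitude.  Form I and the cocrystal mixture deliberately share the
14.2° reflection, so the resolution must cope with overlapping phases.
Per-phase scattering power is folded into pattern amplitudes, keeping the
concentration profiles mole-fraction-like (initial total 1).

Noise is i.i.d. Gaussian with σ = noise_sd · max(CSᵀ) (default 2%), clipped
at zero — one SNR knob, consistent with the bilinear+error model.  The clip
emulates a counting detector's non-negative output and has a real
consequence that users of the recovery numbers should know: in empty regions
the clipped noise has positive mean (≈ 0.4σ), a baseline that a bilinear
model cannot represent.  Even an oracle given the true patterns recovers the
two short-lived early components at 30 µL only to ~0.99 cosine similarity at
2% noise; the tests therefore benchmark ALS against that oracle floor rather
than against an absolute constant.  What passing tests show is that the
resolution extracts essentially all the information the noise model leaves
available — not that real beamline data (with structured background,
preferred orientation, peak shifts) would behave identically.

## The per-impact (CLC) milling model

Transformation in a ball mill is driven by discrete impacts.  Only the
powder fraction κ caught in small volumes under critical loading conditions
reacts at each impact, so with n = f·t impacts (f = impact frequency, an
instrument setting the user must supply; default 1800 min⁻¹ in the
examples) phase fractions evolve as

    dα/dn = κ · ν(α),

with ν the right-hand side of a local per-impact scheme (per-impact rate
constants, dimensionless).  A discrete per-impact Euler map is provided as a
cross-check and agrees with the continuum mode to < 1e-3 beyond ~10³
impacts.  The product fraction α_P,start formed at the very first effective
impact is applied as a proportional transfer from the precursor pool at
n = 1.

The cocrystal phase D is carried as nucleated D_n and growth-form D_g
(observable D = D_n + D_g); product formation is autocatalytic
(D_g + P → 2P) and *seeded* by α_P,start, which is what makes the
first-impact fraction a load-bearing parameter rather than a cosmetic one.
Scheme presets: all three conditions share A→B, D_n→D_g and the D→P growth
step; only 30 µL kinetically resolves R→A; C feeds D entirely at 60 µL and
splits between D and direct product formation at 90 µL.

**Identifiability.**  ν is linear in the local rates, so the embodiment above
is exactly invariant under (κ, k) → (cκ, k/c): any trajectory determines
only the products κ·kᵢ.  This is a property of the model, not of the
optimiser, and holds for shared-κ joint fits and autocatalytic schemes
alike.  The package pins the gauge by convention: the ripening constant
k_DnDg is a fixed model constant (0.003 per impact, the same in every
scheme), making κ "the processed fraction per impact on the ripening-step
scale".  The value is chosen so ripening is rate-limiting within the D
chain — a gauge fixed on a kinetically unresolved step would leave κ
practically indeterminate.  The fitter holds k_DnDg fixed by default,
always reports the gauge-invariant products κ·kᵢ alongside the raw
parameters, and warns when asked to float the gauge.  Joint multi-experiment
fits share a single κ by default (mechanical activation should not depend on
the liquid additive); per-experiment κ fits are available to examine that
assumption.

Default per-impact rates follow a layer-consistency rule — per-impact rate ≈
per-minute network rate / (κ·f) with κ = 0.018, f = 1800 min⁻¹ — so both
model layers describe the same qualitative timeline; the 90 µL C→D branch is
set high enough that D is clearly observed at all three conditions.

## Pipeline and reporting

`pipeline.run_pipeline` chains the stages in analysis order (rank estimate →
SIMPLISMA → soft ALS → kinetic MCR → CLC fit), persists every intermediate,
and emits a versioned JSON report.  The component↔species mapping is
established by matching the soft concentration profiles against the model
curves at the initial guesses.  MCR concentrations are converted to phase
fractions for the CLC stage by solving non-negative scales s with C·s ≈ 1
(valid because the generated system is closed).  The CLC stage fits the
per-impact preset to profiles generated by the per-minute ODE networks —
a different model family — so its parameters are reported without truth
comparison.  Rate-error columns appear only where truth is known, i.e. on
synthetic runs.  Reports are pure functions of (scenario, seed, noise), and
byte-identical reproduction is part of the acceptance checks.

## Degenerate inputs and numerical edges

* All-zero data matrix: LOF undefined → error; all-zero candidate vectors
  get zero purity; zero-norm components score cosine 0 and match last.
* Zero pure-profile columns are left unscaled by the normalisation step.
* ODE outputs are clipped at 0 (solver undershoot within tolerance).
* Equal-rate chains use the matrix-exponential limit of the Bateman cascade.
* Finke–Watzky with k₂ = 0 degenerates to first-order decay; the closed form
  guards the exp overflow at large t.
* κ = 0 freezes the CLC state; compositions failing row-sum ∈ [0.9, 1.1] are
  rejected rather than silently renormalised.

## Known limitations

* No instrument aberrations, preferred orientation, amorphous halo or
  structured background in the generator; no background modelling in the
  resolution beyond optional 2θ masking at load.
* No uncertainty quantification on fitted rate constants (point estimates
  only); no reversible steps or temperature dependence in the networks.
* The unknown-phase check is a similarity screen against supplied reference
  patterns; it identifies that a profile is unassigned, never what the phase
  is.
* CLC κ is meaningful only relative to the declared ripening-gauge
  convention; cross-study comparisons must use the κ·k products.
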