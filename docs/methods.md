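# Methods

`synergize` quantifies protein segregation by extracellular-domain size at
immune synapses from two-colour fluorescence images. This note records the
models, the estimators, the numerical choices, and what the synthetic test
bed does and does not establish.

## Biophysical model

Two membrane species compete for the local inter-membrane separation
`z` at a cell:bilayer or cell:cell contact: a short receptor–ligand
complex (CD2–CD58 or KIR–HLA-Cw6; natural bond length `z_C`, default
13 nm within the 12–14 nm structural range) and the long unbound ligand
ICAM1 (exodomain length `z_I = 18 nm`). Each pays a quadratic elastic
energy for a mismatched separation,

    E_C(z) = λ_C (z − z_C)²,   E_I(z) = λ_I (z − z_I)²     [kT],

with `k_B T` absorbed into the spring constants (units kT nm⁻²; the
membrane, not the protein, supplies most of the compliance). The
point-load stiffness of a tension-plus-bending sheet
(`effective_spring_constant`) gives the order of magnitude: with
κ = 25 kT, σ = 0.02 kT nm⁻², protein radius 2 nm it yields
~0.02 kT nm⁻², consistent with the ~0.1 kT nm⁻² scale inferred from
images. We solve the annular boundary-value problem exactly in the
{1, ln r, K₀, I₀} basis with a clamped outer rim at 20 ℓ
(ℓ = √(κ/σ); the tension response is logarithmic, so some outer scale is
required) and validate against an independent finite-difference radial
solve (agreement < 2 %, tolerance 5 %). Note the stiffness *increases*
with protein radius — a wider footprint spreads the load.

### Boltzmann exclusion energies and the SQRE line

At local equilibrium each species' concentration follows
`c = c_ref exp(−E)` relative to its optimal environment (free-surface
concentration for ICAM1, optimal-binding concentration for the
complex). Eliminating `z` between the two quadratics links the
*square-root energies* (SQRE) `e = √E` linearly on the physical branch
z ∈ [z_C, z_I]:

    e_I = α − β e_C,   β = √(λ_I/λ_C),   α = √λ_I (z_I − z_C).

The line is the falsifiable signature of size exclusion: mutual
exclusion with a straight SQRE relation, slope set only by the spring
ratio. The default parameters used throughout the package are
β = 0.7, α = 1.6 (λ_C ≈ 0.209, λ_I ≈ 0.102 kT nm⁻²) — magnitudes that
also bound the energies at E_I ≤ α² ≈ 2.6 kT and E_C ≤ (α/β)² ≈ 5.2 kT,
matching the few-kT scale seen in real interfaces.

## Reaction–diffusion dynamics and the instability criterion

Five fields on the interface: free receptor R, free small ligand L,
complex C, long ligand I, separation z. Species diffuse; binding
R + L ⇌ C has constant on-rate `kon` and separation-dependent off-rate
`koff0·exp(E_C(z))`; C and I drift down their spring-energy gradients;
the membrane relaxes overdamped (response coefficient M) against
bending (κ∇⁴z), tension (σ∇²z) and the spring forces
−∂_z(C·E_C + I·E_I). Written this way the system is an exact gradient
flow of the free energy

    F = Σ_X X(ln X − 1) + C(E_C − ln K) + I E_I + ½σ|∇z|² + ½κ(∇²z)²,

with a symmetric positive-semidefinite mobility (diffusion, a rank-one
reaction channel, and 1/M for the membrane). Two consequences we exploit:

1. **Stability = convexity.** A uniform steady state is linearly stable
   at wavenumber k exactly when the reduced free-energy Hessian is
   positive definite. Schur-complementing the conserved densities gives
   the instability margin

       2λ_C C (2e_C² − 1) + 2λ_I I (2e_I² − 1) > κk⁴ + σk²,

   so k = 0 is always the most unstable mode (elasticity only ever
   penalises). Using the steady-state force balance
   √λ_C C e_C = √λ_I I e_I, the k = 0 condition collapses to SQRE
   coordinates:

       g(e_C, e_I) = e_I(2e_C² − 1) + β e_C (2e_I² − 1) > 0,

   depending on the springs only through β — which is precisely the
   slope the image regression measures. The *stability curve* is
   g = 0; the patternation test asks whether the fitted line
   e_I = α − β e_C enters the g > 0 region. Both line endpoints (pure
   complex, pure ICAM1) are always stable: patternation needs a
   balanced composition.
2. **Oracle equivalence.** `instability_condition` (the analytic margin,
   normalised by the membrane stiffness so it is an O(1) signed number)
   and `dispersion_relation` (max real eigenvalue of the directly
   assembled 5×5 linearisation) are independent code paths; their sign
   agreement over random parameter sets is the standing cross-check
   (measured 100 % over hundreds of states; the test demands ≥ 99 %
   outside a |margin| < 10⁻⁶ band).

Uniform steady states come from a bracketed scan (400 intervals over
[z_C − 5, z_I + 5] nm) of the force balance with composition
equilibrated against a free-surface reservoir (area ratio default 0.3),
followed by bisection; roots merge below 10⁻⁴ nm. The model yields 1 or
3 states; in the multistable regime (e.g. kon = 10⁻⁴ µm² s⁻¹,
koff0 = 0.1 s⁻¹, R_tot = 190, L_tot = 1000, I_tot = 100 µm⁻²) the two
extreme states hug the natural lengths and the middle state has a
positive homogeneous-mode eigenvalue.

The simulator uses flux-form explicit finite differences for the
species (face fluxes vanish at the no-flux boundary, so mass is
conserved to machine precision) and a semi-implicit cosine-spectral
step for the stiff membrane operator. The default time step is half a
conservative stability bound assembled from diffusion, drift, reaction
and spring-relaxation rates; a user-supplied dt above the bound raises
`CFLError` with a suggestion. Seeded linear-regime runs agree with the
dispersion relation to ~2 % (tolerance 5 %). The standard pattern
demonstration (128², dx = 0.06 µm, 2 s of model time) grows the
separation variance by >10³ and develops a bimodal z histogram; sizes
were chosen to keep the run under a minute on one core.

Close-contact patch statistics (`close_contact_patch_stats`) emulate
pre-binding thermal roughness as a squared-exponential Gaussian random
field (spectral synthesis, periodic domain) with mean 18 nm, sd 3 nm,
correlation length 30 nm; the sub-12 nm excursion fraction matches the
Gaussian tail (Φ(−2) ≈ 0.0228) and 8-connected component analysis gives
patch diameters ≈ 30 nm — patch seeding is generic, so an initially
unbound interface will eventually nucleate close-contact domains.

## Observation model

Counts per pixel, after deconvolution treated as independent:
free-surface pixels have homogeneous means per channel; contact-interface
pixels carry the energies,

    small ligand:  µ_S = Γ µ_fs,S + A_B exp(−e_C²) + bg
    long ligand:   µ_L = µ_fs,L exp(−e_I²) + bg,

with Γ ∈ (0,1] the entry-barrier discount on free small ligand
(default 0.63, the measured 37 % CD58 reduction) and A_B the
optimal-binding amplitude. Efficiencies are never separated from
concentrations. Noise families: Poisson (continuous extension via
log-Γ for deconvolved counts), Gaussian with variance = c·mean, Gamma
with shape k and scale mean/k (captures free-surface skew in
cell-conjugate data). 3D stacks model the apparent membrane thickness
with a Gaussian transect profile, wider on the free surface
(ruffling) than in the contact.

## Inference

Per-synapse adaptive random-walk Metropolis-within-Gibbs: scalar
globals one at a time, then all per-pixel locals as one vectorised
block (pixels are conditionally independent given globals). Proposals
reflect at the uniform prior bounds; scales adapt (Robbins–Monro,
targets 0.3 global / 0.44 local) during the first half, then freeze;
burn-in is the first half; 4 chains with seeds spawned from one
`SeedSequence`. Convergence is the classic Gelman–Rubin potential scale
reduction, house threshold R̂ < 1.1; local parameters are monitored via
per-chain running moments rather than stored draws.

Priors are uniform. Two deliberate prior-design choices, both made on
known-truth simulations and worth recording:

* **SQRE ceiling e_max = 2.5** (energies to 6.25 kT). A much larger
  ceiling is not "safely uninformative": beyond e ≈ 2 the Boltzmann
  factor is < 10⁻², the likelihood is flat, and that flat tail feeds a
  marginal-likelihood (Occam) bias into the barrier factor Γ (measured
  +0.08) which propagates into the fitted slope (+0.11). 2.5 remains
  well above the ≤ 3 kT energies these interfaces exhibit.
* **Constrained-fit local = normalised separation z_hat** with uniform
  support [−0.06, 1.06], mapped through the physical quadratic branches
  e_C = (α/β)|ẑ|, e_I = α|1 − ẑ| (energies fold back up outside the
  natural lengths, so no clamp is needed). The padding was calibrated
  by simulation so that boundary folding at the two pure phases leaves
  (α, β) centred: support barely past [0,1] biases β high (folded e_I
  cannot exceed α), wide support biases it low (prior mass in the flat
  wings). 0.06 nulls the two effects under the default study
  conditions; the calibration used its own seed set, disjoint from the
  test seeds.

The **unconstrained fit** gives independent (e_C, e_I) per pixel; the
"mean line of regression" through the posterior-mean scatter is a
weighted total-least-squares fit (scipy ODR; both coordinates are
uncertain) restricted to pixels identified in both coordinates
(posterior sd < 0.35) and detected (mean > 2 sd): at the
signal-to-noise edges the energies are prior-dominated and their
boundary-folded means would otherwise rotate the line. The
**constrained fit** imposes the line and returns (α, β) posteriors, the
slope-unity test (β = 1 means symmetric spring constants; the data
favour β < 1: accommodating unbound ICAM1 is cheaper than stretching
the bond), the patternation posterior (fraction of (α, β) draws whose
line crosses the instability region), and the reconstructed hidden
separation histogram.

Known estimator limitations, visible on synthetic truth: the flat
per-pixel priors make global posteriors mildly sensitive to the latent
separation *distribution* (an integrated-likelihood effect of order a
few per cent on β when the truth's mixing distribution is far from
uniform), and Γ retains a small positive bias (≲ 0.05) at default
counts — the recovery tests bound it at 0.12 absolute. Pixels are
treated as independent although the underlying field is spatially
correlated, so credible intervals are, if anything, optimistic for
field-level quantities.

## Imaging pipeline

Flat-field division, background subtraction with clip-fraction logging;
Richardson–Lucy deconvolution implemented with reflective-boundary
direct convolution (a flat image is an exact fixed point; FFT/zero-pad
variants leak boundary error one PSF-radius per iteration); a single
global chromatic shift per cell chosen by maximising |Pearson r| over
integer shifts (magnitude, because synapse channels are anti-correlated;
optionally restricted to a cell mask — the structureless background
dilutes the peak). 3D contour tracking is polar ridge-following about
the cell centre with a continuity limit, circular smoothing of r(θ),
and ~1 px arc resampling before rasterising to an ordered, closed,
8-connected, counter-clockwise chain; it is a stand-in for per-lab
tracing, validated only on synthetic stacks (≥ 95 % of true membrane
pixels within 1.5 px). Region extraction takes per-slice contours plus
user-annotated contact-interface limits (index pairs into the chain) and
produces disjoint masks and perpendicular transect samples for the
thickness model.

## Synthetic data

The generator draws counts from the exact observation model over a
known separation field, and returns the full truth, so every estimator
can be scored without re-derivation. Anchors: z_C = 13 nm, z_I = 18 nm,
β = 0.7, α = 1.6, Γ = 0.63, ICAM1 reference 500 µm⁻², receptor
densities 190/100 µm⁻², 167 nm pixels, 93×93×360 nm voxels,
counts in the tens–hundreds per pixel (µ_fs = 50/100, A_B = 200).

The default bilayer truth is a patterned two-phase interface: a smooth
Gaussian random field (correlation 6 px ≈ 1 µm), median-centred so both
phases are always represented (the experimental analysis selected
patterned cells with both phases visible), pushed through a soft-clipped
logistic so domain interiors sit exactly at the natural lengths with
diffuse walls, plus 0.8 nm short-range membrane roughness, clipped to
[z_C, z_I]. A 25 px contact disc in a 96×96 frame gives ≈ 1976 interface
pixels.

Default counts are Gamma-distributed with shape 4.5: real synapse
images are strongly overdispersed relative to shot noise (expression and
density heterogeneity, gain), and this is what places the default
image's interface channel correlation at r ≈ −0.53, inside the
−0.39…−0.69 per-synapse range reported for real bilayer and NK
synapses. Under pure Poisson noise at informative counts the
deterministic anti-correlated signal forces r ≈ −0.9, so shot noise
alone cannot reproduce the observed range — a fact worth remembering
when interpreting measured correlations. The recovery studies
(slope, calibration, PSF) use the pure-Poisson configuration, the
idealised shot-noise limit.

What passing tests show — and don't. The generator shares the
observation model with the estimator, so recovery tests establish
internal correctness and calibration, not robustness to model error;
real images add PSF residuals after deconvolution, spatially varying
backgrounds and gain, membrane tilt, and non-equilibrium dynamics, none
of which are emulated. The step-phantom study addresses the largest
known confound: blurring a two-level truth manufactures a continuous,
strongly anti-correlated SQRE scatter (fitted r ≈ −0.96 with only two
true levels), and Richardson–Lucy deconvolution (50 iterations) shrinks
the resulting slope error in ≥ 4/5 seeds — so the deconvolution step is
load-bearing for the biological interpretation of SQRE linearity.

The NK-like z-stack generator builds a spheroidal cell whose per-slice
circular cross-section is flattened to a chord over a 35 % contact arc,
paints the membrane as a Gaussian tube (wider on the free surface),
enriches the small ligand and excludes ICAM1 in the cap, and uses Gamma
noise; the truth includes per-slice ordered contours and labels.

## Reproducibility

All randomness flows through `numpy.random.default_rng` /
`SeedSequence` (PCG64); generators, fits and simulations are bit-stable
for a given seed. CLI commands write JSON run-logs; chain draws export
to CSV with seeds and acceptance rates.
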