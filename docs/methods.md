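# Methods

`llextract` models the liquid–liquid equilibrium (LLE) machinery behind
solvent extraction of a fermentation acid (butyric acid) from dilute
aqueous broth with a high-boiling ester (octyl acetate): the NRTL activity
model, the two-liquid-phase flash, a non-iterative tie-line–constrained
parameter estimator, a countercurrent multistage extractor, and the
annualized recovery-cost arithmetic. This note records the models, the
numerical choices, and what the synthetic data do and do not establish.

## Thermodynamic model

Activity coefficients come from the multicomponent NRTL model,

    G^E/(nRT) = Σ_i x_i (Σ_j τ_ji G_ji x_j)/(Σ_k G_ki x_k),
    G_ij = exp(−α_ij τ_ij),  τ_ii = 0,  α symmetric, α_ij ∈ [0, 1],

with ln γ_i the exact mole-number derivative of n·G^E/RT (verified against
central finite differences to 1e-7, and Gibbs–Duhem to 1e-6, in the test
suite). τ is stored dimensionless at T_ref = 298.15 K — the extraction is
isothermal at 25 °C — with an optional a + b/T form for forward
compatibility. For fitted LLE pairs the non-randomness parameter defaults
to α = 0.2, the common LLE convention; pairs missing from a parameter file
default to ideal (τ = 0, α = 0.3) with a logged warning.

The dimensionless Gibbs energy of mixing of a split is

    ΔG_mix/RT = Σ_phases Σ_i L^k x_i^k (ln x_i^k + ln γ_i^k),

with the x ln x → 0 convention at zero composition. Equilibrium requires
this to be minimal; operationally that is enforced by the tangent-plane
stability test plus the flash post-condition ΔG(split) ≤ ΔG(feed).

## Stability test and flash

`stability_test` minimizes the tangent plane distance by Michelsen-style
successive substitution on unnormalized trial mole numbers from
vertex-biased starts (0.95 on each component in turn). A converged trial
with TPD < −1e-8 flags instability and seeds the flash.

`lle_flash` solves the phase equations

    x_i^I = z_i / (1 + (K_i − 1) L^II),  x_i^II = K_i x_i^I,
    K_i = γ_i^I / γ_i^II

by successive substitution on K with an inner bisection-safeguarded
Rachford–Rice solve for L^II (brentq, xtol 1e-15). Oscillations damp the
log-K update by 0.5; trivial solutions (phases merging for an unstable
feed) trigger perturbed restarts; non-convergence after 500 iterations is
returned flagged, never silently. Converged results satisfy iso-activity
to 1e-8 and the material balance to 1e-12. Phase I is the aqueous
(water-rich) phase, resolved by the mole fraction of component 0, ties
broken on the solvent; the phase equations themselves are label-symmetric.

`binodal_curve` marches feeds from the immiscible water/solvent edge
toward the plait point, stepping the previous tie-line midpoint by 0.01 in
solute content, and stops when a feed goes single-phase or the tie-line
shrinks below 1e-3. Requested line counts are met by even subsampling of
the marched curve, always keeping the solute-free edge line.

## Parameter estimation (non-iterative K-value method)

The estimator avoids flashing inside the objective by fixing the feed and
phase split from measured tie-line geometry: the feed z lies on the
tie-line (collinearity of z − x^II with x^I − x^II; one component's value,
by default the midpoint of the two measured values, determines the rest,
and Σ z_i = 1 holds identically), and the organic fraction follows from
the lever rule L^II = d(x^I, z)/d(x^I, x^II) with Euclidean distances.
K is evaluated once at the measured compositions, the phase equations give
computed compositions (renormalized), and the objective is the unweighted
RMS of computed − measured over all components, both phases, all
tie-lines. Non-positive phase-equation denominators yield a large penalty
residual rather than an exception so optimizers can traverse.

A zero of this objective is exactly an iso-activity solution at the
measured compositions — which is necessary but not sufficient for
equilibrium: a parameter set can place a *metastable* iso-activity pair at
the data while its actual (Gibbs-minimal) phase split lies elsewhere. At a
0.003 mole-fraction noise level such spurious minima can undercut the true
parameters' residual. The estimator therefore enforces the Gibbs-minimum
requirement by construction:

1. **Diagram-type constraint.** Binary pairs for which the data contain no
   essentially-binary tie-line must remain miscible: the minimum of
   d²(g_mix)/dx² over each such binary edge (analytic binary NRTL on a
   99-point grid) enters the least-squares residual as a hinge penalty.
   Spurious solutions characteristically open a second miscibility gap;
   a type-1 tie-line pattern rules that out on physical grounds.
2. **Feasibility screen.** A candidate is accepted only if, at every
   measured feed, a cold flash (initialized from its own stability test,
   so metastable pairs cannot hide a deeper split) reproduces the measured
   phase compositions within 0.05 mole fraction and lowers ΔG_mix/RT
   relative to the homogeneous feed.
3. **Penalized refinement.** If no candidate passes, the top candidates
   are re-optimized with flash-split hinge penalties active
   (weight √10, tolerance half the screen), then re-screened.
4. **Multistart batches.** Local optimizations (scipy `least_squares`,
   trf, bounds τ ∈ [−5, 12], α fixed at 0.2 unless freed within
   [0.2, 0.47]) start from 16 Latin-hypercube points per batch
   (seeded; default seed 42, recorded in the result); up to 3 fresh
   batches run before the estimator raises an explicit failure with
   diagnostics.

Because NRTL parameters are strongly correlated, quality is judged in
tie-line space (predicted vs measured splits), never by raw parameter
values; `FitResult.predicted_tielines` exports the overlay data.

## Synthetic data

`make_demixing_system` provides deterministic presets: a symmetric
demixing binary (τ12 = τ21 = 3, α = 0.2); a type-1 ternary (one
immiscible water–ester edge, verified by edge-wise stability scans); a
broth-like ternary whose solute partitions into the ester phase (D > 1,
decreasing toward the plait point); and a quaternary broth stand-in
(water/acetic acid/butyric acid/ester) for cascade exercises. Seeded
Gaussian jitter on τ (preserving preset symmetries) yields families of
distinct demixing systems for property tests. Every preset's water/ester
edge is verified to demix at construction.

`generate_tielines` samples n tie-lines evenly over the first 70% of the
traced binodal — the experimentally accessible range: measured LLE tables
report tie-lines whose phases are clearly separable, and stop well short
of the plait point where phase analysis fails and a fixed composition
uncertainty would swamp the signal. Compositions are perturbed by
independent Gaussian noise (default sd 0.003 mole fraction, the standard
uncertainty typical of chromatographic phase analysis), clipped to [0, 1]
and renormalized; renormalization projects out the sum direction, so the
realized per-entry scatter is slightly below the nominal sd (verified to
stay within [0.002, 0.004] by a Monte-Carlo test). The noiseless truth is
returned alongside for recovery tests.

What passing the recovery regression shows: with measured-range tie-lines
at realistic noise, the constrained estimator reconstructs the underlying
binodal to better than 0.01 RMS mole fraction (typically 0.002–0.007
across noise realizations; occasional unlucky realizations reach ~0.014).
What it does not show: performance on systems with strongly
temperature-dependent τ, type-2 diagrams, electrolyte effects, or
systematic (non-Gaussian) measurement bias — none of which the generator
emulates.

## Countercurrent cascade

Stages are numbered from the top; the aqueous feed enters stage 1, the
solvent stage N, phases flow countercurrently, and each stage flashes its
combined inlet (warm-started from the previous sweep to skip redundant
stability tests). Sweeps repeat until the relative stage-to-stage stream
change falls below 1e-9 *and* overall closure is within max(10·tol, 1e-9)
— closure lags the sweep by one update, so both are required. A stage
whose combined inlet is single-phase passes it to the like phase with a
warning. The scheme is plain successive substitution: simple, robust for
the ≤ 50 stages of interest, and fast at desk scale (a 32-stage run on the
packaged broth streams converges in ~40 sweeps, a few seconds). Recovery
(outlet/feed component flow), distribution coefficient
D = x_org/x_aq, selectivity S = D_solute/D_water, and the lever-rule
mixing point (flow-weighted mean; distance ratio equals the molar flow
ratio identically) round out the module. No rate-based stages, hydraulics,
or closed-loop flowsheet convergence; the packaged feed stream already
contains the recycle, so the cascade is evaluated open-loop.

## Economics

Unit recovery cost = (investment/payout_years + annual utilities) /
(product_rate · hours_per_year), with straight-line annualization matching
the payout-time convention (5 yr, 8000 h/yr defaults; a capital-recovery-
factor option with a discount rate exists but is off by default). The
packaged cost table carries the extraction + three-column train line items
(1.032 M$ investment, 0.273 M$/yr utilities) and the 265 kg/h product
bottoms rate, giving $0.23/kg. The product rate is an input, not computed:
the product stream is a distillation bottom, outside this package's scope.

## Problem sizes and runtime

The test suite runs at desk scale: the flash-vs-oracle sweep uses 20
random demixing ternary instances (8 in the module-level variant); the
recovery regression fits 6 tie-lines with 16 starts (seconds to ~1 min
depending on the noise realization); cascade properties use 1–8 stages
with a 32-stage run for the broth configuration. The acceptance script
recomputes everything from scratch in a few minutes.

## Known limitations

- The estimator's feasibility tolerance (0.05 mole fraction) is a coarse
  screen, not a statistical criterion; very noisy near-plait data can
  still yield fits whose binodal deviates ~0.01–0.015 RMS.
- Successive substitution (flash and cascade) converges linearly; strongly
  coupled columns would want a Newton-based scheme.
- The binodal tracer assumes a single two-phase region reachable from the
  water/solvent edge (type-1 topology); island (closed-loop) miscibility
  gaps are not traced.
- Three-liquid-phase splits and VLE are out of scope throughout.
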