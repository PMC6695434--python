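# Methods

`ellipshape` treats a globular protein as the uniform triaxial ellipsoid with
the same moment of inertia as its van der Waals atom model — the *ellipsoid
of equivalent steric volume* — and builds everything else on that reduction:
dilute hydrodynamics, crowded self-diffusion, reduced-scale particle
simulation, surface cartography, and composition-based shape prediction.
This note records the models, the parameters that matter, and the design
choices made where the design was genuinely open.

## Equivalent steric ellipsoid

Every heavy atom is a solid sphere of unit density with a vdW radius by
element (C 1.70, N 1.55, O 1.52, S 1.80, H 1.20 Å; anything else 1.70 Å with
a logged warning). The inertia tensor sums, per atom, the point-mass dyadic
weighted by (4π/3)r³ plus the solid-sphere (2/5)r² diagonal term; positions
are taken relative to the volume-weighted centroid (the natural centre for
the solid-body analogy; the choice matters only at the third decimal of the
semi-axes). Eigenvalues λ1 ≥ λ2 ≥ λ3 give semi-axes
a = √(5(λ1+λ2−λ3)/2M) (and cyclic) with M = Σ(4π/3)r³. Because the
semi-axes depend only on the *normalized* inertia, (4π/3)abc tracks the
geometric envelope volume of the atom cloud, not M itself; for overlapping
or sparsely sampled clouds the two differ, and the package treats the
geometric volume (4π/3)abc as "the" ellipsoid volume throughout.

Degenerate (planar) clouds with λ2+λ3 ≤ λ1 are rejected. Axis order ties are
broken deterministically: the a and b eigenvectors take a positive leading
component and c completes the right-handed triad.

Shape is the pair (α, β) with α = a/c and α^β = b/c. The prolate/oblate
boundary β(α) = (ln(α+1) − ln2)/lnα is the locus where b is the arithmetic
mean of a and c; it rises from 1/2 at α→1 toward 1, so near-spherical bodies
split evenly and elongated ones are mostly classed prolate.

Calliper (Feret) diameters scan rotations R_y(θ_y)R_x(θ_x) with both angles
on {0°, …, 89°} (the π/2 endpoint is redundant by symmetry), recording
axis-aligned extents padded by each atom's vdW radius. The worst-case
relative discretization error of the 1° grid is 1 − cos(π/180) ≈ 0.02%.
Whether published calliper protocols padded by the radii or used bare
coordinates is ambiguous; padding is used because an atom's extent *is* its
sphere, and the flag is not exposed — the difference is ~3 Å on either end.

Surface area uses the Knud Thomsen approximation with p = 1.6075, written in
(α, β, V) form; it is exact for spheres and within ~1.1% of the true
ellipsoid area, which bounds every downstream area claim.

## Dilute hydrodynamics

Per-axis translational and rotational diffusion constants of a triaxial
ellipsoid follow the Perrin-type expressions written with Carlson symmetric
elliptic integrals R_F and R_D (evaluated by `scipy.special.elliprf/elliprd`,
duplication-algorithm implementations; the test suite checks them against
adaptive quadrature of the defining integrals to 1e−8). Orientation-averaged
constants are arithmetic axis means, and the translational mean is verified
against the independent shape-reduced identity
D_t = kT/(6πη r′)·R_F(a′²/r′², b′²/r′², c′²/r′²) with r′=(a′b′c′)^{1/3} to
1e−9 relative.

Hydration enters as a rigid dilation δH of every semi-axis before the
hydrodynamic evaluation: 2.32 Å for structures without hydrogens, 2.30 Å
with (switchable). Units are fixed by contract — Å, K, mPa·s in; cm²/s and
s⁻¹ out — and pinned by the Stokes-Einstein(-Debye) sphere limits in tests.

For scaling laws, the hydrated volume of a protein of mass M_p is taken as
(4π/3)r′³ = 2.39·M_p Å³ at the modal shape α′ = 1.65, β′ = 0.34. A log-log
least-squares fit of c·M_p^{−1/3} over 40 log-spaced masses from 10 kDa to
1 MDa at 20 °C, η = 1.0016 mPa·s gives c ≈ 254 (×10⁻⁷ cm² s⁻¹); the
rotational analogue c_r·M_p^{−1} follows the same route. The in-cell variant
rescales to 37 °C, η = 0.6913 mPa·s and multiplies by the long-time
self-diffusion ratio at φ = 0.19; the critical volume fraction behind that
attenuation is an explicit parameter (φ_c = 0.58 gives a ≈0.34 factor,
0.64 gives ≈0.37) rather than a hard-coded 0.35.

## Crowded self-diffusion and the rate optimum

Short-time self-diffusion uses the Tokuyama-Oppenheim form; long-time
self-diffusion divides it by the cage factor
1 + κ(D_S^S/D⁰)(φ/φ_c)(1−φ/φ_c)^{−2}, vanishing at φ_c, with κ = 2 as the
protein-calibrated default. The reaction-rate proxy φ·D/D⁰ is maximized by
closed form for the quadratic hard-sphere model (argmax exactly φ_c/3, i.e.
19% for φ_c = 0.58) and by 1e−5 grid scan for the cage model. When a
φ_c(α, β) surface is supplied the product is jointly maximized over shape,
optionally weighted by the dilute triaxial reduction factor.

Fitting (φ_c, κ) to D(φ)/D⁰ data uses bounded nonlinear least squares with
deterministic initialization (φ_c at 1.05× the largest observed φ, κ at 2);
κ may be frozen. Data not reaching φ = 0.2 are flagged as poorly
constraining the extrapolation.

## Soft-spheroid dynamics

Particles are unit-steric-volume spheroids interacting through the uniaxial
Gay-Berne potential truncated at ζ_cut = 2^{1/6} (no shift; the force is
zero at the cutoff, so only the repulsive branch acts and the particles are
soft quasi-hard spheroids). The length parameters ℓ∥, ℓ⊥ are calibrated in
closed form so two parallel particles have V = 1 kT at end-to-end contact 2a
and side-by-side contact 2c; for parallel spheroids the range parameter is
exactly 2ℓ∥ or 2ℓ⊥, so no root finding is needed. ε defaults to 1 kT.

Reduced units kT = 1, γ_t = γ_r = 1, δt = 1e−4. Two integrators: first-order
Euler-Maruyama Brownian dynamics (orientation drift is gradient descent of
the potential along the unit symmetry axis, with isotropic rotational noise
perpendicular to it), and unit-mass, unit-moment Langevin dynamics. The
orientation state is the unit axis vector — sufficient for a uniaxial body.
Deep overlaps are handled twice over: the pair energy is linearized below
ζ = 0.15, and the per-step deterministic displacement is clamped at
0.05 σ_min (forces this large occur only during compression from random
starts; at equilibrium the clamp never engages).

A state point runs as: random sequential insertion at φ ≤ 0.15 → box ramped
linearly to the target φ over 10⁴ steps with affine position rescaling →
10⁴ equilibration steps → production with wrapped and displacement-
accumulated positions sampled. Pair forces use a Verlet neighbour list
(skin 0.4, rebuild on half-skin displacement). One seed governs every random
number in a run; repeat runs are bit-identical.

Diffusion constants come from time-origin-averaged MSD slopes, D = slope/6,
over a configurable lag window (late lags for crowded runs, early lags for
free particles where the whole curve is linear), with particle-block
standard errors and a log-log exponent flag for caged or ballistic motion.

**Scale.** The published-scale protocol (8100 particles, 2.5×10⁵ steps) is
reachable through the config but the package's working defaults are a desk
scale: 256 particles and 3×10⁴–10⁵ production steps. φ_c(α) extraction uses
four volume fractions {0.30, 0.40, 0.48, 0.54} approaching arrest — the
informative region for the cage-model extrapolation — at three seeds. At
this scale the sphere gives φ_c ≈ 0.54 (the full-scale value is ≈0.565) and
α = 1.6 spheroids are consistently higher by ≈0.03–0.05; the desk scale
resolves the *ordering* of φ_c with shape, not its absolute value to the
third decimal.

## Collision cartography

For Gay-Berne runs a collision is the onset of a contiguous ζ < 1 interval
of a pair; for triaxial ellipsoids, which the uniaxial Gay-Berne form cannot
represent, a dedicated "ghost" run propagates interaction-free anisotropic
Brownian motion (per-axis D_t, D_r from the dilute triaxial theory,
normalized to mean D_t = 1) and detects surface-overlap onsets with the
Perram-Wertheim contact function. Contact states carry hysteresis (release
only once the tangency scale clears 1.02) so boundary flicker cannot spawn
duplicate events. The contact location on each body is the surface point
along the inter-centre direction in that body's frame. Because collisions of
a persistent neighbour pair are temporally correlated, collision maps are
statistically smoother than their event count suggests; tests therefore
bound bin deviations rather than applying an iid χ² test.

## Surface maps

The body-frame surface is parameterized by θ (from the a-axis) and φ_s
(from b toward c) through the radial distance t(θ, φ_s); maps are 180×360
images with pixel centres at half-degrees. Geodesic distances are shortest
paths on the 8-connected pixel lattice (wrapped in φ_s) with Cartesian step
costs between pixel-centre surface points — the image-walk algorithm, run
here as true Dijkstra on a cached sparse graph. Eight-connectivity carries a
few-percent direction-dependent metrication error; against a 0.25° refined
lattice the 1° grid agrees within 3%, and sphere quarter-great-circles are
recovered within 2%.

Deposits are Gaussian spots exp(−g²/2σ²) with σ = 10° interpreted as a
standard deviation of geodesic *arc*, converting length to degrees through
the local surface radius at the deposited point (a flat-pixel-degrees mode
exists behind a flag). Deposition is additive; maps are presented without
sinθ area weighting (matching the field's presentation), with an
area-weighted mass available for quantitative symmetry checks.

Dimer contact centres shrink both partners' equivalent ellipsoids by a
common factor about their own centres to external tangency — bisection on a
Perram-Wertheim overlap predicate — and report the tangency point in each
body frame. Residue-value maps project surface Cα atoms (fractional radial
extent m ≥ 0.75 by default; the literature does not pin this threshold)
radially to the surface and show the ratio of value-weighted to unweighted
deposits, i.e. a smoothed surface average; an optional 180° flip about a
puts the lower-valued face in 0 < φ_s < 180 (idempotent canonicalization).

## Composition models

V = 203·N Å³ and A = 47·N_s Å², with N_s = Σ counts_t·propensity_t.
Inverting the area model gives a unique α for each β, so composition fixes
shape; chains holding N_s/N = 0.55 can stay spherical only above
N_min = 36π·203²/(0.55³·47³) = 270 residues. The binary surface/core (HP)
model takes the binomial mode N_s = N/2, and edit operations (surface/core
insertions, deletions, swaps) re-solve α, flagging sub-spherical outcomes.
The packaged per-type surface propensity table is a synthetic,
plausibility-ranked placeholder (11 of 20 types above 0.5, mean ≈0.55) for
fixture work — clearly labelled, and replaceable by any measured scale. The
HP-model α values computed with the rounded constants 203 and 47 differ by
~2–3% from published figures derived from unrounded fits; tests assert the
band, not the printed digits.

## Synthetic data

The generator fills a prescribed triaxial ellipsoid with uniformly
distributed atoms (cube-root radial sampling), one flagged Cα per residue,
eight atoms per residue, and a protein-like C:N:O:S ≈ 62:17:20:1 element
mixture so radius statistics resemble structures; the 0.64 packing-density
and 3.1 Å-per-residue conventions set the volume-per-residue scale used by
`GeneratorSpec.for_protein`. Dimers are two axis-aligned clouds posed at
external tangency along a requested body direction with the ground-truth
contact angles returned. Scalar tables implement uniform, c-pole-low
(2× surface contrast in a 45° cap), and radial-gradient (4× core-to-surface)
patterns with optional log-normal noise. Everything is deterministic under
its seed.

What the generator does *not* emulate: bonded geometry, secondary structure,
side-chain packing anisotropy, rough non-ellipsoidal surfaces, or realistic
sequence statistics. Tests passing on these fixtures show the estimators are
correct for bodies that truly are uniform ellipsoids; on real structures the
equivalent-ellipsoid reduction itself, not the code path, is the dominant
approximation.

## Known limitations

- No hydrodynamic interactions in the particle simulations; crowding enters
  only through direct soft repulsion, so absolute φ_c values sit a few
  hundredths below hard-particle literature values.
- The Gay-Berne simulator is uniaxial; triaxial bodies are covered only by
  the interaction-free collision atlas.
- Ellipsoid geodesics are lattice approximations (few-percent bias), not
  exact elliptic-integral geodesics.
- The anomalous-diffusion regime of heterogeneous cytoplasm is out of scope;
  all crowding formulas assume normal diffusion with a single φ_c.
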