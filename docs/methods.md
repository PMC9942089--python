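# Methods

## Model

The tip–sample interaction of a CO-terminated probe over a flat-lying
molecule is decomposed into four contributions:

* **Short-range (Pauli) repulsion** from the overlap of the probe and
  sample electron densities,
  E_SR(R) = V₀ ∫ ρ_sample^α(r) · ρ_tip^α(r − R) dV, with V₀ = 18 eV·Å³ and
  α = 1 by default. With α = 1 this is a plain cross-correlation of the two
  densities; it carries the chemical contrast (bond order, heteroatoms,
  halogen size) because the sample density itself does.
* **Electrostatics** as the convolution of the total sample potential
  V_sample with the tip differential density,
  E_ES(R) = ∫ V_sample(r) · Δρ_CO(r − R) dV, where Δρ_CO is the
  CO-minus-atoms density difference: neutral by definition, with dipolar
  and quadrupolar axial structure.
* **Dispersion** as the attractive r⁻⁶ pairwise sum over atoms with
  probe–element C6 coefficients (geometric-mean combination of UFF-derived
  homonuclear values, C6 = 2εr₀⁶). There is no r⁻¹² term; the repulsive
  wall is carried entirely by E_SR. Distances are clamped below a
  per-element minimum-approach radius (r_cov + 0.6 Å) so the sum stays
  finite; the clamp region lies far inside the repulsive wall and is never
  sampled by a physical scan.
* **Tilt** of the CO probe, E_tilt = ½κ(δθ)², with δ = 3.02 Å the lever
  arm from the pivot atom to the O apex and κ the lateral stiffness in N/m
  (converted internally by 1 eV/Å² = 16.02177 N/m). κ spans 0.4–1.0 N/m in
  the standard parameter grid; softer attachments tilt more and blur/widen
  the apparent structures.

Both correlation integrals are evaluated as FFT cross-correlations on the
periodic orthorhombic cell, so one FFT pair yields the energy at every
probe lattice position. Periodicity in z is formally wrong but harmless:
the default cell keeps ≥ 8 Å of vacuum above the scan range, making
wrap-around contributions negligible (validity condition, not enforced).

## Synthetic fields

The generators stand in for DFT-derived inputs; any of them can be
replaced by grids read from XSF or cube files.

* **Electron density**: ρ(r) = Σ_a N_val,a · exp(−|r−R_a|/λ_a)/(8πλ_a³),
  one isotropic exponential per atom normalized to its valence-electron
  count. Decay lengths follow λ = 0.24 + r_cov/20 Å (0.26–0.31 Å across
  the ten supported elements). The narrow band mirrors real valence
  densities, whose asymptotic decay is set by ionization energies rather
  than atomic size; it lets heavier atoms reach slightly farther (halogens
  stay visible at large tip heights) while keeping overlap energies at
  chemically sensible magnitudes (E_SR ≈ 0.1–1 eV at imaging heights).
  Grids coarser than 0.5 Å are refused; at the default 0.15 Å spacing the
  quadrature norm of every profile is within ~0.1 % of its analytic value.
* **Ionic charge**: Gaussian-smeared +N_val point charges
  (σ ≥ 2 voxels enforced; default 0.4 Å). Electron and ionic totals
  balance, so the combined charge entering the Poisson solve is neutral to
  quadrature accuracy.
* **Sample potential**: spectral solution of the periodic Poisson equation
  with the k = 0 mode zeroed (zero-mean potential). A net-charged input is
  refused unless `neutralize=True`, which adopts the uniform-background
  (Ewald) convention. Units are e, Å, eV throughout, with
  e²/4πε₀ = 14.399645 eV·Å.
* **Tip differential density**: two opposite-signed axial Gaussian lobes
  (apex-negative; defaults q = 0.2 e, ±0.25 Å, σ = 0.35 Å) plus an
  optional charge- and dipole-free quadrupole triplet. The discrete
  integrals are rebalanced so the net charge vanishes below 10⁻⁶ e. The
  multipole strengths are free model parameters — CO-like in sign and
  order of magnitude, not fitted to any reference density.
* **Probe total density** (for E_SR): a single exponential at the apex
  normalized to the 10 valence electrons of CO with λ = 0.28 Å.

## Probe relaxation

The tilt is parameterized by the lateral displacement s of the probe from
the untilted axis (probe = pivot + (s, −√(δ²−s²)), θ = asin(|s|/δ)),
capped at θ = 0.5 rad, the validity limit of the small-angle
approximation; capped probes are flagged. The relaxation drives the
generalized force — the tangential interaction force plus the spring
restoring force — below 10⁻⁶ eV/Å.

Two numerical choices matter here:

* The interaction force used in the residual is the trilinear
  interpolation of lattice-sampled force grids (central differences of
  E_total on the grid). Interpolating the *force* gives a continuous
  residual; the gradient of the interpolated *energy* is discontinuous
  across voxel facets, and minima pinned on a facet would make a 10⁻⁶ eV/Å
  tolerance unreachable.
* Descent steps are −R/h with a per-probe stiffness h, initialized from
  the spring constant plus the lever-curvature term −F_z/δ and updated by
  Barzilai–Borwein secants, under a per-probe trust radius; steps are
  accepted only if the residual norm (or the energy) decreases. On smooth
  fields the accepted-step energy is monotonically non-increasing, and the
  iteration is exact for linear PES fixtures. All probes of an image are
  relaxed together as one vectorized batch.

Scans approach from the farthest z in Δz = 0.1 Å steps, warm-starting each
relaxation from the previous tilt (deterministic: θ = 0 at the top, no
randomness anywhere in the simulation path). F_z(z) is the central
difference of the relaxed energy (one-sided at the endpoints).

## Spectroscopy and imaging

The finite-amplitude frequency shift is the weighted force average
Δf(z) = −(f₀/πkA) ∫₋₁¹ F_z(z + A(1+u)) · u/√(1−u²) du, evaluated with
64-node Chebyshev–Gauss quadrature on a cubic spline of the sampled force
curve; z is the closest-approach position. The linear-force case
Δf = −(f₀/2k)·c is reproduced exactly for every amplitude, and A → 0
recovers the force-gradient formula at the oscillation midpoint. Cantilever
defaults f₀ = 30300 Hz, k = 1800 N/m are typical qPlus sensor values chosen
by this package and exposed as configuration.

Tip–sample distances are measured between the closest oscillation turning
point and the mean atomic z-plane. A stack shares one relaxed per-pixel
scan across all heights and amplitudes (the scan depends only on κ), which
is what makes the 24-subset builds affordable. Rendering maps each image's
[min, max] linearly to [0, 255] (most negative Δf darkest; constant maps
render 128); per-stack normalization is available via a flag. Whether the
original collection normalized per image or per stack is not documented;
per-image is the default here.

## Dataset layout

One subset directory per (A, κ) pair named `A{amp:05.2f}_K{kappa:05.2f}`
(zero-padded so lexicographic equals numeric order), one folder per
molecule named by its CID-like integer id, ten PNGs `df_0.png` (farthest)
… `df_9.png` (closest), a `stack.json` sidecar, and root-level
`layout.json`, `manifest.json` and JSON indexes (formula → CIDs,
CID → name/formula). Rebuilds are idempotent: a molecule is skipped when
every recorded image checksum matches the file on disk. JSON was chosen
over serialized-object dictionaries for language neutrality.

## Fixture generator

`fixture_molecules(seed)` constructs six quasi-planar molecules (8–30
atoms, all inside the 24 Å cell) jointly covering all ten supported
elements, including a halogen/hydroxy-substituted aza-ring of composition
C5H2BrClINO (the canonical halogen-contrast test case) and a methylated
ring with sp³ out-of-plane hydrogens (z-extent 1.78 Å, probing the
quasi-planarity bound), plus four molecules each violating exactly one
selection rule. The seed jitters xy coordinates by ≤ 0.03 Å; all geometric
invariants hold for every seed, and a given seed is bit-reproducible.

What the synthetic fixtures do *not* emulate: self-consistent charge
rearrangement (bonds, lone pairs, σ-holes beyond the imposed tip/sample
multipoles), adsorption-induced relaxation, or absolute DFT energy scales.
Passing tests therefore validate the machinery — correlations, Poisson
solve, relaxation, quadrature, bookkeeping — and qualitative contrast
ordering, not quantitative agreement with measured force spectra.

## Problem sizes and defaults

Field grids default to 0.15 Å spacing (160×160×133 for the 24×24×20 Å
cell); tests and the acceptance script use 0.375 Å (64×64×53), where a
full 256×256, 10-height stack takes ~25 s on one core. Oracle comparisons
against O(N²) direct sums use 16³ grids. The Poisson oracle uses a 32 Å
cube with the analytic erf potential corrected by two shells of periodic
images plus the uniform-background term, after which the solver agrees to
~3·10⁻⁵ relative.

## Known limitations

* Orthorhombic cells only; xy periodicity is assumed in the scan raster.
* The vdW clamp makes energies inside the minimum-approach radius
  constant, so forces there vanish — irrelevant for scans above the
  molecule, wrong if grids are probed inside atomic cores.
* The tilt model relaxes a point probe on the rigid-case PES; the tip
  charge density does not rotate with the tilt (small-angle
  approximation), so contrasts at θ near the 0.5 rad cap are qualitative.
* Δf conversion assumes F_z sampled densely enough for a cubic spline over
  [z, z+2A]; the Δz = 0.1 Å default satisfies this for all standard
  amplitudes.
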