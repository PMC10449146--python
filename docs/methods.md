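# Methods

## The estimation problem

Scattered photons reaching a CT detector add a smooth, object-dependent
bias to every projection; estimating the scatter image quickly and
accurately is the core of deterministic scatter correction.  `qmcffd`
estimates, for a point X-ray source, a voxelized phantom and a flat
pixel detector, the probability per source photon that a photon reaches
detector pixel `D_j` after exactly `i` interactions (Compton or
Rayleigh), for `i = 1..n`, together with the unscattered (primary)
image.

The probability of the full path `S → A_0 → A_1 → … → A_i → D_j` is a
product of per-leg factors — emission, free-path, scatter-type,
deflection, and escape — and the expectation over all paths is a
`4n`-dimensional integral: each scatter order consumes four uniform
variates (one for the interaction type, two for the scatter direction,
one for the free path; the first order uses energy, two emission
variates and one path variate).  The estimator averages a weighted
per-history detector functional `f_{n,j}(u)` over `N` points `u` in
`[0,1)^{4n}`: pseudorandom points give the Monte Carlo variant,
scrambled Sobol' points the quasi-Monte Carlo variant, whose smoother
integrand coverage yields a substantially smaller replicate variance at
equal `N` (asserted, not assumed, by the test suite).

## Forced fixed detection

Two variance-reduction devices make the integrand smooth and every
history informative:

* **Forced interaction.**  The free path to the next interaction is
  drawn from the exponential law *truncated to the in-phantom segment*:
  with total optical depth `τ` to the boundary, the depth is
  `-ln(1 - (1 - e^{-τ}) u)`, and the photon weight is multiplied by the
  interaction probability `1 - e^{-τ}`.  Chains never leave the phantom
  and always reach the configured maximum order `n`.
* **Fixed detection (splatting).**  At every interaction point `A_i`
  the analytic probability of scattering toward *each* detector pixel
  and escaping unattenuated is accumulated:

  `P_i(A_i→D_j) = Σ_δ p_{Tδ}(A_i) · p_θ^δ(cosθ_{ij}) ·
  exp(-τ(A_i→boundary, E_i^δ)) · cosα_{ij} h² / r_{ij}²`

  where `δ ∈ {Compton, Rayleigh}`, `p_{Tδ} = μ_{Tδ}/μ_tot`, `p_θ^δ` is
  the per-steradian deflection density, and the last factor is the
  pixel solid angle in the point approximation.  The recorded
  contribution is `W_i · P_i(A_i→D_j)` with weights
  `W_1 = 1 - p_0` and `W_i = W_{i-1} (p_{T0}+p_{T1}) (1 - p_{i-1})`:
  the `(p_{T0}+p_{T1})` factor accounts for survival against
  photoelectric absorption when the chain is continued, while the
  splat's own `δ`-sum carries the scatter-type probabilities.  Weights
  are non-increasing by construction.

Unbiasedness of this scheme is verified against an independent analog
Monte Carlo oracle (natural free paths, explicit absorption,
rejection-sampled deflection angles, binary pixel hits) and, for order
1, against a deterministic brute-force quadrature of the path integral.

## Geometry

Right-handed world frame, source at the origin, beam along +y.  The
phantom is centered on the beam axis 500 mm from the source; the
detector plane is 500 mm beyond the phantom center (1000 mm from the
source), normal facing the source, in-plane axes +x and +z.  The full
detector is 512 × 512 pixels of 0.8 mm; coarse `n × n` grids covering
the same 409.6 mm aperture are used during transport (the per-pixel
solid-angle integrand is smooth, so a 16 × 16 splat grid reproduces
detector totals to ~0.1% of a 32 × 32 grid at a fraction of the cost;
full-resolution images are recovered by conservative bilinear
upsampling).  Voxels are half-open boxes; a point on a shared face
belongs to the voxel in the positive direction, which makes the
Amanatides–Woo traversal watertight.

Emission maps two unit variates bilinearly onto the phantom-facing face
of the phantom bounding box and normalizes the source-to-point vector.
Every emitted photon therefore enters the phantom, and `W_0 = 1` is the
natural "per source photon aimed at the object" normalization.  This
parametrization deviates from exact solid-angle uniformity over the
cone by O(half-angle²) ≈ 1% across the widest scene, which is absorbed
into the definition of the source (the emission law *is* the source
model, and the deterministic primary projector uses no angular factor
for the same reason).

## Physics model

Attenuation tables (photoelectric, Compton, Rayleigh components in
1/mm) for air, aluminium, cortical bone (ICRU-44 composition), soft
tissue (ICRU-44) and water are bundled as small CSV files on a 60-point
log grid over 16–120 keV and interpolated log-log; energies outside the
grid raise.  The tables are generated once (scripts in `scripts/`) from
closed-form models:

* Compton: free-electron Klein–Nishina, exact total and differential
  forms.  A crude incoherent-scattering-function correction
  `S(x,Z) = Z u²/(1+u²)` is available behind a flag and off by default.
* Rayleigh: Thomson × squared one-parameter screened form factor
  `F(x,Z) = Z (1+(x/(g Z^{1/3}))²)^{-2}`, with the single screening
  constant `g` calibrated to a tabulated aluminium coherent cross
  section at 60 keV.
* Photoelectric: `σ ∝ Z^{4.5} E^{-3.1}` per atom, calibrated to a
  tabulated aluminium value at 30 keV; mixtures combine by mass
  fraction.

These models reproduce total attenuation of the bundled materials to a
few percent across the window (no absorption edges, no Doppler
broadening, no relativistic form factors).  The *angular* fidelity is
weaker: a free-electron Compton kernel does not suppress forward
incoherent scatter and the one-parameter form factor is only an
approximate shape, so forward single-scatter — exactly the component a
forward-geometry detector collects — carries the largest model error.
Consequently the absolute per-order detector totals computed here run
about a factor 2 above values computed from bound-electron DCS
databases, while order *ratios*, image shapes, estimator unbiasedness
and QMC-vs-MC variance orderings are insensitive to this (the tests
separate these claims accordingly).

The bundled source spectrum is a 120 kVp-like Kramers bremsstrahlung
shape filtered by 2.5 mm of aluminium, tabulated on 1 keV bins over
16–120 keV (no characteristic lines); any two-column CSV can replace
it.  Compton-scattered energies falling below the 16 keV table floor
are clamped there by default (a flag zeroes the photon weight instead);
such photons carry negligible weight through the escape exponential
either way.

## Sampling machinery

* **Streams.**  Scrambled Sobol' (Owen scrambling; distinct scramble
  ids are independent randomizations, which is how QMC replicate
  standard deviations are defined) or pseudorandom, both reproducible
  bit-for-bit from (kind, dimension, seed, scramble).  The plain
  unscrambled sequence is available and then starts at index 1,
  skipping the all-zeros point.
* **Walker alias tables** sample the discrete spectrum with a single
  variate; the construction (Vose) reproduces the source distribution
  exactly, which is asserted as an invariant.
* **RITA tables** (rational inverse transform with aliasing) sample the
  deflection cosine: per interval, a rational interpolant of the
  inverse CDF parametrized by the exact CDF and density at the knots;
  knots are inserted adaptively in the interval with the largest
  sampler CDF error until the sup-norm error is below 1e-4.  Tables are
  precomputed on a 64-point log-energy grid (per material for Rayleigh,
  energy-only for Compton) and the nearest-energy table is used at
  sample time; the nearest-table discretization is part of the
  documented physics approximation.
* Azimuth is uniform (`2π u`), by the azimuthal symmetry of unpolarized
  cross sections; the deflected direction is built in a local basis
  chosen by the smallest-component rule (deterministic and
  singularity-free).

## Numerics

* Transport kernels (numba) consume dense resamplings of the physics:
  attenuation components on a uniform 0.25 keV grid (linear lookup;
  ≤1e-4 relative deviation from the log-log tables, covered by the
  kernel-vs-reference equivalence tests), Rayleigh angular
  normalizations per (material, energy) by 2048-node Gauss–Legendre
  quadrature, Klein–Nishina normalization in closed form.
* Voxel traversal accumulates per-material chord lengths, so one
  traversal prices attenuation at any number of energies; chord lengths
  sum to the clipped ray length to 1e-9 mm (watertightness invariant).
* Forced-path inversion marches voxel by voxel and inverts analytically
  inside the voxel containing the target optical depth — exact to
  rounding, no iterative solver (verified to 1e-8 mm against closed
  forms and a bisection oracle).
* Direction components below 1e-12 are treated as exactly zero.
* A segment with total optical depth ≤ 1e-12 (vacuum) cannot be forced:
  the library raises; the kernels end the history with zero further
  contribution.

## Problem sizes

The canonical runs use N = 2^17 histories with n = 10 orders for the
aluminium slab and bone-tissue cylinder (matching their printed
convergence order) on the 16 × 16 splat grid; variance comparisons use
N = 2^15 with 20 replicates per sampler on a 4 × 4 splat grid (the
replicate summary is the scalar total detected scatter probability, so
the coarse grid changes the statistic identically for both samplers);
estimator-correctness checks use a 16 mm aluminium cube at 60 keV with
10^4 forced histories against 10^6 analog histories.  The Shepp-Logan
builder supports a scale factor so tests exercise it at reduced grids.

## Known limitations

* Cross sections are analytic approximations, not a validated photon
  database; absolute scatter magnitudes inherit the forward-scatter
  bias discussed above.  Swapping in better per-material tables (same
  CSV schema) requires no code change.
* The per-order reference values this package is compared against are
  published only as printed tables whose per-pixel normalization is not
  recoverable; the package reports detector-total per-order
  probabilities, the only reading consistent with their magnitude.
* The pixel solid angle uses the point approximation `cosα h²/r²`; its
  midpoint error grows with pixel size (≈0.5% at 15 mm pixels at
  500 mm, negligible at the physical 0.8–6.4 mm pitches).
* Ideal detector: no energy response, depth effects or anti-scatter
  grid; no Doppler broadening, fluorescence, electron transport or
  bremsstrahlung; no polarization.
* Timing-dependent figures of merit are computed from supplied (T, σ)
  pairs; wall-clock is reported but deliberately not asserted anywhere.
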