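# Methods

## Model

`hhpf` simulates single-species mesoscale fluids (and bonded two-bead
molecules) in the NVT ensemble with two interchangeable descriptions of
the nonbonded interaction:

**Multi-Gaussian core model (MGCM).** A pair potential that is a signed
sum of Gaussians,

    V(r) = sum_i a_Gi exp(-(r / sigma_Gi)^2),

with positive amplitudes acting as soft steric repulsion and negative
ones as attraction.  The canonical parameter set (`ARGON_MGCM`, a_G =
29.288 / -8.291 kJ/mol, sigma_G = 0.208 / 0.304 nm) is a two-Gaussian
emulation of the argon Lennard-Jones potential: its well (~0.74 kJ/mol
at r ~ 0.41 nm) is shallower and wider than the LJ well, which is the
price of representing a 12-6 shape with two Gaussians.

**Hamiltonian hybrid particle-field (HhPF).** Particles are scattered
onto a periodic mesh with a window function P (tri-linear/cloud-in-cell
by default; nearest-node available), the resulting number density phi is
convolved with a filter H(x) = sum_i a_i g_i(x) — each g_i a normalized
Gaussian of spread sigma_Hi — and the interaction energy is the
quadratic (incompressibility-type) functional

    W = (c/2) * integral (phi_filtered(x) - phi0)^2 dx,

evaluated by mesh quadrature.  For a fixed particle number the phi0 term
only shifts W by a constant, so the single-species dynamics are governed
by the phi_filtered^2 part.  A Flory-Huggins chi coupling is housed in
`EnergyFunctionalParams` for completeness but is never exercised: all
simulations here are single-species.

**Exact correspondence.** Because W is quadratic, the field interaction
of two isolated particles is c (H * H)(r).  By the Gaussian product
rule each filter pair (i, j) yields one effective Gaussian pair term
with sigma_bar_ij^2 = (sigma_Hi^2 + sigma_Hj^2)/2, amplitude
(2 - delta_ij) c a_i a_j (4 pi sigma_bar^2)^(-3/2), and GCM spread
sigma_G = 2 sigma_bar — N_G(N_G+1)/2 distinct terms in total, of which
only the diagonal ones are independent.  `expand_filter_to_pair_terms`
implements these closed forms; a brute-force 3-D double-convolution
quadrature in the test suite pins the convention (amplitudes agree to
machine precision, which fixes both the exponent convention of the GCM
form and the normalization of the filter Gaussians — with these choices
the diagonal term of a sigma_H1 = 0.10 nm filter lands at
sigma_G ~ 0.21 nm, consistent with the canonical MGCM parameters).

The canonical two-Gaussian filter (`TWO_GAUSSIAN_FILTER`, weights
1.1486 / -0.6882, spreads 0.1027 / 0.2150 nm) is obtained by
least-squares fitting the three-term expansion of a two-Gaussian filter
to the canonical MGCM potential on r in [0, 1.2] nm
(`fit_filter_to_potential`; the fit is reproduced by the test suite).
Since a 3-term expansion cannot equal a 2-term target exactly, the
implied field potential deviates from the MGCM curve by < 0.02 kJ/mol
pointwise.

## Mesh numerics

* Node counts are `round(box/h)` per axis (minimum 4); the spacing is
  recomputed per axis so box lengths are exact.
* Filtering multiplies the density FFT with the *analytic* Gaussian-sum
  transform at the mesh wavevectors, not the DFT of a sampled kernel;
  narrow filters therefore alias only through the window, and a warning
  fires when any sigma_H < h/2.
* **Self-energy.** On a mesh the per-particle self-interaction is not
  constant: it depends on the sub-cell position through the window
  weights and carries a spurious O(h) force.  The provider computes it
  exactly — a quadratic form in the window weights with the bandlimited
  filter autocorrelation as kernel — and subtracts it from the reported
  interaction energy.
* **Two force formulations.**
  - `spectral` (default): the external potential field c H*H*phi is
    differentiated in reciprocal space and the gradient is gathered with
    the assignment window.  The total force vanishes identically (the
    integrand is odd in k), so momentum is conserved to round-off; the
    force deviates from the exact gradient of the discrete energy at
    O(h/sigma) because the cloud-in-cell energy is piecewise linear in
    each coordinate.
  - `gradient`: the exact analytic gradient of the reported discrete
    energy (window-derivative gather of the real-space potential field
    plus the self-energy gradient).  Finite differences of the energy
    reproduce it to round-off; Newton's third law holds only to O(h),
    so for dynamics the optional `project_momentum` flag removes the
    (zero-mean) net force each step.  This formulation needs two FFTs
    per step instead of four and is used for the long production runs;
    at the production resolution the two formulations differ by less
    than the intrinsic mesh error and give the same phase behavior.
* Mesh arithmetic runs in float64 by default; the long acceptance runs
  use float32 transforms (force error ~1e-6 relative, far below the
  discretization error, at half the cost).
* **Grid softening.**  Off-grid particle placements smear the effective
  interaction: refitting two-particle mesh scans shows |a_G2| decreasing
  and sigma_G2 increasing monotonically with h.  Orientation-averaged
  two-particle energies show the effect quantitatively: at h = 0.04 nm
  the well is ~5% shallow; at h = 0.064 nm ~12% shallow with a ~30%
  steepened core.  Phase boundaries are correspondingly sensitive: the
  two-bead system at rho* = 0.3 condenses at T* = 1.67 only for
  h <~ 0.04 nm, which is why production meshes use ~0.04 nm even though
  it is computationally the dominant cost (the optimal spacing is just
  under half the narrowest filter width, sigma_H1 ~ 0.1 nm).

## Pair engine

Direct evaluation of the MGCM sum with minimum-image convention,
truncated (no shift — Gaussian tails at the enforced cutoff
>= 5 sigma_G,max are < 1e-5 of the well depth) with cell lists rebuilt
every step (numba kernels; an all-pairs fallback handles boxes smaller
than 3 cells per axis, and a vectorized numpy all-pairs routine serves
as the independent O(N^2) oracle in tests).

## Dynamics

Velocity-Verlet integration with positions wrapped each step.
Thermostats:

* **CSVR** (canonical sampling through velocity rescaling): stochastic
  global rescaling of the kinetic energy toward the canonical gamma
  distribution, relaxation time 0.1 ps by default; preserves net
  momentum; deterministic given the run seed.
* **Nosé-Hoover chain**: deterministic chain (default length 3, damping
  0.4 ps) in the standard Suzuki-Trotter half-step split; the extended
  conserved quantity drifts < 1e-4 relative over 10^4 steps in tests.

Default pairing mirrors common practice for the two engines (CSVR with
the field engine at dt = 200 fs for monatomic runs; NHC with the pair
engine at a few fs), both freely overridable.  Initial velocities are
Maxwell-Boltzmann at the target temperature with net momentum removed;
dof = 3N - 3.  Bonds are stiff harmonic springs (no constraints):
V = k/2 (r - r0)^2 with minimum-image distances.

## Observables and classification

* **RDF**: pair-distance histogram normalized by the ideal-gas shell
  expectation, averaged over frames; the returned table carries raw pair
  counts so downstream peak detection can ignore shot-noise-dominated
  bins (< 30 pairs).
* **Second-peak criterion**: on a 5-point smoothed g(r), the first
  coordination peak is the global maximum over well-sampled bins; a
  second peak with prominence >= 0.05 above the inter-peak minimum
  signals liquid-like order.
* **Local-density bimodality**: per-frame occupancy histograms of cubic
  cells of edge 3 reduced lengths (~20 particles per liquid cell, so the
  two occupancy modes clear Poisson noise at desk-scale N; a 2-unit edge
  left the modes Poisson-merged).  A histogram is bimodal when the
  valley between the two tallest modes dips to <= 0.75 of the smaller
  mode.  Coexistence requires pooled bimodality plus >= 60% of frames
  individually bimodal, or the RDF second peak; clear vs blurred
  coexistence splits at a valley ratio of 0.5.
* **Morphology**: the time-averaged occupancy grid (edge 2 reduced
  lengths) is thresholded at the inter-mode valley; the minority phase
  is labeled with periodic 6-connectivity (union-find across the faces),
  and the largest component's spanning count maps to sphere (0),
  cylinder (1), slab (>= 2), with droplet/bubble from whether the
  minority is the dense or dilute phase.
* **Heat capacity**: c_V* as central finite differences of u*(T*)
  (one-sided at the ends); a fluctuation-based estimate
  Var(U)/(N kB^2 T^2) is available as a cross-check.  The finite-
  difference route is primary because scans are the intended input.

## Desk-scale study conditions

The full-size production sweeps behind the phase diagram (N = 8788,
5-10 ns, dense temperature grids) are out of desk scale; the package's
own experiments use sizes chosen to keep every suite runnable on one
CPU while preserving the qualitative physics:

* Single-species MGCM scans: N = 500 at rho* = 0.3, 0.2-0.6 ns per
  state point (dt = 10 fs, NHC).  Coexistence (cylinder droplet) appears
  at T* <= 1.2 and homogeneous fluid at T* >= 1.6, with the c_V*
  discontinuity in between.
* Two-bead runs: 256 molecules (512 beads) at rho* = 0.3, bonds
  r0 = 0.25 nm, k = 500 kJ/mol/nm^2 (thermal stretch ~20% of r0; the
  bond parameters of the reference two-bead study are not public, so
  these are the package's own choice), dt = 50 fs so that
  omega_bond dt ~ 0.25, mesh 100 nodes per axis (h ~ 0.041 nm),
  10^4 + 10^4 steps.  The 200 fs time step that suffices for monatomic
  field runs is unstable for any usefully stiff bond.
* Synthetic classifier fixtures (uniform gas, half-box density
  contrast, constructed sphere/cylinder/slab grids) emulate ideal
  limits of the real states; they validate the labeling logic, not the
  thermodynamics.  What passing tests show about real data is therefore
  limited: the classifier thresholds are calibrated on these fixtures
  and on the desk-scale runs above, and near-transition state points
  legitimately flicker between blur and homogeneous labels.

## Known limitations

* No pressure/virial on the field path; NVT only.
* The chi (mixing) term is present but untested — single species only.
* Cell edge choices in the classifier assume reduced densities of order
  0.05-0.7; far outside that range the occupancy histograms need
  rebinning.
* The mesh force error decays only linearly with h near the window's
  resolution limit, so phase boundaries computed on coarse meshes are
  systematically low (see Grid softening above).
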