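# Methods

This note documents the models, numerical choices, and study conditions
behind `deltaxc`, in the order data flows through the package.

## Density representation

Densities live on explicit quadrature grids (`Grid`: points, positive
weights, optional periodic cell). Three backends are provided:

* **Uniform voxel grids** (cube-file layout; weights = voxel volume). Used
  for interoperability and by the finite-difference toy solver. Smooth,
  rapidly decaying integrands are integrated with spectral accuracy by the
  trapezoidal character of the grid; fields with a cutoff kink (the atomic
  reference profile) converge only algebraically, which is why normalization
  contracts are stated per backend.
* **Atom-centered union-of-spheres grids** (`union_descriptor_grid`): one
  Gauss–Legendre × (Gauss–Legendre in cos θ × trapezoid in φ) product grid
  per atom, truncated at the basis cutoff r_o, valid only when the cutoff
  spheres are pairwise disjoint (enforced with an error). On this grid every
  same-atom basis product is a polynomial integrated *exactly*, so per-atom
  orthonormality holds to ~1e-12 and the projection of any density supported
  inside the spheres is limited only by how well the radial rule resolves
  it. This is the reference quadrature for all descriptor work. The angular
  product rule integrates products of real spherical harmonics exactly up to
  the band limit — the same guarantee a Lebedev rule would give, with a
  simpler construction.
* **Becke molecular grids** (`molecular_grid`): per-atom spherical grids
  stitched with Becke fuzzy-partition weights, for full-space integrals of
  smooth multi-center fields when the density extends beyond the cutoff
  spheres (≈1e-6 relative at default resolution; an optional radial split at
  r_o tightens fields that kink there). Overlapping cutoff spheres make the
  1e-6 orthonormality unreachable on this backend at practical sizes
  (measured ~1e-4 at 5·10⁵ points), which motivated the disjoint-spheres
  design above; the study geometries therefore keep 2 r_o below every
  interatomic distance.

The basis is ζ̃_n(r) = (1/N) r²(r_o − r)^{n+2} (inner cutoff fixed at zero),
each raw function normalized to unit L² norm under r² dr (the closed-form
Euler beta integral), then symmetrically (Löwdin) orthogonalized via
S^{−1/2}; the transformation is deterministic and order-independent, and a
condition-number guard rejects over-complete requests. Real spherical
harmonics use the Condon–Shortley-free convention (m = −l…l ascending),
orthonormal on the sphere; the serialized c_nlm depend on this convention,
the invariants d_nl do not.

The atomic reference density ρ_atm places each species' valence charge in
the normalized raw n = 1, l = 0 profile (positive everywhere inside the
sphere); δρ = ρ − ρ_atm integrates to zero by construction. Models carry a
`use_delta` flag; projection and potential assembly are unchanged because
δρ differs from ρ by a density-independent field.

## Energy model and potential

Per species: an affine preprocessing pipeline (variance mask at threshold
1e-10, shift/scale to zero mean and unit variance, PCA truncation retaining
explained variance γ ∈ (0, 1]) followed by a feed-forward network with
sigmoid hidden layers and a linear head with trainable bias (a per-species
atomic reference energy; on by default). The total energy is the sum of
atomic outputs — permutation invariance by construction.

All derivatives are analytic: backpropagation through the network, the
affine pipeline (mask-scatter of W_pca/σ), and the power-spectrum chain rule
∂E/∂c_nlm = 2 (∂E/∂d_nl) c_nlm. Finite differences are never used in the
potential path; the directional-derivative test (observed order ≥ 1.9 in ε)
is the defining check that V_ML is the functional derivative of E_ML. V_ML
vanishes identically outside the union of cutoff spheres because every ψ_β
does.

Moments: electrons carry charge −1, nuclei their valence charge;
the traceless quadrupole follows the Buckingham convention
Θ = ½ Σ q (3xxᵀ − r²·1); Q_T = ½(q_max − q_min) of its eigenvalues; the
valence spread is −∫r²ρ. Dipoles are reported in Debye, second moments in
D·Å. For net-charged fields the dipole is origin-dependent; a warning
records the origin and the value is still returned.

## Training

The Δ-learning loss Σ((E_ref − E_base) − E_ML)² is minimized by full-batch
Adam (defaults α = 0.001, β₁ = 0.9, β₂ = 0.999; the capacity studies use
α = 0.003 with early stopping on a 10% internal validation split, patience
5000 epochs). The l2 penalty applies to weights only. Fold assignment in
cross-validation is a seeded shuffle (k = 5 below 100 samples, else 3);
exact ties select the earlier grid entry; the winning setting is refit on
all data.

Iterative (freeze-and-grow) training: iteration 1 fits on baseline
densities; each further iteration re-projects densities made self-consistent
with the current model, freezes all existing hidden layers, appends one new
hidden layer of the same width before the linear head, and retrains.
Pipelines are refit on the regenerated descriptors (stale scaling would leak
iteration-1 statistics), but inherit the previous variance mask and
retained-axis count so frozen layers keep a compatible input dimension.
Convergence is declared when the self-consistent MAE changes by less than
1% relative (with a 1e-6 Ha absolute floor, so an exactly-null correction
terminates) between consecutive iterations, capped at 5 iterations; the
returned model is the iteration with the lowest self-consistent MAE, which
makes the procedure non-increasing versus iteration 1 by construction.
Samples whose SCF fails are flagged and excluded from that iteration's MAE;
training aborts only if every sample fails.

### Why the self-consistent benchmark is regularized

With few training systems, a flexible network can interpolate the energies
while acquiring arbitrarily large gradients in feature directions the data
do not constrain; the assembled potential then reaches several Hartree
(measured: ±24 Ha unregularized versus a true functional derivative of
~0.02 Ha) and the SCF loop has no physical fixed point nearby. The
self-consistent study therefore trains with γ = 0.9 (gradients restricted
to the data manifold's leading principal axes) and l2 = 1e-2, uses linear
density mixing 0.2, and this brings the learned potential onto the physical
scale robustly across seeds (|w| ≲ 0.04 versus ±24 unregularized).
This mirrors the general observation that functional derivatives of learned
models are only trustworthy where data constrain them.

## The toy self-consistent solver

A single-particle model: 7-point finite-difference Laplacian with Dirichlet
boundaries on a uniform cube grid, attractive Gaussian wells as the external
potential, and a local baseline functional E_base = A∫ρ^p (defaults A = 0.3,
p = 4/3) with analytic derivative. The lowest n_elec orbitals are singly
occupied; linear density mixing (default 0.3; 0.2 in the correction
studies) iterates to an integrated-|Δρ| residual below 1e-8 e, warm-starting
the Lanczos eigensolver with the previous ground state and a deterministic
start vector, so identical inputs reproduce identical iteration paths (the
null correction is bitwise identical to the baseline). Energies use the
double-counting form E = Σε − ∫V_scf ρ + E_base[ρ] (+ E_ML[ρ]). The solver
claims no chemical realism; it exists to exercise the projection → gradient
→ potential → density loop on genuine 3-D grids (the study uses 20³–32³
boxes; discretization-order and two-well separability checks pin its
correctness).

## Synthetic study conditions

Geometries: a bent three-atom molecule (one six-valence-electron heavy
center, two light atoms; bond 3.4 Bohr, angle 104.5°) with seeded Gaussian
deformations of 0.08 Bohr per coordinate; draws that would let cutoff
spheres (r_o = 1.5 Bohr) touch are redrawn (a > 4σ event). Densities: per
atom, a mixture of two anisotropic Gaussians (principal widths uniform in
[0.06, 0.21] Bohr, independent random orientations, mixing weight in
[0.1, 0.9]), normalized analytically to the valence charge; widths stay
below r_o/7 so the density is compactly supported inside the spheres to
~1e-10 relative and the union grid is exact for every training integral.
The two-component family matters: its per-atom shape manifold is
higher-dimensional than the 12 invariants per atom, which is what makes the
capacity study discriminate network depth from linear regression.

Reference energies: E_ref = E_base + F[ρ] (+ optional seeded Gaussian
noise; default 0 for clean recovery, a noisy preset exercises
regularization), with the analytic target

    F[ρ] = a ∫ρ^{4/3} + b ∫ρ² + c Σ_I (∫ρ(r) e^{−|r−R_I|²/2s²} d³r)²,

a = 0.1, b = 0.0002, c = 0.02, s = 0.25 Bohr. The ρ² term is nearly linear
in the invariants (it is Σd plus an out-of-basis remainder); the ρ^{4/3} and
squared-smeared terms are not — the latter carries radial cross-terms
c_n00·c_n'00 outside the diagonal power spectrum — so depth is required:
at the study seed a linear model misses the 5%-of-std recovery bar while
the width-8 network reaches ~1%. All terms decompose over the disjoint
atomic supports, so F is exactly determined by the per-atom density shapes
the descriptors observe; with overlapping supports or centroid-based
nonlocal terms part of the target would be invisible to the features and
the recovery floor rises accordingly.

Everything regenerates bitwise from (spec, seed): each sample's randomness
comes from an independent `SeedSequence((seed, index, stream))`.

The self-consistent benchmark uses two Gaussian wells ("X" species, one
electron each; separation 3.4–4.2 Bohr, depths 2.5–3.5 Ha, widths 0.65–0.85
Bohr) on a 20³ box of 12 Bohr, with a gentler target (a = 0.02, b = 0.004,
c = 0.002, s = 0.5) and reference energies from solving the exact
(baseline + target) functional self-consistently — so the Δ-target includes
the density-relaxation contribution that iterative training is designed to
capture.

### What the synthetic world does and does not show

The generator emulates the *structure* of real Δ-learning data — localized
atomic densities with shape variability, energies from a nonlinear density
functional, self-consistent feedback — but not real electronic structure:
no cusps or shell structure, no inter-atomic density overlap, no basis-set
or pseudopotential artifacts, and reference energies that are exactly a
functional of the density (real correlation energies are not). Passing
tests therefore validate the machinery (projection, invariance, gradients,
potential assembly, training dynamics, iterative self-consistency), not
chemical accuracy on real systems.

## Problem sizes in the validation study

The study runs on one CPU: capacity/recovery at 500 training + 60 held-out
samples with width-8 networks (≤30k epochs), the learning curve over five
seeds at n = 10 vs n = 500, the self-consistent benchmark on 8 training +
10 held-out two-well systems, and quadrature/symmetry checks at the default
grid resolutions quoted above. `scripts/acceptance.py` reruns the entire
study from a single seed.

## Known limitations

* The union-of-spheres descriptor quadrature requires disjoint cutoff
  spheres; overlapping-sphere systems fall back to cube or Becke grids with
  documented looser orthonormality (~1e-4).
* Nuclear forces are out of scope (they need a host code's Hellmann–Feynman
  machinery), as is spin polarization.
* Cross-channel invariants beyond the diagonal power spectrum are not
  implemented; densities that differ only in relative m-block phases are
  indistinguishable to the model.
* Exported cube files sample the sharp synthetic densities on uniform
  grids; at coarse export resolutions the sampled field loses charge, which
  the moments diagnostics flag as a net-charge warning.
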