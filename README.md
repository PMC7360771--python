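# deltaxc

Machine-learned additive exchange–correlation functionals of the electron
density, built from atom-centered rotation-invariant density descriptors and
per-species atomic neural networks, with the analytic functional derivative
needed to deploy the learned correction inside a self-consistent field (SCF)
loop.

The package is for researchers who want to study the *mechanics* of
density-based Δ-learning — descriptor construction, invariance, potential
assembly, regularization, iterative self-consistent retraining — in a fully
controlled model world: every experiment runs on synthetic densities with an
analytically known target functional, so there is nothing to download and
every number has an independent oracle.

## The model

A valence density ρ(r) is represented by projecting it onto an orthonormal
atom-centered basis ψ_nlm(r) = Y_lm(θ,φ) ζ_n(r), where the Y_lm are real
spherical harmonics and the ζ_n are Löwdin-orthogonalized radial polynomials
ζ̃_n(r) = (1/N) r² (r_o − r)^(n+2) with compact support inside a cutoff r_o:

    c_nlm^I = ∫ ρ(r) ψ_nlm(r − R_I) d³r            (projection)
    d_nl^I  = Σ_m (c_nlm^I)²                        (power spectrum)

The invariants d_nl feed per-species feed-forward networks (sigmoid hidden
layers, linear head); the total correction is the sum of atomic outputs,

    E_ML[ρ] = Σ_I ε_{α_I}(d^I),

which is permutation-invariant by construction and rotation/reflection-
invariant through the features. Because each c_β is a *linear* functional of
ρ, the functional derivative is a finite linear combination of the basis,

    V_ML(r) = δE_ML/δρ = Σ_β (∂E_ML/∂c_β) ψ_β(r),
    ∂E_ML/∂c_nlm = 2 (∂E_ML/∂d_nl) c_nlm,

with ∂E_ML/∂d computed by exact backpropagation through the network and its
preprocessing pipeline (variance filter, standardization, PCA truncation at
explained variance γ). The correction composes additively with a baseline
functional: E_NXC = E_base + E_ML, V_NXC = V_base + V_ML.

Training minimizes the Δ-learning loss Σ_i ((E_ref,i − E_base,i) −
E_ML[ρ_i])² with full-batch Adam (α = 0.001, β₁ = 0.9, β₂ = 0.999 by
default), hyperparameters selected by k-fold cross-validation (k = 5 below
100 samples, else 3). Because a deployed correction changes the
self-consistent density, the package also implements iterative
freeze-and-grow training: retrain on densities made self-consistent with the
previous model while freezing existing hidden layers and appending a new
one, until the self-consistent error stops changing.

## A worked example

`examples/03_potential_in_scf.py` trains a regularized correction on six
two-well model systems whose reference energies come from an exact analytic
functional, then puts the learned potential inside the SCF loop:

```
6 systems; baseline is off by 16.15 mHa on average
corrected SCF converged in 72 cycles (residual 8.9e-09 e)
baseline error   15.485 mHa
corrected error    0.571 mHa
```

The baseline functional misses the reference by ~16 mHa; with the learned
correction applied *self-consistently* (the potential re-assembled from the
current density every cycle) the error drops to a fraction of a mHa, and the
converged density is a fixed point of the combined potential. The other
examples show descriptor projection (`01`), plain Δ-learning with held-out
validation (`02`), and multipole diagnostics against closed forms (`04`).

There is also a thin CLI (`deltaxc generate | project | train | cv |
iterate | evaluate | scf-toy | moments`) over the same functions; see
`deltaxc --help`.

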