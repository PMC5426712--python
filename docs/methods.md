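# Methods

## Model

A structure is an ordered list of N atoms with mean positions x° and
form factors f_k(q).  Thermal motion is modelled as independent,
isotropic Gaussian displacement: atom k moves with variance τ_k² along
each coordinate, so the 3N-vector X is Normal(x°, diag(τ_k² I₃)).  This
is the Debye–Waller picture; it ignores anisotropy and inter-atomic
correlation (see Limitations).

Under this model the distance between atoms k and l is distributed as
the norm of a 3-D Gaussian with mean separation d°_kl and per-coordinate
variance s² = τ_k² + τ_l², i.e. a noncentral χ with three degrees of
freedom:

    p(d) = d / (d° s √(2π)) [e^{−(d−d°)²/2s²} − e^{−(d+d°)²/2s²}].

Its sinc transform has an exact closed form,

    E[sinc(q d)] = sinc(q d°) e^{−q² s² / 2},

which makes the ensemble-mean Debye intensity exact as well (self terms
k = l have identically zero distance and are exact by construction).
For uniform τ the mean is the convex combination
e^{−q²τ²} I_x°(q) + (1 − e^{−q²τ²}) Σ f_k²(q): thermal motion fades the
coherent structure into the incoherent self-term floor at q ≳ 1/τ.
Mixtures of conformational states are weighted sums of such means;
weights must be supplied normalized (no silent renormalization).

## Covariance

The covariance of I_X at two momentum transfers arises from a quadruple
sum over ordered index pairs (k,l) and (m,n).  Pairs with four distinct
atoms factorize and cancel; the surviving classes are the
*autocovariance* (the same unordered pair, {k,l} = {m,n}) and the
*cross-covariance* (pairs sharing exactly one atom).  Linearizing
sinc(q d) about d° (the delta method) with the distance moments

    Var(d_kl) = τ_k² + τ_l²,   Cov(d_kl, d_kn) = ν τ_k²,
    ν = cos ∠(l, k, n),

gives, per unordered configuration,

    V°(q_i,q_j; d°)      = (τ_k²+τ_l²) q_i q_j σ(q_i d°) σ(q_j d°)
    V×(q_i,q_j; d°,d°')  = ν τ_k² q_i q_j σ(q_i d°) σ(q_j d°')

with σ(x) = d/dx sinc(x).  Counting ordered tuples, each unordered pair
appears 4 times in the auto class and each (shared atom, partner pair)
configuration 4 times in the cross class; relative to sums written as
Σ_k Σ_{l≠k} and Σ_k Σ_{l≠k} Σ_{n≠k,l} the implementation carries
prefactors 2 and 4.  This convention was fixed analytically and then
confirmed against the Monte-Carlo oracle (a wrong factor shows up as a
2× ratio; the observed analytic/MC ratio is 1 within the second-order
bias).  A two-atom system reduces to the hand-derivable closed form
V = 4(τ₁²+τ₂²) q_i q_j σ(q_i d)σ(q_j d), which is a unit test.

Consequences encoded as tests: every entry carries the q_i q_j
prefactor, so the q = 0 row/column is exactly zero (I(0) counts
electrons and cannot fluctuate); both kernels are linear in τ², so
V(2τ) = 4 V(τ) to leading order; the truncation error is second order
in the displacement, so the deviation from the true covariance falls
~4× when τ halves.

The cross term is factorized through A_k(q) = Σ_l f_l(q) σ(q d_kl) u_kl
(u_kl the unit vector k→l), reducing O(N³ n_q²) to O(N² n_q + N n_q²);
the per-q-pair elementwise products keep the cost O(N² n_q²) overall.
Analytic covariance is capped at N = 2000 atoms by default (an explicit
`force` flag overrides); a 500-atom structure on a 121-point grid takes
a few seconds.

Correlation ρ = V_ij/√(V_ii V_jj) is left undefined (NaN) on the q = 0
row rather than imputed; entries are clamped to [−1, 1] and the number
of clamping events is reported, because the second-order covariance is
not guaranteed positive semidefinite.  A negative diagonal raises
`ApproximationBreakdownError` naming the cause: it means τ/d° left the
validity region, and the numerical ensemble path should be used.

## Monte-Carlo oracles and tolerance policy

`sascov.synthetic` provides brute-force estimators that share nothing
with the analytic path beyond the model definition: conformers are
sampled directly, profiles evaluated with `numpy.sinc` over explicit
pair distances, and the sample mean/covariance compared to the closed
forms.  Standard errors: the exact std/√n formula for the sample mean
(a 10-block jackknife SE has ~24% relative noise at 9 degrees of
freedom, which makes a hard 3-SE gate over a 101-point grid fail
spuriously even for an exact formula); a 10-block leave-one-out
jackknife for covariance entries, where no closed form exists.

Covariance assertions use |analytic − MC| ≤ 3·SE + allowance with

    allowance = C ((q_i² + q_j²) τ² + (τ/d_min)²) √(V_ii V_jj),  C = 3,

matching the two classes of neglected terms: damping corrections of
relative order (qτ)² and distance-distribution corrections of relative
order (τ/d)².  C = 3 covers their O(1) coefficients and was validated
across independent seeds and toy geometries.  A floor of
10⁻¹² × max|V| absorbs pure floating-point accumulation noise at the
deterministic q = 0 entries.

The convergence-rate measurement (fitted exponent of the max-norm
deviation as τ halves between τ/d = 0.04 and 0.02) uses 2×10⁶
conformers per level: the fine-level bias is ~0.7% of the covariance
max-norm, so the MC noise floor must sit well below that for the rate
to be measurable; at 10⁵ samples the measurement is noise-dominated.

## Synthetic structures

The toy generator covers the geometries the theory distinguishes:
Gaussian clouds and uniform-density globules (compact particles; a
ball of radius R has R_G = √(3/5) R), linear chains, and two-domain
structures (two tangent balls plus a sparse linker) for mixture
scenarios.  Defaults used by the tests: a 500-atom globule of radius
15.5 Å (R_G ≈ 12 Å, protein-sized) with τ = 0.5 Å, a typical median
atomic fluctuation for a folded protein; IDP-like scenarios use
τ of a few Å.  All generation is seed-deterministic.

What the toys do *not* emulate: chemical connectivity, excluded volume
between atoms, anisotropic or collective motion, and realistic polymer
statistics for disordered chains.  Passing oracle tests therefore
demonstrates the correctness of the statistics under the stated
Gaussian model, not the realism of that model for any particular
protein; for real systems with correlated motion the numerical
ensemble path exists precisely because the independent-motion formulas
underestimate the spread.

## Form factors

Vacuum factors are standard four-Gaussian fits (f(0) = electron count)
for H, C, N, O, P, S plus a point pseudo-element "X" with f ≡ 1.  The
in-solution correction is deliberately simple: a dummy-atom
excluded-volume Gaussian scaled by c1 (default 1) and an experimental
per-atom hydration constant scaled by c2 (default 0) with no
solvent-accessibility weighting.  All ensemble statistics are
form-factor-agnostic — the oracle suite runs with f ≡ 1 — so the
simplification bounds absolute profile accuracy, not the validity of
the covariance theory.  Alternative coefficient tables load from a
plain-text file.

## Numerical choices and conventions

* sinc and σ switch to short series below |x| = 10⁻⁴; q = 0 is handled
  by the exact limits, never by division.
* Atom order is file order; pair indices are defined by it.
* Unbiased (M−1) sample covariance; weighted ensembles use the
  effective-sample-size correction 1/(1 − Σw̃²).
* Interpolation onto experimental grids is linear in I vs q (SDs
  combine linearly).
* Mutual information is reported in nats (natural log); |ρ| ≥ 1 maps
  to the largest representable float with a saturation flag.
* Correlation bandwidth is the contiguous diagonal run with
  ρ ≥ threshold (default 0.5), reported as half the run's q-span; any
  monotone definition preserves the location of its minimum, which is
  the scientifically meaningful output.
* Kabsch superposition is provided for real-space diagnostics only;
  Debye intensities are rigid-motion invariant (tested to 1e-10
  relative).
* Hydrogens are kept as given by default; they can be dropped, or
  folded into heavy atoms via per-atom implicit-hydrogen counts
  (united-atom style additive factors).
* Waters and non-water heteroatoms are excluded by default (solvation
  enters through the form-factor correction, not explicit solvent);
  flags include them.

## Limitations

* The analytic covariance is second order in τ/d°: for τ/d ≳ 0.2 the
  normal approximation to the bivariate distance distribution degrades
  (a warning is emitted) and the covariance can lose positive
  semidefiniteness.
* Independent isotropic motion is a lower bound on realistic spread;
  correlated (domain) motion typically multiplies the SD severalfold.
  Use the numerical path on explicit ensembles for such systems.
* The hydration model is a stand-in; absolute profiles at high q
  should not be compared quantitatively against shell-model codes.
* mmCIF and trajectory formats beyond multi-model PDB are out of
  scope; the exact closed-form autocovariance (numerically unstable)
  and anisotropic per-atom covariance generalizations are not
  implemented.
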