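# sascov

Ensemble mean, covariance and information content of small-angle
scattering (SAS) profiles.

## The problem

Solution SAXS/SANS measures the orientationally averaged intensity
I(q) of particles that are *moving*: every conformer of the thermal
ensemble contributes its own Debye profile

    I_X(q) = Σ_k Σ_l f_k(q) f_l(q) sin(q d_kl) / (q d_kl),

with q = 4π sin θ / λ the momentum transfer (Å⁻¹), d_kl the distance
between atoms k and l, and f_k(q) the (solvent-corrected) atomic form
factor.  For flexible systems — multi-domain proteins, and especially
intrinsically disordered proteins — the measured curve is an ensemble
average, and single-conformer modelling quietly ignores both the bias
and the structure of the fluctuations around that average.

`sascov` implements the closed-form statistics of I_X(q) when atomic
positions X are Gaussian about a mean structure x° with per-coordinate
SD τ_k per atom (the Debye–Waller picture):

* **Exact mean.**  The pair distance follows a 3-DOF noncentral χ law,
  and E[sinc(q d_kl)] = sinc(q d°_kl) · exp(−q²(τ_k²+τ_l²)/2) exactly,
  giving E[I_X(q)] in closed form; for uniform τ it is the convex
  combination e^{−q²τ²} I_x°(q) + (1−e^{−q²τ²}) Σ_k f_k²(q).
* **Covariance to second order in τ/d°.**  V(I_X(q_i), I_X(q_j)) =
  V_auto + V_cross, built from the kernel σ(x) = d/dx sinc(x); the
  autocovariance couples each pair distance with itself, the
  cross-covariance couples distances sharing one atom through the
  geometric factor ν = cos of the inter-bond angle.
* **Correlation and information content.**  ρ(q_i,q_j), the Gaussian
  mutual information −½ ln(1−ρ²) between profile points, and the
  correlation bandwidth along the diagonal — which locate the
  information-richest region of a SAS curve at qR_G ≈ 3–6.
* **Numerical path.**  The same statistics estimated from explicit
  conformer sets (multi-model PDB ensembles, MD frames), with
  confidence bands and a detectability comparison against experimental
  error bars.
* **Oracles.**  Brute-force Monte-Carlo samplers that validate every
  analytic formula, with jackknife standard errors.

## Worked example

`examples/thermal_covariance.py` builds a 500-atom globule
(R_G ≈ 12 Å), lets every atom vibrate with τ = 0.5 Å, and evaluates the
analytic theory:

```
R_G:                      12.12 A  (tau = 0.5 A)
SD at q = 0:              0.0 (exactly zero by construction)
SD peak:                  q = 0.145 A^-1
relative SD:              mean 3.19%, max 6.75% at q = 0.505
smallest correlation:     -0.585 at (q_i, q_j) = (0.225, 0.315)
neighbor-MI minimum:      qR_G = 3.39 (information-richest band)
bandwidth minimum:        qR_G = 3.39
clamped rho entries:      0
```

Reading the numbers: the profile SD vanishes at q = 0 because I(0)
counts electrons and cannot fluctuate; it peaks at intermediate q where
conformational diversity is imprinted.  Profile points close in q are
nearly perfectly correlated, distant regions decorrelate (the
hierarchical structure of SAS curves), and at least one negative basin
appears.  Both information diagnostics place the locally
information-richest band at qR_G ≈ 3.4, inside the qR_G ∼ 3–6 window
where SAS data are known to be most valuable for refinement.

The other examples cover the rigid Debye profile
(`rigid_profile.py`), two-state mixtures and high-angle dominance of
the ordered state (`two_state_mixture.py`), ensemble spread versus
experimental noise for an IDP-like toy (`ensemble_vs_experiment.py`),
and the Monte-Carlo validation of the closed forms
(`oracle_check.py`).

A thin CLI wraps the same library calls:

```sh
sascov profile  structure.pdb --qmax 0.5 --out run/
sascov thermal  structure.pdb --tau 0.5 --out run/
sascov ensemble models.pdb    --out run/
sascov info     run/correlation.txt --threshold 0.5 --out run/
sascov synth    --kind globule --n-atoms 100 --tau 0.5 --out run/
```

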