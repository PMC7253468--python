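# Methods

## Model

The package studies the generalized Lotka–Volterra system

dN_i/dt = N_i ( r_i + Σ_j a_ij N_j ),  i = 1…n,

with intraspecific regulation scaled to a_ii = −1 and growth rates fixed at
r_i = +1.  Fixing r while sweeping the mutualism proportion P isolates P as
the only moving cause of any change in stability; the positive growth rate
corresponds to facultative mutualists that persist without their partners.
The alternative normalization that pins all N_i* = 1 and frees the growth
rates is deliberately not implemented: it changes r every time P changes and
collapses the per-species recovery-time structure this package is built to
expose.

The interior equilibrium solves A N* = −r; it is *feasible* when every
N_i* > 0.  Local stability is governed by the community matrix (Jacobian)
S = DA, D = diag(N*), whose eigenvalues λ_i define the critical eigenvalue
Λ = max Re λ_i.  With r = e two identities are exact and are enforced at
1e−10 in the tests:

* S N* = DA N* = −De = −N*, so −1 is an eigenvalue with eigenvector N*;
* Σ λ_i = trace(S) = −Σ N_i*, hence ⟨λ_i⟩ = ⟨−N_i*⟩.

For feasible purely mutualistic communities S + αI is a non-negative matrix
for α ≥ max N_i*, and N* > 0 is its Perron eigenvector, so Λ = −1 exactly.
For weak interactions the bulk eigenvalues track −N_i*, giving the working
approximation Λ ≈ max(−N*_min, −1).

## Random community generation

`generate_chen_cohen` draws one community per seeded RNG:

1. each unordered pair {i, j} is retained with probability C (connectance),
   both entries zeroed otherwise — pair-level dilution preserves the (+/+)
   semantics of a mutualistic pair;
2. retained pairs are labelled mutualistic with probability P, otherwise
   they take the background type (exploitative by default; competitive and
   random selectable);
3. each nonzero magnitude is an independent half-normal draw σ·|N(0,1)|
   (mean σ·√(2/π) ≈ 0.798 σ); only *signs* are coupled by the pair type.
   Exploitative pairs orient their +/− uniformly at random.

Choices made where the design was genuinely open: magnitudes of a_ij and
a_ji are independent (the scheme specifies pair type, not magnitude
symmetry — also the convention in the random-matrix ecology literature);
σ is interpreted as the half-normal *scale*, which makes it exactly the
standard deviation of a signed exploitative entry; with the "random"
background each entry gets an independent uniform sign and the pair is
labelled by its realised pattern, so the label fraction equals P exactly
only for the exploitative/competitive backgrounds.

`generate_uniform` builds the deterministic skeleton (all selected pairs at
strength m; closed-form equilibrium N* = 1/[1 − (n−1) m C P], blow-up bound
m < 1/(n−1)), and `generate_gaussian` draws Normal(m, σ) entries, optionally
truncated positive by redraw — the generator used for the pulse-comparison
ensembles.

## Parameters that matter

| parameter | meaning | default | why |
| --- | --- | --- | --- |
| n | species count | 100 | study scale for sweeps/clouds |
| σ | half-normal interaction scale (dimensionless) | 0.02 | weak-interaction regime where feasibility dominates |
| C | connectance | 0.7 | standard sweep configuration |
| P | proportion of mutualistic pairs | swept 0–0.9 (step 0.02) | the treatment variable |
| r_i | growth rates | +1 | scaling argument above |
| pulse depth | density units removed | 0.4 | standard pulse experiment |
| ε | return-time band (absolute density) | 0.01 | resolves recovery without touching integrator noise |

The mean-field comparison uses the effective strength m = σ√(2/π), the mean
of a mutualistic entry under the generator; exploitative background entries
have mean zero and do not enter the mean-field denominator.

## Numerical choices

* Linear solves use LAPACK via `numpy.linalg.solve`; condition numbers above
  1e12 warn, above 1e15 raise the blow-up/singular error.
* Integration: adaptive explicit RK45, rtol 1e−8 / atol 1e−10 (the systems
  are non-stiff at these interaction scales); a density cap of 1e6
  terminates divergent runs deterministically, naming the first diverging
  species.
* Outlier identification uses eigenvector alignment (maximal cosine
  similarity with N*), not nearest-to-−1, so it stays correct when the bulk
  overlaps −1 at small P.
* Two-phase recovery fits: best two-segment least-squares fit of
  log ‖N(t) − N*‖, accepted when it beats a single line's residual by ≥20%
  with a steeper first slope; samples below a floor of 1e−6·(1+‖N*‖) are
  discarded because the integrator's absolute error scales with density
  magnitude and flattens the tail below that level.
* Crossing location on sweep curves applies isotonic (pool-adjacent-
  violators) smoothing before linear interpolation: the underlying curve is
  theoretically monotone in P, and a raw first-crossing rule on noisy means
  is biased toward smaller P.
* Sweep averages condition on feasibility, matching the analysis of feasible
  systems; infeasible draws are counted and logged per replicate (child
  seed, flag, Λ, N*min), never silently redrawn.

## Study conditions and problem sizes

The sweep experiments use n = 100, σ = 0.02, C = 0.7, exploitative
background, 50 feasible replicates per P — the standard configuration for
this model family.  The acceptance script pools 16 independent replications
of that 50-replicate sweep (grid 0.20–0.60, step 0.02) before locating the
N*min crossing; pooling reduces the Monte-Carlo standard error of the
crossing to ~0.002 so the reported value reflects the model, not sampling
noise.  Under these conditions the measured crossing is ≈ 0.375.

The purely mutualistic Perron–Frobenius check runs at n = 100, σ = 0.02,
P = 1 with C = 0.4.  Connectance must come down for this ensemble: a
feasible purely mutualistic community requires the mean-field factor
(n−1)·σ√(2/π)·C·P < 1, and at C = 0.7 (let alone C = 1) that factor exceeds
1 at n = 100, so feasible draws do not exist; C = 0.4 puts the factor at
≈ 0.63, comfortably inside the bound, and feasibility is then the norm.

The pulse comparison uses n = 10, depth 0.4, five replicates per ensemble:
mutualistic (m = 0.1, σ = 0.05, truncated positive — mean equilibrium
density ≈ 1/[1 − 0.9] = 10) versus mean-zero (m = 0, σ = 0.05, densities
≈ 1).  Negative draws in the positive ensemble are redrawn (truncation at
zero) rather than rejecting whole matrices.

## What the generators emulate — and what they do not

The synthetic communities reproduce the statistical structure assumed by
random-matrix ecology: independent random pairwise interactions with
controlled type proportions, homogeneous connectance, identical
self-regulation and growth rates.  They do not emulate structured topologies
(nestedness, bipartite plant–pollinator networks, degree heterogeneity),
saturating functional responses, demographic noise, press perturbations or
extinction dynamics.  Passing tests therefore demonstrate the spectral and
resilience mechanisms of the idealised model, not quantitative predictions
for any empirical network.

## Known limitations

* Feasibility of strongly mutualistic systems occupies a narrow parameter
  sliver (the blow-up bound above); sweeps approach it near P ≈ 0.9 at the
  default configuration, where rejection rates rise and the mean-field
  denominator nears zero.
* Only the interior equilibrium is analysed; boundary equilibria with
  extinct species are out of scope.
* The elliptical bulk is characterised empirically (centre, exported
  clouds); no analytic elliptic-law boundary is computed.
* Return times are measured on the sampling grid of the trajectory;
  sub-grid precision requires a denser `t_eval`.
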