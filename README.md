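# randlv — random Lotka–Volterra communities

`randlv` simulates random multi-species communities under the generalized
Lotka–Volterra equations

```
dN_i/dt = N_i ( r_i + Σ_j a_ij N_j ),    i = 1, …, n
```

and asks how the *proportion of mutualistic interactions* shapes equilibrium
densities, stability and resilience.  It is aimed at theoretical ecologists
and anyone working with random-matrix models of interaction networks.

The key modelling choice is that stability is read off the **community
matrix** (Jacobian) **S = DA**, with **D** = diag(N\*) the equilibrium
densities — not off the interaction matrix **A** alone, as much of the
random-matrix literature does.  With the standard scaling a\_ii = −1 and
r\_i = +1, two exact identities follow for any feasible equilibrium
(A N\* = −e):

* **S N\* = −N\***, so −1 is always an eigenvalue of S with eigenvector N\*
  (the *outlier*); for purely mutualistic communities the Perron–Frobenius
  theorem pins the critical eigenvalue Λ = max Re λ\_i at exactly −1;
* **⟨λ\_i⟩ = ⟨−N\_i\*⟩**, so the *bulk* of the spectrum — the elliptical
  cloud of the other n−1 eigenvalues — is centred near −⟨N\*⟩.

Because mutualism builds up densities (mean-field:
N\* ≈ 1/[1 − (n−1)·m·C·P] with m the mean interaction strength, C the
connectance and P the mutualistic proportion), raising P pushes the bulk
left and makes Λ saturate at −1: mutualistic communities are *more*
resilient, recovering faster from pulse perturbations — both in the slow
outlier-driven phase (rate |Λ|) and especially in the fast bulk-driven
phase (rate ≈ ⟨N\*⟩).

## What's in the package

| module | contents |
| --- | --- |
| `randlv.matrix_gen` | Chen–Cohen random generator (retain pairs with prob. C, make them (+/+) with prob. P, half-normal magnitudes σ·\|N(0,1)\|), uniform/regular skeleton, Gaussian-mean generator |
| `randlv.equilibrium` | `solve_equilibrium` (A N\* = −r), feasibility, mean-field closed forms, blow-up bound 1/(n−1), May's ratio nσ²/(1+m)², Monte-Carlo feasibility probability |
| `randlv.spectra` | community matrix S = DA, spectra with bulk/outlier classification, Λ ≈ max(−N\*min, −1), λ\_i ≈ −(1+E(a\_ij))N\_i\*, trace-identity check |
| `randlv.dynamics` | adaptive RK integration, pulse perturbations, return times, two-phase recovery-rate fits |
| `randlv.experiments` | seeded pipelines: P sweep, eigenvalue clouds, paired pulse-recovery comparison |

A `randlv` CLI (`generate`, `equilibrium`, `spectrum`, `perturb`, `sweep`,
`cloud`, `pulse-compare`) wraps the library for shell use; matrices are
plain-text with JSON sidecars, tables are CSV.

## Worked example

```python
from randlv import (GenParams, generate_chen_cohen, solve_equilibrium,
                    community_matrix, spectrum, lambda_approx)

params = GenParams(n=100, P=0.5, C=0.7, sigma=0.02,
                   background="exploitative", seed=7)
im = generate_chen_cohen(params)
eq = solve_equilibrium(im)                      # A N* = -e
spec = spectrum(community_matrix(im, eq.Nstar), eq.Nstar)
print(f"feasible={eq.feasible}  Nmean={eq.Nmean:.3f}  Nmin={eq.Nmin:.3f}")
print(f"Lambda={spec.Lambda:.6f}  bulk_center={spec.bulk_center.real:.3f}")
print(f"lambda_approx={lambda_approx(eq.Nstar):.3f}")
```

prints

```
feasible=True  Nmean=2.140  Nmin=1.254
Lambda=-1.000000  bulk_center=-2.151
lambda_approx=-1.000
```

Half the pairs are mutualistic, densities have built up (⟨N\*⟩ ≈ 2.1), the
minimum density exceeds 1, so the critical eigenvalue has saturated at the
outlier value −1 — exactly what `lambda_approx` (= max(−N\*min, −1))
predicts — while the bulk is centred near −⟨N\*⟩ ≈ −2.15.

The paired pulse experiment (one species depressed by 0.4 density units,
n = 10, five replicates per ensemble):

```python
from randlv import pulse_recovery_comparison
res = pulse_recovery_comparison(seed=31)
print(res.mean_return_mutualistic, res.mean_return_neutral)
```

gives mean return times of **1.39** (purely mutualistic, m = 0.1, σ = 0.05)
versus **4.66** (mean-zero interactions, m = 0) — mutualists pull the
community back far faster.

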