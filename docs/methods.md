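# Methods

## Model

Two dimensionless rate equations describe the zeb1–cdh1 core of the EMT
circuit in a single breast-cancer cell:

```
dx1/dt = a1 h(x1) + b1 − k1 x1                 = F1(x1)
dx2/dt = a2 h(x2) + b2 θ^n/(θ^n + x1^n) − k2 x2 = F2(x1, x2)
h(x)   = x^n / (θ^n + x^n)
```

`x1` is ZEB1, `x2` E-cadherin.  Both genes self-activate through the same
Hill nonlinearity; ZEB1 additionally represses E-cadherin.  The additive
superposition of the self-activation and repression terms in F2 encodes
an "or" regulation logic (either input can sustain expression).  Standard
constants are `k1 = k2 = 1`, `θ = 0.5`, `n = 4`, `b1 = 0.2`, `b2 = 1`;
`a1` and `a2` are the biologically tunable inputs (`a1` is the proxy for
TGF-β signalling, `a2` for the methylation state of the *cdh1* promoter)
and must always be supplied explicitly.  The Hill coefficient is accepted
as any real `n > 0`, since the tristability boundary is scanned
continuously in `n`; powers are evaluated as real powers with the
`x = 0` limit handled explicitly.  All quantities are dimensionless; no
unit handling exists anywhere.

Key structural facts used throughout:

* **Skew product.** F1 does not depend on `x2`, so the Jacobian is lower
  triangular and its eigenvalues are the two diagonal partials.  Fixed
  points are found by dense bracketing + Brent on F1 over
  `[0, 1.02 (a1+b1)/k1]` (400 seeds by default), then the same on
  F2(x1⁰, ·) per root.  This is exhaustive for this model class (a Hill
  sigmoid plus a line has at most three crossings per axis) and far more
  robust than 2-D Newton from random seeds.  Duplicates are merged at
  1e-7 in max-norm; output is sorted by (x1, x2).
* **Invariant box.** Outside `[0, (a1+b1)/k1] × [0, (a2+b2)/k2]` the flow
  points inward, which bounds every search and simulation domain.
* **Phenotype labels.** A stable state is B (`x1 ≥ θ > x2`), S (both
  `≥ θ`), or L (`x1 < θ ≤ x2`); anything else is `other`.  θ is the
  model's only intrinsic concentration scale and the computed attractor
  coordinates separate cleanly around it.  Near-degenerate eigenvalues
  (|Re λ| < 1e-9) are classified `unstable` with a warning; the reference
  parameter sets never sit on a bifurcation point.

## Scans

`phase_diagram` re-solves the fixed points cell by cell for any pair of
kinetic parameters and stores the region code (sorted phenotype letters,
L < B < S, e.g. `LBS`).  `bifurcation_scan` does the same along one
parameter.  Scans are pointwise re-solves, not continuation; saddle-node
tangencies falling between bracketing seeds at the very edge of a region
can in principle be missed, which matters only within one grid cell of a
boundary.

`critical_hill` bisects the Hill coefficient `n` against a tristability
oracle: some cell of an 80×80 (a1, a2) grid over `[0.05, 2]²` must carry
three stable states labelled S, B and L.  The scan exploits the skew
product (a column is skipped unless F1 is bistable, a necessary
condition).  With the basal rate held at `b1 = 0.2` the x1 subsystem
keeps bistability only down to its cusp — setting `b_c(n) =
θ((n−1)/(n+1))^((n+1)/n)` equal to `b1` gives `n ≈ 3.02` — and full
S/B/L tristability additionally needs the high-x1 root large enough to
de-repress x2, so the measured transition under these conditions is
`n_c ≈ 3.4–3.5` (stable under refinement of the parameter grid to
320×320).  The default bracket must straddle the transition or a
`BracketError` explains how to widen it.

## Stochastic simulation

Euler–Maruyama with additive noise, `x ← x + F(x) dt + sqrt(2 D dt) η`,
default `dt = 1e-3` (1e-3…2e-3 is well inside the weak-convergence
plateau for these smooth drifts; halving `dt` moves occupancies by less
than their replicate error).  Concentrations are kept non-negative by
reflection at zero, matching the no-flux boundary of the grid solver;
an `unconstrained` toggle exists (`reflect=False`).  Replicates draw
from independently spawned numpy `SeedSequence` streams, so every result
is reproducible from `(seed, dt, sizes)` alone.

Basin occupancies assign each recorded sample to an attractor through a
precomputed deterministic-relaxation map: grid-cell centres are relaxed
under the noiseless flow (vectorised RK4, `dt = 0.05`, horizon 40) and
matched to the attractor they approach within 0.05 (max-norm).  This is
watershed-correct without ever constructing separatrices; unresolved
cells (near-separatrix starts) are reported as `other` and contribute
well under 1% at the resolutions used.  Standard errors come from
between-replicate scatter.

Monte-Carlo first-passage times start all samples at the source
attractor and stop on first entry into a max-norm disk of radius 0.05
around the target (2-D) or on first crossing of the target point (the
clamped 1-D dynamics, matching the exact double-integral definition).
Censored samples are counted at `t_max`, biasing the mean low; results
carry a warning when more than half are censored.

## Landscapes

The stationary Fokker–Planck solution is computed on a cell-centred grid
(default domain `[0, 2] × [0, 2.5]`, which pads the invariant box for
noise excursions; resolution ≥ 64 per axis) in conservative
finite-volume form: first-order upwind advective fluxes, centred
diffusion, zero total flux through the walls.  The generator's columns
sum to zero, so probability is conserved to rounding at every step.
Backward-Euler steps with `dt = 5` (one sparse LU, reused) damp the fast
modes; iteration stops when `‖dP/dt‖∞ < 1e-9`.  `U = −ln P` is masked
where `P < 1e-12 · max P` to avoid meaningless logs in the deep tails.

Two systematic effects are worth knowing.  First, upwinding adds
numerical diffusion of order `|F| h / 2`; at 64 cells per axis this is a
noticeable fraction of `D = 0.02` and the main term in the
total-variation gap between solver and histogram (≈ 0.044 at 64², ≈ 0.030
at 128²).  Second, the maxima of `P_st` at finite `D` do not sit exactly
on the attractors: the density skews towards the shallow side of each
well.  The offset is physical, not numerical (stable under 128→256
refinement) and shrinks as `D → 0` (≈ 0.06 at `D = 0.02`, ≈ 0.03 at
`D = 0.005`); tests therefore match modes to attractors within 0.1 at
`D = 0.02` rather than to grid precision.

The histogram estimator bins post-burn-in ensemble samples on the same
grid; basin probabilities integrate `P_st` over the relaxation basins.

## One-dimensional reduction and first-passage theory

B and S share the high stable root `x0` of F1, so their interconversion
is treated as a 1-D diffusion in `x2` with `x1` clamped at `x0`, in the
potential `U(x0, x2) = −∫ F2(x0, ·)`.  For `n = 4` the antiderivative is
closed-form (arctangent + logarithm + quadratic − linear); for other `n`
it is built by adaptive quadrature of `−F2`.  The antiderivative
identity `U′ = −F2` is verified to 1e-8 at 1000 points — the strongest
guard against transcription errors in the arctan/log pair.  Stationary
points come from bracketed root-finding on F2, curvatures analytically
(`U″ = k2 − a2 h′`).

Three MFPT estimates:

* **Exact integral** `τ = ∫_{y1}^{y2} dy/(D P_st(y)) ∫_0^y P_st(k) dk`
  with `P_st ∝ exp(−U/D)`, nested adaptive quadrature.  The lower limit
  is the reflecting origin (concentrations are non-negative and the
  density below 0 is negligible); passages towards smaller `x2` use the
  mirrored form with an upper cutoff placed 40·D above the well bottom.
  Exponentials are shifted by a common reference so neither factor
  overflows at small `D`.
* **Kramers / steepest descent**
  `τ = 2π |U″(min) U″(saddle)|^(−1/2) exp(ΔU/D)` with the deterministic
  potential in the exponent — the only reading under which the
  steepest-descent limit of the exact integral reproduces the formula,
  since `P_st ∝ exp(−U/D)` (the effective potential `−ln P_st` equals
  `U/D` up to a constant, so quoting it inside an exponent already
  divided by `D` would double-count the noise).
* **Monte-Carlo** on the clamped Langevin dynamics.

Barrier heights `ΔU_{u1B} = U(u1) − U(B)` and `ΔU_{u1S} = U(u1) − U(S)`
are exposed for both the deterministic potential (D-independent;
0.0343 and 0.0112 at the reference point) and for sampled `−ln P_st`
sections, whose barriers scale as `ΔU/D`.  The crossing `D_c` of
`τ_BS(D)` and `τ_SB(D)` is found by bracketed bisection; for the Kramers
method it must and does agree (to 1e-6) with the closed form
`D_c = (ΔU_B − ΔU_S)/(½ ln(U″_B/U″_S))`, giving `D_c ≈ 0.083` at the
reference point.

## Known limitations

* The 1-D reduction is exact only with `x1` frozen.  In the full 2-D
  dynamics, `x1` fluctuations around the shared root modulate the
  repression term asymmetrically — dips in `x1` de-repress `x2` and
  accelerate B→S while hindering S→B — and at `D = 0.02` this is strong
  enough to *reverse* the τ ordering relative to the 1-D theory
  (2-D Monte-Carlo gives `τ_BS ≈ 20 < τ_SB ≈ 28`, while the clamped
  dynamics reproduces the theory, `τ_BS ≈ 35 > τ_SB ≈ 19`).  The
  directionality statements tied to `D_c` are therefore statements about
  the reduced model; 2-D passage-time tests assert only the robust
  decreasing-τ-with-D trend.
* Transitions involving the luminal state have no analytic treatment
  (L sits on a different x1 branch); they are covered by 2-D Monte-Carlo
  only.
* Scans are pointwise; no continuation, no codimension-2 classification
  (cusps are visible in the phase map but not labelled).
* No curl-flux decomposition or path-integral transition paths: only
  `P_st` and `−ln P_st` are computed.
* Test and default problem sizes (ensemble lengths, grid resolutions)
  are chosen so replicate standard errors resolve the trends being
  asserted at desk scale; estimates tighten in the obvious way with
  longer runs.
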