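# Methods

## Model

Two particle densities on the line: active particles `A` diffuse (unit
coefficient), branch at rate 1, and become irreversibly inactive on
collision with any particle; inactive particles `I` are produced by
collisions and directly at rate `r ≥ 0`, and never move or decay:

    A_t = A_xx + A − A(A + I),
    I_t = A(A + I) + r A.

All quantities are dimensionless (the general rate/diffusion constants are
removed by a linear rescaling; only the normalized system is implemented).
`I_t ≥ 0` pointwise, so the inactive field only accumulates, and every
state `(0, K)` is steady: the model has a continuum of equilibria, which is
what makes the wave analysis nonstandard — the limits of a front are not
known a priori but selected by the dynamics.

In the frame `z = x − ct` a wave solves the first-order system

    a' = b,   b' = a(a+i) − a − cb,   i' = −(1/c) a (a+i+r),

whose fixed points `(0, 0, K)` carry one zero eigenvalue (the direction
along the continuum; the center manifold coincides with the fixed-point set,
so no flow occurs along it) and the pair `λ± = −c/2 ± sqrt(c²/4 + K − 1)`.

## Closed forms implemented

- critical density `i_c = max{0, 1 − c²/4}`; admissible right limits are
  `i(+∞) ∈ [i_c, 1)`, admissible left limits `i(−∞) ∈ (1, 2 − i_c]`.
- tail rates `μ±∞ = −c/2 + sqrt(c²/4 + i±∞ − 1)`, with a sub-exponential
  flag when the discriminant vanishes (decay of order `z e^{−cz/2}`) and a
  spiraling flag when it is negative.
- unstable eigenvector at `(0,0,i(−∞))`, stored in the component form
  `(−λ₋, i(−∞) − 1, (r + i(−∞)) λ₋ / (c λ₊))` whose sign pattern
  (+, +, −) drives the shooting initialization; a unit-normalized accessor
  is provided separately.
- the limit map `i_{+∞}(a0, i0)`, its inverse threshold `α(i0)` (the start
  that drains the system exactly to `i_c`), the attractor bound
  `a*(i0) = min{α(i0), 1 − i0}`, and the turning-point closed form relating
  `(a, i)` at the first `b = 0` crossing to the left limit.

One algebraic correction was required: the mass-transfer identity between
two points with `b = 0` reads

    i(z1) − i(z2) = (1+r)/c · ∫ a dz + a(z2) − a(z1),

including the last term, which vanishes in full-line applications (where it
yields the limit symmetry `i(−∞) + i(+∞) = 2`) but not on partial spans
such as tail-to-turning-point.  The package implements and tests the general
form; the companion identities (the collision-integral identity and the
quadratic identity) hold as usually printed.

## Wave construction by shooting

The unstable manifold of `(0, 0, i(−∞))` is one-dimensional, so the wave is
realized by offsetting the fixed point a distance `ε = 1e−7` along the unit
unstable eigenvector (linearization error `O(ε²)`) and integrating with
DOP853 at `rtol = 1e−10, atol = 1e−12`.  Events: the first *downward* zero
of `b` is root-polished into the turning point (upward first crossings would
indicate a numerical artifact); integration terminates when
`max(|a|, |b|) < 1e−10` (convergence) or at a state-norm cap of `1e3`
(divergence).  The phase-time horizon is scaled automatically from the
analytic rates — escape at `λ₊(i(−∞))`, decay at `|μ₊∞|` — so waves with
limits near the continuum edge `i = 1` (both rates `→ 0`) still converge.
For the critical wave the convergence threshold is relaxed to `1e−8` and
the horizon enlarged, because the tail closes only like `z e^{−cz/2}`.

The raw final `i` underestimates the limit by the truncated tail mass; one
application of the limit map at the final small-amplitude state (valid since
`|b|` is below threshold there) removes this bias, leaving the measured
limits accurate to ~1e−11.  Negative excursions of `a` beyond `10·atol`
clear the nonnegativity flag; this separates genuine spiraling (the
mechanism that excludes right limits below `i_c`) from roundoff.

Tail rates are measured by linear fits of `log a` over the trailing/leading
15% of samples.  In the critical case the fit is `log(a / (z − z0 + 1))`
with `z0` the turning point: the linear prefactor grows from the wave
center, and referencing the integration origin instead biases the fitted
rate by several percent.

## Trapping triangle

For frozen `i ∈ [i_c, 1)` the planar `(a, b)` flow has fixed points `(0,0)`
and `(1−i, 0)`; the triangle between them, closed by the apex where the
half-line below the stable eigenvector at the origin meets the half-line
below the unstable eigenvector at `(1−i, 0)`, is forward invariant.
Invariance is certified by sampling each edge uniformly and checking the
inner product of the flow with the inward normal (counterclockwise vertex
ordering fixes all normal signs); an `ε = 1e−6` edge-fraction neighborhood
of the two fixed-point vertices is excluded, where the flux legitimately
vanishes.  At `i = i_c` with positive `i_c` (and at `c = 2, i = 0`) the two
eigenvalues collide; the triangle is then flagged degenerate and the scan
reports that status instead of pass/fail — the degenerate case is settled
by continuity in the analysis, not by the scan.

## PDE simulation

Method of lines: second-order central differences for `A_xx` with no-flux
(reflecting) boundaries (ghost node mirrored), no spatial operator on `I`.
Time stepping is classical RK4 at the fixed diffusive cap `dt = 0.4 dx²`;
steps are rounded so output times are hit exactly.  Steady states `(0, K)`
are preserved to machine precision per step; negative values are never
clipped — an instability must surface as a failure (`max |A| > 10` aborts),
not be masked.

The reference run is `A(x,0) = exp(−x²)/2, I = 0` on `[0, 400]` with
`dx = 0.1` to `t = 150` (the even initial data lets the reflecting boundary
at `x = 0` stand in for the left half-line).  Front position is the
rightmost linear-interpolated crossing of `A` through 0.01.  Pulled fronts
approach their speed like `c − k/t`, so the speed is the `t`-coefficient of
a least-squares fit `x_f(t) = x0 + c t − k ln t` over the last half of the
outputs; the raw slope over the same window underestimates `c` by ~0.6%.
The plateau is the mean of the final `I` over `[x_f − 60, x_f − 30]`
restricted to nodes with `A < 1e−6`; the 30-unit margin is the width of the
active pulse, and `A` falls below `1e−6` only ~43 units behind the front,
so smaller margins leave no active-free window.  The scaled-down runs used
in the unit tests (domains 20–120, times 5–50) exercise identical code; the
full-size run lives in the acceptance script and the acceptance test.

## Weighted spectral probe (exploratory)

Linearizing the comoving PDE about a wave profile gives
`L = D ∂zz + c ∂z + JR(w)` with `D = diag(1, 0)` and
`JR(w) = [[1−2a−i, −a], [2a+i+r, a]]`.  Since inactive particles neither
diffuse nor react back, perturbations are convected toward `z = −∞`;
stability is therefore probed in `H¹_α` with weight `e^{αz}`.  The weight is
applied by operator similarity (`∂z → ∂z − α`), avoiding explicit
exponentials over long domains.  Discretization: central stencils in the
active row, *forward* one-sided differences for the `c ∂z` transport in the
inactive row — the transport convects leftward, so the donor side is `+z`;
a backward stencil would be anti-dissipative and seed spurious modes with
real parts up to `+2c/h`.  Homogeneous Dirichlet closure at the truncation
ends; an `α` pushing the transformed convection past the central-stencil
cell-Péclet bound is rejected.

Two structural facts shape what can honestly be measured:

- With Dirichlet truncation the discrete spectrum accumulates on the
  *absolute* spectrum of the far-field coefficients, not on the essential
  spectrum curves; a periodic assembly variant is provided for
  constant-profile dispersion checks against the Fourier symbol.
- The weighted operator of a pulled wave has **no isolated point
  spectrum**: the translation eigenvalue 0 sits at (or embedded in) the
  essential-spectrum edge for every admissible weight — the same
  obstruction that blocks the classical nonlinear-stability machinery.
  Consequently individual gap eigenvalues are domain modes that shift with
  the truncation length (while being grid-converged below `1e−3` at fixed
  length), and the truncation-robust quantity is the stability verdict
  itself.  The translation eigenvalue is estimated two ways: the eigenvalue
  of the discrete mode with maximal overlap against the weighted profile
  derivative (clean at `α = c/2`, where the active row is symmetrized), and
  the Rayleigh quotient of that derivative (the robust estimate at `α = 0`,
  where the zero is embedded and overlap cannot separate it from essential
  modes).  For the critical wave at `α = c/2 = 1` the measured margin,
  translation excluded, is ≈ `−0.013` on the default grid; the pass
  threshold 0.05 is a discretization allowance, not a sharp bound.

## Synthetic scenarios

The generators produce exactly the families the analysis assumes: Gaussian
heaps (amplitude 1/2, unit width, zero inactive background — optionally
mirrored for two outgoing fronts), attractor starts `(f·a*(i0), 0, i0)`
with `f > 1` flagged for must-fail exploration, perturbed-wave fields
(profile resampled by monotone cubic interpolation with analytic-rate tail
extension beyond the computed span, plus a seeded, compactly supported,
exponentially enveloped random bump sum scaled to a requested sup-norm),
and admissibility-filtered parameter sweeps.  Every generator is a pure
function of its arguments and seed (default 0); payloads round-trip through
CSV/JSON exactly (`%.17g` on write, round-trip float parsing on read).

What the scenarios do *not* emulate: the underlying stochastic branching
network (tip-level noise, annihilation geometry, 2-D/3-D structure), finite
particle numbers, or measurement noise.  Passing tests therefore validate
the continuum model's wave analysis, not the fidelity of the continuum
limit to discrete tissue growth.

## Problem sizes and limitations

Defaults: shooting samples 4000 points (8000 critical) over an
automatically scaled span; the reference PDE grid is 4001 nodes × 37,500
RK4 steps (~7 s); spectral matrices are dense `2n × 2n` with `n = 800`
default (property tests use 400–800).  Known limitations: shooting
accuracy degrades as `i(−∞) → 1⁺` where both rates vanish (spans grow like
their inverse); the explicit PDE scheme is diffusion-limited, so halving
`dx` costs 8×; the spectral probe is a discretized surrogate — it samples
absolute/essential spectra and cannot resolve embedded eigenvalues beyond
the Rayleigh estimate; and no claim is made about nonlinear or convective
stability, only about the location of the discretized spectrum.
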