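# Methods

## The functional

For an absolutely continuous distribution with density f and CDF F, the
derangetropy density is

    ρ[f](x) = (24/πe) · sin(πF(x)) · F(x)^F(x) · (1−F(x))^(1−F(x)) · f(x).

Three algebraically equivalent evaluations are implemented and kept as
separate code paths, because their mutual agreement is one of the strongest
internal consistency checks available:

1. the defining product form above;
2. the Bernoulli-entropy form `(24/πe)·sin(πF)·exp(−H_B(F))·f`, where
   `H_B(p) = −p log p − (1−p) log(1−p)` is the entropy (in nats) of a
   Bernoulli trial with success probability p = F(x);
3. the Gamma form `(24/e)·[Γ(F)Γ(1−F)]⁻¹·F^F(1−F)^(1−F)·f`, obtained from
   Euler's reflection formula `sin(πz) = π/(Γ(z)Γ(1−z))`.

Substituting z = F(x) shows that ρ integrates to
`(24/πe)·∫₀¹ sin(πz) z^z (1−z)^(1−z) dz`, and that integral equals πe/24,
so ρ is itself a probability density regardless of the base distribution.
The package treats this as a verifiable identity (adaptive quadrature
reproduces it to ~1e−16), not an assumption.

Conventions: natural logarithms throughout (the constant C = log(24/πe) is
unit-consistent only in nats); `0⁰ = 1` and `H_B(0) = H_B(1) = 0`, so the
evaluated formula returns exactly 0 wherever F ∈ {0, 1}. Inside logs and
powers F is clipped to `[1e−300, 1−1e−16]` purely as a floating-point
guard; exact zeros are enforced afterwards.

### Boundary behavior

For bases with bounded density, ρ → 0 at the edges of the support (the sine
factor vanishes). The arcsin law is the instructive exception: its density
diverges at the edges at exactly the rate sin(πF) vanishes, leaving the
finite boundary limit `48/(π²e) ≈ 1.789`. Evaluating the formula *at* the
edge still returns 0 (F is exactly 0 or 1 there); the limit is approached
along interior points. This matters for grid quadrature (below).

## Distribution layer

The five analytic families wrap frozen `scipy.stats` distributions
(uniform, norm, expon, semicircular, arcsine), with closed-form density
derivatives attached per family for the derangetropy derivative. The
semicircle family is parameterized by its support interval (a, b) with
radius (b − a)/2; the arcsin family uses the standard arcsin-law CDF
`(2/π)·arcsin(√u)` on (a, b) — the parameterization under which the
double-angle identity `sin(πG_arcsin(x)) = 2√(x(1−x))` holds exactly.
Medians are located by bisection on the CDF to 1e−12 in F (closed-form
checks: (a+b)/2, μ, ln 2/λ, center, midpoint).

The empirical estimate is a Gaussian-kernel KDE with bandwidth h from the
robust Silverman rule `0.9·min(sd, IQR/1.34)·n^(−1/5)` (user-overridable).
Rather than pairing the KDE with a step ECDF, the CDF is the *exact
integral of the same density*: the Gaussian-mixture CDF, truncated to the
extended support `(min − 3h, max + 3h)` and renormalized. This keeps
(f, F) mutually consistent — the property the unit-mass theorem needs — and
makes the CDF hit exactly 0 and 1 at the support edges. The ~0.27% of
kernel mass outside ±3h is folded back by the renormalization.

Evaluation grids: bounded supports get equally spaced *interior* points
(energies diverge at F ∈ {0,1}); unbounded or half-bounded supports are
truncated to the quantile interval `[F⁻¹(1e−6), F⁻¹(1−1e−6)]`.

## Energies and equilibria

Taking logs splits ρ into modulation energy `−log sin(πF)` and structural
energy `H_B(F) − log f`, with `E_total = −log ρ + C`. For the uniform(0,1)
base both derivatives have closed forms:

    dE/dx   = −π·cot(πx) + 2·atanh(1−2x)
    d²E/dx² = π²·csc²(πx) − 1/(x(1−x))

The second line deserves a note: `d/dx [2·atanh(1−2x)] = −1/(x(1−x))`
(binary entropy is concave), so the `1/(x(1−x))` term enters with a *minus*
sign, and the curvature at the equilibrium x = 1/2 is `π² − 4 ≈ 5.8696`.
A plus sign (giving π² + 4) sometimes appears in the literature but is
inconsistent with the first derivative one line above; the finite-difference
curvature of the actual energy confirms π² − 4. The qualitative picture is
unaffected: `sin²(πx) ≤ π²x(1−x)` makes the expression strictly positive on
(0,1), so the equilibrium is a minimum, and it diverges like 1/x² toward
the boundaries.

`find_equilibria` scans the sign of dE/dx on a 2048-point interior grid and
refines each bracket by bisection (width tolerance 1e−12); uniform(0,1)
uses the closed forms, other bases central differences of `−log ρ + C` with
step equal to the grid spacing. `atanh` is evaluated as
`½·log((1+z)/(1−z))`.

## The governing ODE

For the uniform base (x ≡ F), ρ satisfies

    ρ″ + 4·atanh(1−2F)·ρ′ + [π² − 1/(F(1−F)) + 4·atanh²(1−2F)]·ρ = 0,
    ρ(0) = 0,  ρ′(0) = 24/e.

The module verifies rather than integrates (the closed-form solution is
known). With analytic derivatives — `ρ = A·sin(πF)·μ`,
`μ = exp(L)`, `L = F log F + (1−F)log(1−F)`, `L′ = −2·atanh(1−2F)`,
`L″ = 1/(F(1−F))` — the residual cancels algebraically and evaluates to
rounding error (~1e−13). The integrating factor is used as the positive
magnitude `μ = F^F(1−F)^(1−F)` (the textbook calculation produces −μ, but
an integrating factor is defined up to a nonzero constant, and the positive
sign is the one that reproduces ρ with C₁ > 0). Dividing it out reduces the
ODE to `ν″ + π²ν = 0`; (C₁, C₂) are recovered by least squares of ν = ρ/μ
against {sin(πF), cos(πF)}, and the initial slope by quadratic
extrapolation of ρ(F)/F through the three smallest grid points.

Grid-size note: the level-1 curve is renormalized to unit trapezoid mass on
an interior grid, which biases every value up by the missing boundary-cell
mass ≈ (24/e)h². The coefficient recovery inherits that bias directly, so
the ODE verification defaults to an 8192-point grid, where it is ~4e−7 —
an order below the 1e−6 agreement the check asserts. Residuals from
*sampled* curves use central first differences and a direct 3-point second
difference (composing two gradient passes would widen the stencil to 2h and
quadruple the truncation error); on a 4096 grid the max residual over
F ∈ [0.01, 0.99] is ~8e−4, dominated by the log-singular higher derivatives
near the window edges.

## Recursion

`ρ⁽ⁿ⁾` is built from `ρ⁽ⁿ⁻¹⁾` and its running CDF `G⁽ⁿ⁻¹⁾` on a fixed grid
(default 4096 points — finer than the single-level default because repeated
application sharpens the mode). G is computed by cumulative trapezoid,
clamped monotone into [0,1] before entering the sine and power terms, and
every level — including level 1 — is renormalized to unit trapezoid mass.
Renormalization is what keeps quadrature drift from compounding; it is
*required* at level 1 for the arcsin base, whose finite nonzero boundary
limit lives partly in the truncated edge cells (raw grid mass 0.99916 at
4096 points). Convergence diagnostics report per-level mean, variance and
the mass within ±0.05 of the *base* median; for multimodal or asymmetric
bases the choice of the base median (rather than a level-dependent
quantile) is a convention.

Numerical stability: `arcsin(√x)` loses ~half its digits as x → 1, so the
arcsin sine identity is evaluated through the reflection
`arcsin(√x) = π/2 − arcsin(√(1−x))` on the upper half-interval, keeping the
identity check accurate to rounding error (the 1e−12 assertion would be
unattainable near x = 1 with the naive evaluation).

## Signal pipeline

The empirical pipeline operationalizes "per-channel amplitude analysis":
each channel's *marginal amplitude distribution* is estimated by the KDE
construction above, and the level-1 derangetropy curve is computed on a
512-point grid by default. Summary features per channel: peak location and
height, the standard deviation of ρ across the grid (the documented
"variability" summary), and the mean level. Channels are independent; a
zero-variance channel is skipped with a reason, not fatal.

The synthetic generator emulates multichannel oscillatory recordings: per
channel, a sum of unit-amplitude sinusoids at the requested frequencies
with independent uniform random phases, plus noise of chosen standard
deviation. Nonzero skew replaces Gaussian noise with a standardized
lognormal transform (mirrored for negative skew), preserving mean 0 and the
requested variance while skewing the amplitude distribution. Everything is
driven by one `numpy` Generator seed, making the pipeline bit-deterministic.

What the generator does *not* emulate: real electrode recordings have 1/f
spectra, cross-channel correlation (volume conduction, common reference),
nonstationarity and artifacts. Passing tests therefore demonstrate the
pipeline's *contract* — valid per-channel PDFs, median-centered peaks for
symmetric channels, determinism — not any clinical claim. Default test
problem sizes (2000-sample channels, 256–512-point grids, recursion to
level 6 at 4096 points) were chosen as the smallest sizes at which the
quadrature tolerances above hold with comfortable margin.

## Known limitations

- The quantile function of the empirical estimate is a bisection on the
  integrated KDE (100 iterations); fine for grid construction, slow for
  bulk quantile queries.
- `find_equilibria` reports equilibria for skewed bases (e.g. exponential)
  from the numerical energy landscape; no closed-form cross-check exists
  for those, and the results are reported without an accuracy guarantee.
- The resemblance between the level-3 arcsin curve and the level-1 uniform
  curve is real but has no canonical metric; the package reports a maximum
  pointwise discrepancy and deliberately asserts no fixed bound.
- No symbolic algebra or arbitrary-precision arithmetic; tolerances are
  those stated above and in the test suite.
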