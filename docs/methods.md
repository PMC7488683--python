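# Methods

## Models and conventions

Two model families share one data model (`model_core`):

* the smooth ring, `dx_i/dt = α_i/(1 + x_{i-1}^{h_{i-1}}(t−τ_i)) − β_i x_i`
  with cyclic indexing (gene 1 is repressed by gene n), and
* its infinite-cooperativity limit, where the production term is
  `β_i α_i` while the delayed regulator is at or below the threshold and 0
  above it.

All quantities are dimensionless; time is normalised so degradation rates
are O(1), and every closed-form result additionally assumes `β = 1`
(functions that rely on a closed form reject other values rather than
rescaling silently).  The switching threshold is fixed at 1: rescaling the
state absorbs any other choice.  The value of the step response exactly at
the threshold is taken on the "on" branch; trajectories sit on the
threshold only at isolated instants, so the convention never affects an
integral, only event bookkeeping.

The scalar autorepressor (`n = 1`) anchors everything: equilibrium `x₀`
solves `x(1+x^h) = α` (unique, because the left side is strictly
increasing); the feedback gain is `w = h·x₀^h/(1+x₀^h)`; for `w > 1` and
`u = √(w²−1)` the equilibrium destabilises at `τ* = (π − arctan u)/u` with
an emergent cycle of period `2π/u`.  Since `w < h` always, cooperativity
`h ≤ 1` can never oscillate regardless of promoter strength or delay.

## Delay-equation integrator

The paper-scale simulations use the method of steps with a semi-implicit
variable-step scheme (`dde_engine`):

* The linear degradation `−β_i x_i` — the stiff direction — is integrated
  exactly (exponential integrator), so pure decay and equilibria are
  reproduced to rounding.
* The delayed production `g_i(t)` is sampled at the step start, midpoint
  and end (delayed lookups interpolate the stored solution with cubic
  Hermite polynomials; history before t = 0 comes from the user-supplied
  segment).  The step update convolves the quadratic interpolant of `g`
  with the decay kernel in closed form; the embedded comparison against
  the linear-interpolant update gives the local error estimate.  Steps are
  controlled to `atol + rtol·|x|` with a standard multiplicative law and a
  step ceiling (default 0.1) that keeps delayed-lookup interpolation error
  subordinate to the tolerance.
* All scheme weights are non-negative for the step sizes used and the
  production terms are non-negative, so states stay non-negative by
  construction — no clipping.
* When a lookup falls inside the open step (delays shorter than the step,
  including zero), stage values blend the current state with an
  exponential-Euler predictor.  When *all* delays are zero the problem is
  a plain ODE and is delegated to `scipy.integrate.solve_ivp` (RK45, dense
  output), which is both faster and battle-tested for that case.

Defaults: `rel_tol 1e-6`, `abs_tol 1e-9`, `max_step 0.1`.  Period
estimation discards a transient (caller-specified; half the span by
default), takes upward crossings of the post-transient mid-level by local
Hermite interpolation, and averages the last ≤ 12 intervals; convergence
requires ≥ 8 intervals with relative spread below 1e-3.  A signal whose
swing shrinks below 20% of its early value, or below absolute tolerance,
is classified "no-oscillation" — this separates a slow spiral into the
equilibrium from a sustained cycle near the threshold, where both cross
the mid-level for a long time.

An independent cross-check (tests only) integrates the same equations with
scipy's Radau solver segment by segment at 10× tighter tolerance; periods
agree to ~1e-5 relative.

## Exact event-driven step-limit solver

Between switching events every component follows
`x(t) = target + (x₀ − target)·e^{−β(t−t₀)}` with `target ∈ {α_i, 0}`, so
the next threshold crossing of each component is a logarithm away.  The
solver (`piecewise`) keeps a priority queue of (a) exact crossing events,
which commit a production toggle of the repressed gene `τ` later, and
(b) the toggles themselves; segments are versioned so a toggle invalidates
the stale crossing scheduled from the old segment.  There is no
discretisation error anywhere: event times from simulation match the
closed-form period to ~1e-13 over hundreds of cycles.  A cap of 10⁶ events
guards against pathological inputs, and a component resting exactly on the
threshold with zero derivative is flagged degenerate.

For the symmetric cycle with effective delay `τ`, the closed forms are
`x_min = e^{−τ}`, up-crossing `t₁ = ln[(α−e^{−τ})/(α−1)]`, maximum at
`t₂ = t₁ + τ`, `x_max = (αe^τ−α+1)/e^τ`, down-crossing `t₃ = T − τ`, and
`T(τ) = ln[(αe^τ−α+1)(αe^τ−1)/(α−1)]`, inverted exactly by
`τ(T) = ln[(α + √(α²+4(e^T−1)(α−1)))/(2α)]`.  The printed solution pieces
in the source formulation carry a sign typo in the exponent (they grow for
`t > t_i`); we use the standard decaying convention, which is the one that
actually reproduces the schedule above.

**Cycle families.**  Because a delayed regulator cannot distinguish a lag
of `τ_eff` from `τ_eff + kT` on a `T`-periodic orbit, the scalar equation
at delay `τ` supports a cycle for every `k ≥ 0` with
`τ_k = τ − k·T_k > 0`, `T_k = T(τ_k)`; in the step limit `T(τ) → 0` as
`τ → 0+`, so a root exists for *every* k and the countable family is
infinite — enumeration takes a `k_max` cap (default 10).  The n-gene
symmetric families solve `T = T(τ + (p/n − k)T)` for each phase-shift
numerator `p = 1..n−1`; for `k = 0` a root requires `p/n < 1/2` (the
period function satisfies `T > 2τ_eff` identically).  Each root is then
**validated** by seeding the exact simulator on the implied orbit
(phase-shifted closed-form profile, production flags and pre-committed
toggles reconstructed analytically) and requiring the switching pattern to
persist for 5 periods with crossing intervals within 1e-6 of `T`.
Validation is what enforces the known multiplicity conditions without
re-deriving them: for the delay-free 5-ring, the `p = 1` root exists
exactly when `α²/(α−1) > 5`, i.e. `2α > 5 + √5`, while `p = 2` always
roots — so strong promoters give (at least) two coexisting cycles and weak
ones exactly one; for the 3-ring only `p = 1` is admissible, giving the
unique stable cycle.

## Symmetric-cycle atlas for finite h

A symmetric cycle of the n-ring with phase lag `pT/n` projects onto a
periodic solution of the scalar equation with effective delay
`τ_eff = τ + (p/n)T`.  The scalar period curve `T(τ)` is therefore the
single numeric primitive (`atlas`): it is measured once on a log-spaced
grid from `1.02τ*` to `τ_max` (160 points by default; 150 points to
`τ_max = 34` for the reference census), with the analytic Hopf anchor
`(τ*, 2π/u)` prepended and shape-preserving (PCHIP) interpolation between
nodes.  The measured curve is monotone increasing and satisfies `T > 2τ`
throughout.

Enumeration solves `τ_eff = τ + (p/n)·T(τ_eff)`; at `τ = 0` this is the
intersection of the line `n/p` with `y(τ) = T(τ)/τ`, which for the
reference parameters starts at `y(τ*) ≈ 3.76`, peaks at ≈ 7.58 and decays
toward 2 — hence no cycles for any ratio ≤ 2, one for ratios in (2, 3.76),
two for ratios in (3.76, 7.58), none above.  Ratios within 0.5% of a curve
extremum are counted once and flagged tangent; a ratio the descending tail
has not reached by `τ_max` raises a domain error asking for a larger
`τ_max` rather than guessing.

The reconstruction of the n-dimensional orbit from the scalar profile uses
the per-gene shift `x_i(t) = x(t + i·(p/n)T mod T)`: direct substitution
into the ring equations fixes the shift to `≡ τ − τ_eff (mod T)`,
independent of `τ`.  (The source formulation prints the shift as
`i(τ + (p/n)T)` instead; that form is not consistent with the ring
equations for general `(n, p, τ)`, and the residual checks below confirm
the convention used here.)

Every record is verified by integrating the full n-gene system seeded on
the phase-shifted profile and comparing the measured early-window period
to the record's (tolerance 1%).  Unstable cycles hold the seeded orbit
only for a few revolutions — the delay-free even rings are bistable
triggers, so the orbit eventually falls into a steady state — which is why
verification measures the first crossings only and, on failure, polishes
the fixed point against *simulated* periods (secant iteration) before
retrying: a seed inconsistency of 1e-6 is already enough to lose a
strongly unstable cycle within two periods.

Reducibility is arithmetic: `gcd(n, p) = g > 1` means the cycle is the
lift of the `(n/g, p/g)` cycle of the smaller ring; lifting
(`algorithm2_lift`) preserves the period and the absolute phase lag and
multiplies `(s, q)` by `ℓ`.  The lift is verified by a residual check:
substitute the shifted profile into the n-dimensional right-hand side,
taking derivatives from the integration itself (computed against the true,
unwrapped past) and regulator values from the periodically wrapped
profile, so the residual genuinely probes periodic closure.  With the
fixed point refined by simulation and profile tolerance 1e-10, the
residual at mild parameters (α = 10, h = 4) is ~1e-11.  The stability
labelling (stable iff `n` odd and `p = (n−1)/2`) is the numerically
observed parity rule, exposed as a classification and backed by
perturbation tests, not by proof.

For the n = 9 delay-free census the enumeration also finds the reducible
`p = 3` (lag `T/3`) cycle generated by the 3-ring; the reference listing
omits it, so it is reported flagged as reducible and tests accept it only
in that flagged form.

## Inverse problem

On the unique cycle of the delay-free 3-gene step ring, each coordinate
rises toward its `α_i` and decays exponentially once per period.  With the
phase origin at x's *downward* threshold crossing, the six switching times
satisfy nine chained-exponential relations whose closed-form solution is
`z₁ = e^{t₅−t₁}`, `z₃ = e^{t₅−t₃}`,
`α₃ = (1−e^{−(t₄−t₅)})/(1−e^{−(t₄−t₃)})`, `y₂ = e^{t₃−t₂}`,
`y₀ = y₂e^{−(T−t₂)}`, `α₂ = (1−y₀e^{−t₁})/(1−e^{−t₁})`, `x₄ = e^{T−t₄}`,
`x₅ = e^{−t₅}`, `α₁ = (1−e^{−t₂})/(1−e^{−(t₂−t₅)})`.  The downward-origin
convention is forced by the relations themselves (`x₄e^{−(T−t₄)} = 1` with
`x₄` the maximum means x decays through 1 at the period end) and is
confirmed by round-trip recovery: forward event-driven simulation →
extraction → closed forms reproduces random `α ∈ (1.2, 10)³` to ~1e-12.
A consequence of the chaining worth knowing: *every* strictly ordered
observation is internally feasible (all recovered `α_i > 1`, maxima above
and minima below threshold automatically), so the feasibility errors can
fire only on degenerate or corrupted inputs.  Extraction cuts the
last-but-one complete period of the event schedule and rejects any
crossing pattern other than exactly one crossing per role per period.
Rings with more than three genes require a combinatorial treatment of
block transitions and are explicitly not implemented.

## Problem sizes and numerical choices

* Period curve: 160 grid points default; per point, transient
  `max(60, 6·T_est)` then ≥ 8 measured intervals at `rel_tol 1e-7`; the
  previous point's period seeds the next window size.
* Census verification: profile at `rel_tol 1e-8` (1e-9 after refinement),
  n-dimensional check at `rel_tol 1e-9`, 6 periods.
* Root finding: Brent on brackets from sign scans over log-spaced grids
  (400 points for family equations, 4000 for the ratio curve); tolerances
  1e-12..1e-13.  A 1e-5 floor on family periods rejects rounding-level
  sign flips at the degenerate origin of the fixed-point equation.
* Random draws (closed-form vs simulation agreement, inverse round-trips)
  use seeded `numpy.random.default_rng`; ranges `α ∈ (1.5, 50)`,
  `τ ∈ (0.05, 5)` for the step-limit checks and `α ∈ (1.2, 10)³` for the
  inverse problem — comfortably supercritical but far from degenerate.

## Known limitations

* `T(τ)` slightly above `τ*`: the emergent-cycle period grows away from
  `2π/u` at roughly 1.2% per 1% of delay beyond threshold at the reference
  parameters; statements tying the simulated period to `2π/u` hold only
  asymptotically at `τ → τ*+` (measured: +1.2% at `1.01τ*`, +6.0% at
  `1.05τ*`, confirmed against the independent Radau oracle).
* Only symmetric cycles are enumerated; asymmetric cycles of symmetric
  rings, mixed-sign feedback and stochastic kinetics are out of scope.
* Stability labels follow the observed parity rule; no Floquet analysis is
  performed.
* The inverse problem identifies production parameters of the 3-ring with
  `β = 1`; degradation rates and smooth-model parameters are not
  identified.
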