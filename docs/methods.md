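# Methods

## Model

The system couples two ecological variables and one evolutionary one:
prey density *x*, predator density *y*, and the prey population's mean
quantitative trait *c̄*.  The prey's per-capita growth rate is a fitness
landscape over individual trait values *c*,

r(x, y, c̄, c) = a₁c̄/(1+b₁c̄)·(1 − k₁x(c−c̄)) − d₁(1 − k₂(c²−c̄²) + k₄(c⁴−c̄⁴)) − a₂xy/(1+b₂x),

combining (i) a birth rate that saturates in the mean trait (Holling
type II) and is tilted *directionally* by prey density — crowding
penalizes above-average trait values; (ii) a quartic,
density-independent mortality term, the minimal polynomial form that can
hold one or several local fitness maxima; and (iii) a trait-independent
predation loss with a Holling type II response.  Gradient dynamics close
the system: *x* grows at rate r evaluated at c = c̄, the predator
converts prey with asymmetry yₐ and dies at rate d₂, and c̄ moves up the
local fitness gradient with velocity V·∂r/∂c|c→c̄, where the additive
genetic variance V is a fixed parameter.  Assumptions inherited from
that closure: the trait distribution stays narrow and symmetric, V is
constant, and no demographic or environmental noise acts.  Within the
model, c, c̄ live on the half-line; each of x, y, c̄ factors out of its
own equation, so the coordinate planes are invariant and densities
starting positive stay positive.

Parameter defaults are the canonical set used throughout:
a₁ = 2.5, b₁ = 6, a₂ = 0.05, b₂ = 4/3, d₁ = 0.16, d₂ = 0.004, k₁ = 6,
k₂ = 9, k₄ = 9, yₐ = 8, with V = 1/15 (limit-cycle variant) or V = 1/3
(chaotic variant).  The repeating-decimal renderings of b₂ and V are
interpreted as exact rationals.  Units: x, y are densities, c is in
trait units, all rates are per model time unit; V (trait²) sets the
ratio of evolutionary to ecological timescales and is the bifurcation
parameter of interest.

## Phase-transition structure (closed forms)

In the fast-equilibration limit c̄ → c_eq(x), the trait equilibria at
fixed prey density are c = 0 plus the roots of the cubic
g(c) ≡ (2k₂d₁ − 4k₄d₁c²)(1+b₁c) = a₁k₁x.  The analogy with a Landau
free energy (x the control parameter, c the order parameter) gives the
hysteresis loop its two critical points, both closed-form:

- forward fold: c_fwd solves 6k₄b₁c² + 4k₄c − k₂b₁ = 0 (stationarity of
  g), and x_fwd = g(c_fwd)/(a₁k₁).  Canonical values 0.35646 and
  0.44949.
- backward jump: x_bwd = g(0)/(a₁k₁) = 2k₂d₁/(a₁k₁) = 0.192 exactly;
  the branch lands at c_bwd solving 4k₄b₁c² + 4k₄c − 2k₂b₁ = 0
  (0.62867).
- the limiting equilibrium as x → 0 is c_eq^max = √(k₂/2k₄) ≈ 0.70711,
  the ceiling observed for c̄ anywhere on the attractor; the prey
  viability threshold of a frozen trait is c̄† = d₁/(a₁−b₁d₁) ≈ 0.10390.

`critical_points` always cross-validates the closed forms against a
bisection on the disappearance of the positive stable branch of
`cbar_equilibria` (tolerance 1e-6).  For strictly positive parameters
the fold always exists; the "no hysteresis window" error path only fires
for degenerate inputs.  Complex roots are reported by real part with an
explicit flag and excluded from stability tagging, which uses the sign
of the one-dimensional trait-dynamics derivative at fixed x.

## Numerical integration: why log coordinates

On the chaotic attractor the prey density visits ~20 orders of magnitude
per metastable cycle (x ~ 1e-20 on the slow "rim" of the teacup).
Integrating in the original variables fails there: any feasible absolute
tolerance floor lets x cross zero numerically, after which the off-plane
dynamics blow up (observed as solver aborts at the limit-cycle
parameters).  All strictly positive components are therefore integrated
as logarithms — positivity is exact, error control is relative, and the
transformed right-hand side is bounded and smooth.  Components starting
exactly at zero are pinned to their invariant planes.  Defaults:
DOP853, rtol 1e-9, atol 1e-11 (on the log state), uniform resampling at
dt = 0.1, transient discard 2000, initial condition (0.5, 0.5, 0.5);
LSODA is available as a stiff fallback.  Halving the tolerances moves
the attractor's time-averages of x, y, c̄ by < 0.4%.  A divergence guard
aborts with a diagnostic if any density exceeds 1e6; undershoot below
zero cannot occur by construction.

One consequence the reader should expect: with exact deep-rim dynamics
the attractor's quantitative chaos diagnostics differ from what an
original-coordinate integration with a fixed absolute-tolerance floor
produces (see "Lyapunov spectrum" below).

## Lyapunov spectrum

The global spectrum uses the Benettin/QR tangent-space method: three
tangent vectors co-integrated with the fiducial via the analytic
Jacobian, QR re-orthonormalization every Δt = 1 (results are insensitive
to halving this), exponents = time-averaged log growth of the R
diagonal.  The tangent vectors are propagated in the same log chart as
the fiducial, with variational matrix D⁻¹JD − diag(F).  This choice is
load-bearing: in the original chart the tangent's prey component
traverses the same ~20 decades as x itself, bottoms out on the
error-control floor, and its exponential re-expansion amplifies noise
into a spurious positive bias.  The original-chart estimator yields
λ₁ ≈ 0.0046 with a middle exponent at −0.004 — both symptoms of that
corruption — whereas the log-chart estimator pins the neutral
flow-direction exponent at zero to ~1e-6.  Lyapunov exponents are
chart-invariant while the attractor stays at positive densities (the
distortion of the log chart grows subexponentially).

Two independent routes agree on the honest spectrum for the chaotic
variant (V = 1/3): the log-chart QR method and a direct two-trajectory
divergence experiment measured in both the log and the original metric.
All give λ ≈ (+0.0009…0.0011, 0, −1.873), hence D_KY ≈ 2.0005 by the
Kaplan–Yorke formula, and the sum matches the ergodic average of the
Jacobian trace to well under 2%.  The attractor is chaotic but only
barely (edge of chaos), and effectively two-dimensional.  Published
characterizations of this system quote a largest exponent around 0.003
and D_KY ≈ 2.01; we could not reproduce those magnitudes with any
validated estimator and attribute the difference to the rim-floor
artifact described above.  Convergence is slow (metastable epochs last
hundreds of time units): the default run length 2×10⁵ keeps residual
drift of λ₁ below ~1e-4; a convergence flag trips when the running
estimate still moves by half its magnitude over the final fifth.

The hot loop — an embedded Dormand–Prince 5(4) stepper with FSAL on the
12-dimensional augmented system — is numba-compiled (~7× real-time per
10⁵ time units on one CPU); a windowed scipy route implements the same
scheme independently and agrees to 1e-6, serving as the cross-check in
the test suite.

Local (pointwise) Lyapunov exponents are the real parts of the Jacobian
eigenvalues along a trajectory (complex pairs contribute equal real
parts).  Disruptive-selection epochs are maximal runs with λ₁(t) above
the threshold 0.2 — an order of magnitude above the series median
(~0.023 on the chaotic attractor); runs shorter than two sampling
intervals are discarded as chatter, and run lengths are reported raw.
At simulation time 2×10⁵ the epoch lengths span roughly 1.6–8 time
units (max/min ≈ 5); we do not reproduce a multi-decade spread, and
flag this alongside the exponent-magnitude discrepancy above.

## Regime classification

Labels: extinction > fixed_point > limit_cycle > chaos, decided in that
order.

- extinction: either species' density stays below 1e-6 over the final
  quarter of the record.  An instantaneous end-point check would misfire
  — on the rim the prey density routinely dips below any fixed threshold
  and recovers.
- fixed point: state variance below 1e-8.
- limit cycle: the Poincaré return sequence (upward crossings of the
  mid-range trait level) is periodic — for some period k ≤ 16 the median
  distance between crossings k returns apart is < 1% of the attractor's
  spread.  Peak-amplitude dispersion is useless here: the system's
  cycles are long-period sawtooths whose prey maxima differ by tens of
  percent *within* one period (at V = 1/15 one period contains ten prey
  spikes over ~7800 time units and settles only after t ≈ 7×10⁴, hence
  the generous default transient in `scan_V`).
- chaos: aperiodic section and largest Lyapunov exponent above 5e-4 —
  below the chaotic attractor's honest λ₁ (~9e-4) and above the
  estimator drift measured on marginal cycles (~3–4e-4).  Aperiodic
  sections with an inconclusive exponent are labelled limit_cycle with
  an explicit `uncertain` flag, never silently forced.

Along the canonical V grid {1/15, 0.1, 0.15, 0.2, 1/3} this yields
cycle, cycle, cycle, chaos, chaos — a single cycle→chaos hand-off.  The
V = 1/15 point carries the uncertain flag: its section drifts slowly at
finite time (quasi-periodic-looking) and its label rests on the
exponent.

## Hysteresis events and other diagnostics

Jump events are crossings of c̄ through the midpoint of the two jump
traits, ½(c_fwd + c_bwd) ≈ 0.49.  A downward crossing preceded by ≥ 50
time units continuously above c_fwd is a forward collapse; an upward
crossing followed by ≥ 50 units above c_fwd is a backward recovery (the
dwell conditions reject individual swings of the rapid cycling, which
last ~10–20 units).  With V = 1/3 the recorded forward densities
cluster tightly at the fold (median |x − x_fwd| ≈ 0.007–0.02); backward
recoveries lag strongly — by the time c̄ has regrown, x has undershot
x_bwd to ~0.02 — so the test suite asserts recoveries lie below the
backward critical density rather than at it.  During metastable dwells
the quasi-static c̄ tracks the analytic branch to < 0.01.

Power spectra use Welch averaging (mean removal, Hann taper, 4096-sample
segments, 50% overlap).  Spectral flatness comparisons are made in the
band f ≤ 0.25 cycles/unit where the dynamics live; the chaotic state is
clearly flatter than any cycle there.  Poincaré sections use linear
interpolation of level crossings.  Near-linearity (leading principal
direction ≥ 95% of section variance) holds for the trait plane in both
directions (≥ 99.7%) and for downward predator crossings, but *not* for
upward predator crossings (~78%), which sample the fast-cycling handle
across its thickness.

## Problem sizes

Defaults used by the shipped analyses: trajectories of 4–5×10⁴ time
units for attractor statistics, 2×10⁵ for the Lyapunov spectrum and
epoch distribution, 1.2×10⁵ (transient 7×10⁴) per grid point for regime
scans.  These sizes put every reported quantity past its measured
convergence knee; the spectrum's residual seed-to-seed spread is
~1e-4 on λ₁.

## Known limitations

- The gradient-dynamics closure itself (narrow symmetric trait
  distribution, constant V) is taken as given; no full
  trait-distribution model is included.
- No noise, spatial structure, or environmental forcing; prey densities
  of 1e-20 on the rim are taken literally by the deterministic model,
  where any demographic realism would intervene.  This is precisely the
  regime that separates our chaos metrics from floor-regularized
  integrations.
- `classify_regime` cannot distinguish a genuine quasi-periodic torus
  from a marginally converging long-period cycle at finite time; it
  reports its evidence and an uncertain flag instead.
- The CLI serializes results to JSON/CSV but does not plot.
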