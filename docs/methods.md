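# Methods

## Model and assumptions

The package implements a degree-based (heterogeneous) mean-field SIQRS model
on an uncorrelated scale-free network with demography and individual
alertness. The central assumptions:

* **Static topology via empty sites.** Each of the N sites is empty or holds
  one individual; births (rate b) occur only at empty sites and deaths (d
  for S and R, r = d + α for I and Q) empty sites again. The degree
  distribution p(k) is therefore constant in time, which is what makes the
  per-degree density description closed.
* **Annealed, uncorrelated mixing.** The only network statistic entering the
  dynamics is θ = Σ_k k p(k) I_k/⟨k⟩, the probability that a uniformly
  random *edge* points at an infected node. This assumes the degrees of
  adjacent nodes are independent and that each contact is effectively drawn
  fresh from the edge ensemble (annealed approximation).
* **Alertness as a per-exposure coin.** A susceptible with at least one
  infected neighbour is alert with probability p and is then infected per
  contact at γβ instead of β. In the mean field this simply rescales the
  transmission rate to β̃ = (1 − p + pγ)β. Quarantined individuals are
  non-infectious (they do not enter θ).

## Parameters

All rates are per unit time; compartment variables are densities in [0, 1].

| name | meaning | default (threshold studies) |
|------|---------|------------------------------|
| b | birth rate into empty sites | 0.4 |
| d | natural death rate | 0.01 |
| r | removal rate of I and Q (= d + α) | 0.02 |
| β | baseline per-contact infection rate | scenario-specific |
| p | alertness probability, in [0, 1] | scenario-specific |
| γ | alert attenuation factor (alert rate γβ) | scenario-specific |
| δ | quarantine rate | scenario-specific |
| λ | recovery rate of infected | 0.02 |
| η | recovery rate of quarantined | 0.3 |
| μ | immunity-loss rate | 0.7 |

The early-outbreak case study uses b=0.06, β=0.1316, μ=0.9, d=0.01, λ=0.05,
δ=0.32, r=0.05, η=0.3, started from S(0)=1470, I(0)=1, Q(0)=R(0)=0 on a
head-count scale of 1471 and run for 29 days (1 time unit = 1 day); the
degree law defaults to the k⁻³ power law since the case study does not pin
one. Densities are mapped to counts by the `population_scale` config key so
that the internal dynamics always stay inside the invariant region.

The degree law is a truncated power law p(k) ∝ k^(−s) on 1..M, default
s = 3. The cutoff M is an explicit configuration parameter (default 500,
matching the node count used in the threshold studies; the mean-field
equations depend only on p(k) and M, not on N). Two normalisations are
provided: `renormalized` (masses sum to 1; the default, so moment identities
hold exactly) and `zeta_truncated` (masses exactly k⁻ˢ/ζ(s), the
infinite-support constant, leaving tail mass < 1 unretained). The two differ
in ⟨k²⟩/⟨k⟩ by the truncated tail. ζ(s) is evaluated with SciPy's
exponent-generic zeta; the tests re-derive it independently by partial
series summation.

## Equilibria and the threshold

R0 = b β̃ ⟨k²⟩ / ((b+d)(λ+δ+r) ⟨k⟩) is linear in β̃, hence decreasing in p
iff γ < 1 and increasing in γ iff p > 0 (analytic gradients are exposed and
verified against central differences). Setting the per-degree derivatives to
zero gives closed forms for all compartments in terms of θ; inserting
I_k*(θ) into the θ definition yields a scalar map f with f(0) = 0,
f'(0) = R0, f increasing and concave, and f(1) < 1 — so a unique interior
fixed point θ* exists exactly when R0 > 1. The solver brackets
g(θ) = f(θ) − θ on [1e−10, 1] and refines with Brent's method to 1e−12; it
fails loudly (rather than returning the trivial root) if the bracket sign
pattern contradicts R0, since that can only mean a transcription bug. Every
accepted equilibrium is validated by substitution into the full right-hand
side (residual < 1e−8; in practice ~1e−14). f is evaluated through the
uncondensed per-degree closed forms; a condensed single-sum variant (via the
composite constant β′ = A β̃ / C) is kept solely as a cross-check because
its condensation steps are fragile to transcribe. R0 exactly 1 is treated
as "no endemic equilibrium", with a warning; the boundary case is not
otherwise distinguished.

## Stability verification

Stability is verified *numerically*, not symbolically. The analytic Jacobian
of the 4M-dimensional system is assembled exactly (the θ coupling
contributes rank-one blocks β̃ k S_k · j p(j)/⟨k⟩) and checked against
central finite differences. At the disease-free state the spectrum is known
in closed form — −(b+d), −(r+η), −(μ+d) each with multiplicity M,
−(λ+δ+r) with multiplicity M−1, and the threshold eigenvalue
(λ+δ+r)(R0−1) — and the numeric spectrum is required to match it. At the
endemic state no reduced block argument is used: the full dense spectrum is
the ground truth (4M ≤ 2000 is trivial for a dense eigensolver). The
stable/unstable verdict uses a margin of 1e−8 on the spectral abscissa;
anything inside the margin is reported as "marginal", never rounded.

Global decay below threshold is checked along integrated trajectories with
the case-split Lyapunov candidate (weights a_k = k p(k)/(⟨k⟩(λ+δ+r))): for
μ ≥ b the Volterra form Σ a_k (S_k − S⁰ − S⁰ log(S_k/S⁰)) + Σ a_k I_k
(requires S_k > 0 and trajectories inside the invariant region), for μ < b
the linear form Σ a_k I_k. Monotonicity is asserted stepwise with an
allowance of 10·rtol per reported step.

## Numerical integration

`solve_ivp` with LSODA (stiff-capable; the system becomes moderately stiff
for large δ, η, μ) at rtol = 1e−8, atol = 1e−10, fed the analytic Jacobian.
Densities in (−10·atol, 0) are clamped to zero at reporting time only;
larger negativity raises, since it signals genuine integrator failure
rather than roundoff. A run is marked converged when max|dX_k/dt| < 1e−9 at
the final time. Initial conditions for threshold scenarios default to a
uniform seed infection I_k(0) = 0.01 below the disease-free susceptible
level; acceptance-style checks instead draw random interior starts filling
20–95% of the invariant-region bound, which exercises the basin of
attraction rather than a single trajectory.

## Stochastic check

The agent-based counterpart runs the exact same event rates on a quenched
configuration-model graph (degrees i.i.d. from p(k), one degree resampled if
the stub sum is odd, self-loops and multi-edges discarded). Sampling is
exact event-driven stochastic simulation (Gillespie's direct method) with
per-node total rates in a Fenwick tree — O(log N) per event, no
time-discretisation bias, and bit-reproducible for a fixed seed. The
alertness coin is flipped once per 0→positive transition of a susceptible's
infected-neighbour count, persists while the count stays positive, and is
re-flipped on re-entry into S, matching the mean-field rescaling in
expectation.

Problem sizes: the threshold-dichotomy and Lyapunov checks run 40 random
parameter sets at cutoff M = 50 (200 ODE dimensions, horizon 6000); the
stochastic comparison uses N = 10⁴ nodes and 20 replicate seeds, with the
decay-law calibration pooled over ~10³ infected nodes. These sizes make the
whole verification suite run in well under a minute while keeping
Monte-Carlo standard errors below a percent.

## What the synthetic scenarios do and do not show

The random fixture generator draws p, γ, δ uniformly and then *solves* β
from the (linear) R0 formula so each set lands exactly in a prescribed R0
stratum ((0.1, 0.9] below threshold, [1.1, 5] above). This stresses the
threshold dichotomy uniformly over the control-parameter space but keeps the
demographic rates at the fixed base set; it does not probe extreme rate
ratios (e.g. μ, η ≫ 1) beyond what the base set implies, nor degree
exponents other than the configured one.

## Known limitation: annealed mean field on sparse quenched graphs

The k⁻³ degree law with minimum degree 1 has ⟨k⟩ ≈ 1.35, and a quenched
configuration-model realisation of it barely percolates: the acceptance
script reports the giant-component fraction (≈0.15–0.2 at N = 10⁴,
realisation-dependent because the graph sits close to the percolation
threshold), and a majority of nodes sit in isolated degree-1 dyads where
infection cannot persist. The mean-field equations, which implicitly re-draw neighbours from
the edge ensemble at every contact, see none of this structure.
Consequently the stochastic endemic prevalence on this topology is
several-fold below the mean-field level (the script reports both, ~0.07 vs
~0.43 in the reference endemic scenario, a relative error of ~0.83) — far
outside any sampling error — while on a denser degree law (exponent 1.5,
⟨k⟩ ≈ 5.5, also reported by the script) the two agree to within roughly
10%. The discrepancy is a property of the approximation, not of either
implementation: the simulator is validated against the exact exponential
survival law in the transmission-free limit, and the mean-field equilibria
are validated against the closed forms and long-time integration to ~1e−12.
The corresponding agreement check in the test suite is asserted at the
sparse study topology and therefore fails there; the failure is a
quantified statement of where the annealed mean-field approximation breaks
down, not a defect to be tuned away.

## Design choices made where the design was open

* Initial per-degree densities for the threshold figures default to a
  uniform small seed (I₀ = 0.01), configurable; explicit per-degree CSV
  initial states are supported.
* Whether quarantined neighbours still trigger alertness is unspecified in
  the model statement; they are treated as non-infectious everywhere, so
  they neither transmit nor hold a susceptible's alert flag.
* The Lyapunov case split is selected by comparing μ and b (μ ≥ b uses the
  Volterra form); the boundary μ = b is grouped with the logarithmic case.
* The stochastic oracle defaults to N = 10⁴ and 20 replicates (rather than
  the 500-node scale of the mean-field scenarios) to keep replicate standard
  errors small relative to the effects measured; N is configurable down to
  500.
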