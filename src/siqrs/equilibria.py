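"""Basic reproduction number and the two equilibria of the SIQRS system.

The threshold quantity is

    R0 = b * beta_eff / ((b + d)(lambda + delta + r)) * <k^2>/<k>,

with beta_eff = (1 - p + p*gamma) * beta: a new infection requires a
susceptible host (available at density b/(b+d) at the disease-free state),
transmits for an average 1/(lambda + delta + r), and the excess-degree factor
<k^2>/<k> accounts for the heterogeneous contact structure.  R0 is linear in
beta_eff, hence decreasing in the alertness probability p whenever the
attenuation gamma < 1, and increasing in gamma whenever p > 0.

Below threshold the only equilibrium is disease-free, S_k = b/(b+d) with
I = Q = R = 0.  Above threshold an endemic equilibrium exists; setting the
per-degree derivatives to zero gives closed forms for every compartment in
terms of the equilibrium edge-infection probability theta*:

    I_k* = beta_eff k S_k* theta* / (lambda + delta + r)
    Q_k* = delta I_k* / (r + eta)
    R_k* = (lambda I_k* + eta Q_k*) / (mu + d)
    S_k* = b (r+eta)(mu+d)(lambda+delta+r) / (C + A beta_eff k theta*)

with A = (b+r)(mu+d)(r+eta+delta) + (b+d)(delta*eta + lam*r + lam*eta) and
C = (b+d)(r+eta)(mu+d)(lambda+delta+r).  Re-inserting I_k* into the theta
definition yields the scalar self-consistency map f, whose non-trivial fixed
point theta* in (0, 1] exists and is unique exactly when R0 = f'(0) > 1
(f is increasing and concave with f(0) = 0 and f(1) < 1).

The solver evaluates f through the uncondensed per-degree formulas above; the
condensed single-sum form f(theta) = const * sum_k beta' k^2 p(k) theta /
(1 + beta' k theta) with beta' = A*beta_eff/C is exposed separately as a
cross-check, because the condensed constants are easy to mistranscribe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
from scipy.optimize import brentq

from .degree_distribution import DegreeDistribution
from .model_core import DegreeState, ModelParameters, rhs

__all__ = [
    "EquilibriumResult",
    "R0Gradient",
    "basic_reproduction_number",
    "r0_gradient",
    "disease_free_equilibrium",
    "endemic_state_at",
    "self_consistency_f",
    "self_consistency_f_condensed",
    "solve_endemic",
]


@dataclass
class EquilibriumResult:
    """An equilibrium state with its type and diagnostics.

    ``residual`` is the max-abs right-hand side of the dynamics at the state;
    an accepted result has residual < 1e-8.
    """

    kind: str  # "disease_free" or "endemic"
    theta_star: float
    state: DegreeState
    residual: float
    r0: float


class R0Gradient(NamedTuple):
    d_p: float
    d_gamma: float
    d_beta: float


def _check_rates(params: ModelParameters) -> None:
    if params.b + params.d <= 0:
        raise ValueError("b + d must be positive")
    if params.infectious_exit_rate <= 0:
        raise ValueError("lambda + delta + r must be positive")


def basic_reproduction_number(params: ModelParameters, dist: DegreeDistribution) -> float:
    """R0 = b beta_eff <k^2> / ((b+d)(lambda+delta+r) <k>)."""
    _check_rates(params)
    if dist.mean_degree <= 0:
        raise ValueError("mean degree must be positive")
    return (
        params.b
        * params.beta_eff
        / ((params.b + params.d) * params.infectious_exit_rate)
        * dist.moment_ratio
    )


def r0_gradient(params: ModelParameters, dist: DegreeDistribution) -> R0Gradient:
    """Analytic partials of R0 with respect to p, gamma and beta.

    Since R0 = c * (1 - p + p*gamma) * beta with a positive constant c,
    dR0/dp = c*beta*(gamma - 1) is negative iff gamma < 1 (and beta > 0),
    dR0/dgamma = c*beta*p is positive iff p > 0 (and beta > 0), and
    dR0/dbeta = c*(1 - p + p*gamma) >= 0.
    """
    _check_rates(params)
    c = (
        params.b
        / ((params.b + params.d) * params.infectious_exit_rate)
        * dist.moment_ratio
    )
    return R0Gradient(
        d_p=c * params.beta * (params.gamma - 1.0),
        d_gamma=c * params.beta * params.p,
        d_beta=c * (1.0 - params.p + params.p * params.gamma),
    )


def disease_free_equilibrium(params: ModelParameters, dist: DegreeDistribution) -> EquilibriumResult:
    """The disease-free equilibrium: S_k = b/(b+d), I = Q = R = 0."""
    _check_rates(params)
    m = dist.degrees.size
    s0 = params.dfe_susceptible_level
    state = DegreeState(S=np.full(m, s0), I=np.zeros(m), Q=np.zeros(m), R=np.zeros(m))
    deriv = rhs(state, params, dist)
    residual = float(np.max(np.abs(deriv.to_vector())))
    return EquilibriumResult(
        kind="disease_free",
        theta_star=0.0,
        state=state,
        residual=residual,
        r0=basic_reproduction_number(params, dist),
    )


def _condensed_constants(params: ModelParameters) -> tuple[float, float, float]:
    """A, C and beta' = A*beta_eff/C from the condensed fixed-point form."""
    b, d, r = params.b, params.d, params.r
    lam, eta, mu, delta = params.lam, params.eta, params.mu, params.delta
    A = (b + r) * (mu + d) * (r + eta + delta) + (b + d) * (
        delta * eta + lam * r + lam * eta
    )
    C = (b + d) * (r + eta) * (mu + d) * params.infectious_exit_rate
    return A, C, A * params.beta_eff / C


def endemic_state_at(theta_value: float, params: ModelParameters, dist: DegreeDistribution) -> DegreeState:
    """Evaluate the endemic closed forms at a given edge-infection level theta.

    For theta in (0, 1] this is the candidate endemic state; it is a true
    equilibrium only when theta solves the self-consistency equation.
    """
    _check_rates(params)
    b, d, r = params.b, params.d, params.r
    lam, eta, mu, delta = params.lam, params.eta, params.mu, params.delta
    A, C, _ = _condensed_constants(params)
    k = dist.degrees.astype(np.float64)
    denom = C + A * params.beta_eff * k * theta_value
    S = b * (r + eta) * (mu + d) * params.infectious_exit_rate / denom
    I = b * (r + eta) * (mu + d) * params.beta_eff * k * theta_value / denom
    Q = b * delta * (mu + d) * params.beta_eff * k * theta_value / denom
    R = (
        b
        * (delta * eta + lam * r + lam * eta)
        * params.beta_eff
        * k
        * theta_value
        / denom
    )
    return DegreeState(S=S, I=I, Q=Q, R=R)


def self_consistency_f(theta_value: float, params: ModelParameters, dist: DegreeDistribution) -> float:
    """The self-consistency map f(theta) = sum_k k p(k) I_k*(theta) / <k>.

    Evaluated by composing I_k* = beta_eff k S_k*(theta) theta / (lam+delta+r)
    with the closed form for S_k*(theta), summed explicitly over the support.
    f(0) = 0 exactly; the non-trivial fixed point is the endemic theta*.
    """
    if not 0.0 <= theta_value <= 1.0:
        raise ValueError(f"theta must lie in [0, 1], got {theta_value}")
    state = endemic_state_at(theta_value, params, dist)
    I = params.beta_eff * dist.degrees * state.S * theta_value / params.infectious_exit_rate
    return float(np.dot(dist.edge_weights(), I))


def self_consistency_f_condensed(theta_value: float, params: ModelParameters, dist: DegreeDistribution) -> float:
    """Condensed single-sum form of f using beta' = A*beta_eff/C.

    f(theta) = b(r+eta)(mu+d)/(<k> A) * sum_k beta' k^2 p(k) theta/(1+beta' k theta).
    Kept as an independent cross-check of :func:`self_consistency_f`.
    """
    if not 0.0 <= theta_value <= 1.0:
        raise ValueError(f"theta must lie in [0, 1], got {theta_value}")
    A, _, beta_prime = _condensed_constants(params)
    b, d, r = params.b, params.d, params.r
    eta, mu = params.eta, params.mu
    k = dist.degrees.astype(np.float64)
    pk = dist.probabilities
    series = np.sum(beta_prime * k**2 * pk * theta_value / (1.0 + beta_prime * k * theta_value))
    return float(b * (r + eta) * (mu + d) / (dist.mean_degree * A) * series)


def solve_endemic(
    params: ModelParameters,
    dist: DegreeDistribution,
    tol: float = 1e-12,
    residual_tol: float = 1e-8,
) -> Optional[EquilibriumResult]:
    """Solve for the endemic equilibrium; ``None`` when R0 <= 1.

    Finds the unique root theta* of g(theta) = f(theta) - theta on (0, 1]
    by bracketed root search (g(eps) > 0 for small eps because f'(0) = R0 > 1;
    g(1) < 0 because f(1) < 1), then evaluates the closed-form state at
    theta*.  The result is validated by substituting into the full dynamics;
    a residual above ``residual_tol`` signals a transcription bug and raises.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    r0 = basic_reproduction_number(params, dist)
    if r0 <= 1.0:
        if r0 == 1.0:
            warnings.warn("R0 is exactly 1: no endemic equilibrium returned", stacklevel=2)
        return None

    def g(th: float) -> float:
        return self_consistency_f(th, params, dist) - th

    eps = 1e-10
    if g(eps) <= 0.0:
        raise RuntimeError(
            "self-consistency map not above the diagonal near 0 despite R0 > 1; "
            "this indicates a formula transcription bug"
        )
    if g(1.0) >= 0.0:
        raise RuntimeError("f(1) >= 1: violates the a-priori bound f(1) < 1")
    theta_star = float(brentq(g, eps, 1.0, xtol=min(tol, 1e-12), rtol=8.9e-16, maxiter=200))
    if abs(g(theta_star)) > tol:
        raise RuntimeError(f"fixed point residual {g(theta_star):.3e} exceeds tol {tol:.3e}")
    state = endemic_state_at(theta_star, params, dist)
    deriv = rhs(state, params, dist)
    residual = float(np.max(np.abs(deriv.to_vector())))
    if residual > residual_tol:
        raise RuntimeError(
            f"endemic state residual {residual:.3e} exceeds {residual_tol:.3e}; "
            "closed forms inconsistent with the dynamics"
        )
    return EquilibriumResult(
        kind="endemic",
        theta_star=theta_star,
        state=state,
        residual=residual,
        r0=r0,
    )
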