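"""The SIQRS mean-field system: parameters, state, right-hand side, integration.

The model lives on a static network whose N sites are either empty (V) or
occupied by one individual who is susceptible (S), infected (I), quarantined
(Q) or recovered (R).  Births fill empty sites at rate b with susceptibles;
natural death (rate d) and disease-related removal (rate r = d + alpha for
infected and quarantined individuals) empty sites again, so the degree
distribution never changes.  A susceptible who notices an infected neighbour
becomes "alert" with probability p and is then infected per contact at the
attenuated rate gamma*beta instead of beta; averaging over alertness gives the
effective transmission rate

    beta_eff = (1 - p + p*gamma) * beta.

Grouping nodes by degree k = 1..M and writing S_k, I_k, Q_k, R_k for the
per-degree densities (V_k = 1 - S_k - I_k - Q_k - R_k), the mean-field
dynamics are, for each k,

    dS_k/dt = b*V_k - beta_eff*k*S_k*theta + mu*R_k - d*S_k
    dI_k/dt = beta_eff*k*S_k*theta - (lambda + delta + r)*I_k
    dQ_k/dt = delta*I_k - (r + eta)*Q_k
    dR_k/dt = lambda*I_k + eta*Q_k - (mu + d)*R_k

coupled across degrees only through the probability that a random edge points
at an infected node,

    theta = sum_k k p(k) I_k / <k>.

The per-degree totals obey d(S+I+Q+R)/dt <= b - (b+d)(S+I+Q+R), so the box
with per-degree totals below b/(b+d) is forward invariant (the region Gamma);
trajectories are checked against it with :func:`check_invariant_region`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace as _dc_replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .degree_distribution import DegreeDistribution

__all__ = [
    "ModelParameters",
    "DegreeState",
    "Trajectory",
    "IntegrationError",
    "theta",
    "rhs",
    "integrate",
    "aggregate",
    "check_invariant_region",
    "InvariantRegionReport",
]


class IntegrationError(RuntimeError):
    """Integrator failure; carries the last time the solver reached."""

    def __init__(self, message: str, last_time: float):
        super().__init__(message)
        self.last_time = last_time


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants of the SIQRS system (all per unit time, non-negative).

    Attributes
    ----------
    b : birth rate into empty sites.
    d : natural death rate.
    r : removal rate of infected and quarantined individuals, r = d + alpha
        with alpha the disease-induced death rate; r >= d is expected.
    beta : baseline per-contact infection rate.
    p : probability a susceptible with an infected neighbour becomes alert,
        in [0, 1].
    gamma : attenuation factor for alert susceptibles (infected at gamma*beta).
    delta : quarantine rate of infected individuals.
    lam : recovery rate of infected individuals (lambda).
    eta : recovery rate of quarantined individuals.
    mu : immunity-loss rate (recovered revert to susceptible).
    """

    b: float
    d: float
    r: float
    beta: float
    p: float
    gamma: float
    delta: float
    lam: float
    eta: float
    mu: float

    def __post_init__(self) -> None:
        for name in ("b", "d", "r", "beta", "p", "gamma", "delta", "lam", "eta", "mu"):
            value = float(getattr(self, name))
            object.__setattr__(self, name, value)
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"parameter {name} must be finite and >= 0, got {value}")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"alertness probability p must lie in [0, 1], got {self.p}")
        if self.r < self.d:
            warnings.warn(
                "r < d: removal rate of infected should be r = d + alpha >= d",
                stacklevel=2,
            )

    @property
    def beta_eff(self) -> float:
        """Effective transmission rate (1 - p + p*gamma) * beta."""
        return (1.0 - self.p + self.p * self.gamma) * self.beta

    @property
    def infectious_exit_rate(self) -> float:
        """Total exit rate from the infected compartment, lambda + delta + r."""
        return self.lam + self.delta + self.r

    @property
    def dfe_susceptible_level(self) -> float:
        """S_k at the disease-free equilibrium, b/(b+d)."""
        if self.b + self.d <= 0:
            raise ValueError("b + d must be positive")
        return self.b / (self.b + self.d)

    def replace(self, **kwargs) -> "ModelParameters":
        return _dc_replace(self, **kwargs)


@dataclass
class DegreeState:
    """Per-degree compartment densities (S_k, I_k, Q_k, R_k), k = 1..M."""

    S: np.ndarray
    I: np.ndarray
    Q: np.ndarray
    R: np.ndarray

    def __post_init__(self) -> None:
        for name in ("S", "I", "Q", "R"):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            setattr(self, name, arr)
        m = self.S.size
        if not all(getattr(self, c).shape == (m,) for c in ("S", "I", "Q", "R")):
            raise ValueError("S, I, Q, R must be 1-d arrays of equal length")

    @property
    def n_degrees(self) -> int:
        return self.S.size

    @property
    def total(self) -> np.ndarray:
        """Per-degree occupied density S_k + I_k + Q_k + R_k (<= 1)."""
        return self.S + self.I + self.Q + self.R

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.S, self.I, self.Q, self.R])

    @classmethod
    def from_vector(cls, y: np.ndarray) -> "DegreeState":
        y = np.asarray(y, dtype=np.float64)
        if y.size % 4:
            raise ValueError("state vector length must be a multiple of 4")
        m = y.size // 4
        return cls(S=y[:m].copy(), I=y[m : 2 * m].copy(), Q=y[2 * m : 3 * m].copy(), R=y[3 * m :].copy())

    @classmethod
    def uniform_seed(cls, params: ModelParameters, n_degrees: int, i0: float = 0.01) -> "DegreeState":
        """Disease-free susceptible level minus a uniform seed infection i0."""
        s0 = params.dfe_susceptible_level
        if not 0.0 <= i0 <= s0:
            raise ValueError(f"seed infection i0 must lie in [0, {s0}]")
        m = int(n_degrees)
        return cls(
            S=np.full(m, s0 - i0),
            I=np.full(m, i0),
            Q=np.zeros(m),
            R=np.zeros(m),
        )

    def validate(self, atol: float = 1e-9) -> None:
        """Raise if any density is outside [0, 1] or a total exceeds 1."""
        for name in ("S", "I", "Q", "R"):
            arr = getattr(self, name)
            if np.any(~np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            if np.any(arr < -atol) or np.any(arr > 1 + atol):
                raise ValueError(f"{name} outside [0, 1] beyond tolerance {atol}")
        if np.any(self.total > 1 + atol):
            raise ValueError("per-degree totals exceed 1")

    def copy(self) -> "DegreeState":
        return DegreeState(self.S.copy(), self.I.copy(), self.Q.copy(), self.R.copy())


def _check_dims(state: DegreeState, dist: DegreeDistribution) -> None:
    if state.n_degrees != dist.degrees.size:
        raise ValueError(
            f"state has {state.n_degrees} degree classes but distribution has {dist.degrees.size}"
        )


def theta(state: DegreeState, dist: DegreeDistribution) -> float:
    """Probability that a randomly followed edge leads to an infected node.

    theta = sum_k k p(k) I_k / <k>.  Equals c when every I_k = c, because the
    edge weights k p(k)/<k> sum to the retained mass over <k> (exactly 1 in
    renormalized mode).
    """
    _check_dims(state, dist)
    return float(np.dot(dist.edge_weights(), state.I))


def _rhs_vector(y: np.ndarray, params: ModelParameters, k: np.ndarray, gk: np.ndarray) -> np.ndarray:
    """RHS on the packed vector [S, I, Q, R]; k = degrees, gk = k p(k)/<k>."""
    m = k.size
    S, I, Q, R = y[:m], y[m : 2 * m], y[2 * m : 3 * m], y[3 * m :]
    th = float(np.dot(gk, I))
    infection = params.beta_eff * k * S * th
    dS = params.b * (1.0 - S - I - Q - R) - infection + params.mu * R - params.d * S
    dI = infection - params.infectious_exit_rate * I
    dQ = params.delta * I - (params.r + params.eta) * Q
    dR = params.lam * I + params.eta * Q - (params.mu + params.d) * R
    return np.concatenate([dS, dI, dQ, dR])


def rhs(state: DegreeState, params: ModelParameters, dist: DegreeDistribution) -> DegreeState:
    """Time derivative of the mean-field system at ``state``."""
    _check_dims(state, dist)
    y = state.to_vector()
    if np.any(~np.isfinite(y)):
        raise ValueError("state contains NaN or infinite entries")
    k = dist.degrees.astype(np.float64)
    dy = _rhs_vector(y, params, k, dist.edge_weights())
    return DegreeState.from_vector(dy)


def _jacobian_vector(y: np.ndarray, params: ModelParameters, k: np.ndarray, gk: np.ndarray) -> np.ndarray:
    """Exact Jacobian of :func:`_rhs_vector` (dense 4M x 4M).

    The theta coupling contributes rank-one cross blocks
    d(dS_k)/dI_j = -b delta_kj - beta_eff k S_k g(j) and
    d(dI_k)/dI_j = +beta_eff k S_k g(j) - (lambda+delta+r) delta_kj.
    """
    m = k.size
    S, I = y[:m], y[m : 2 * m]
    th = float(np.dot(gk, I))
    e = params.beta_eff
    eye = np.eye(m)
    cross = np.outer(e * k * S, gk)  # beta_eff * k * S_k * g(j)

    J = np.zeros((4 * m, 4 * m))
    sl_S, sl_I = slice(0, m), slice(m, 2 * m)
    sl_Q, sl_R = slice(2 * m, 3 * m), slice(3 * m, 4 * m)

    J[sl_S, sl_S] = np.diag(-(params.b + params.d) - e * k * th)
    J[sl_S, sl_I] = -params.b * eye - cross
    J[sl_S, sl_Q] = -params.b * eye
    J[sl_S, sl_R] = (params.mu - params.b) * eye

    J[sl_I, sl_S] = np.diag(e * k * th)
    J[sl_I, sl_I] = cross - params.infectious_exit_rate * eye

    J[sl_Q, sl_I] = params.delta * eye
    J[sl_Q, sl_Q] = -(params.r + params.eta) * eye

    J[sl_R, sl_I] = params.lam * eye
    J[sl_R, sl_Q] = params.eta * eye
    J[sl_R, sl_R] = -(params.mu + params.d) * eye
    return J


@dataclass
class Trajectory:
    """Integrated mean-field trajectory reported on an even time grid.

    ``y`` holds raw solver output (rows = times, columns = packed state);
    :meth:`states` applies the reporting-time clamp of tiny negative densities
    (within -10*atol) to zero.  Larger negativity raises at construction.
    """

    times: np.ndarray
    y: np.ndarray
    params: ModelParameters
    dist: DegreeDistribution
    rtol: float
    atol: float
    converged: bool
    final_derivative_norm: float

    def state_at(self, index: int) -> DegreeState:
        row = self.y[index].copy()
        row[(row < 0) & (row > -10 * self.atol)] = 0.0
        return DegreeState.from_vector(row)

    def states(self) -> list[DegreeState]:
        return [self.state_at(i) for i in range(self.times.size)]

    @property
    def final_state(self) -> DegreeState:
        return self.state_at(self.times.size - 1)


def integrate(
    params: ModelParameters,
    dist: DegreeDistribution,
    init: DegreeState,
    t_end: float,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    n_report: int = 201,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the 4M-dimensional system and report on an even grid.

    Uses an adaptive, stiff-capable solver with the analytic Jacobian (the
    system becomes moderately stiff for large delta, eta or mu).  Deterministic
    for identical inputs.  Raises :class:`IntegrationError` on solver failure,
    carrying the last time reached, and on densities more negative than
    -10*atol (a sign of genuine integrator trouble rather than roundoff).
    """
    _check_dims(init, dist)
    if not t_end > 0:
        raise ValueError("t_end must be positive")
    init.validate(atol=max(atol, 1e-9))
    k = dist.degrees.astype(np.float64)
    gk = dist.edge_weights()

    def fun(t, y):
        return _rhs_vector(y, params, k, gk)

    def jac(t, y):
        return _jacobian_vector(y, params, k, gk)

    t_eval = np.linspace(0.0, float(t_end), int(n_report))
    sol = solve_ivp(
        fun,
        (0.0, float(t_end)),
        init.to_vector(),
        method=method,
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
        jac=jac if method in ("LSODA", "BDF", "Radau") else None,
    )
    if not sol.success:
        last_t = float(sol.t[-1]) if sol.t.size else 0.0
        raise IntegrationError(f"integrator failed: {sol.message}", last_time=last_t)
    y = sol.y.T
    if y.min() < -10 * atol:
        raise IntegrationError(
            f"densities went negative beyond -10*atol (min {y.min():.3e})",
            last_time=float(sol.t[-1]),
        )
    final_deriv = _rhs_vector(y[-1], params, k, gk)
    norm = float(np.max(np.abs(final_deriv)))
    return Trajectory(
        times=sol.t,
        y=y,
        params=params,
        dist=dist,
        rtol=rtol,
        atol=atol,
        converged=norm < 1e-9,
        final_derivative_norm=norm,
    )


def aggregate(traj: Trajectory) -> pd.DataFrame:
    """Population-level curves X(t) = sum_k p(k) X_k(t) for X in S, I, Q, R."""
    if traj.times.size == 0:
        raise ValueError("empty trajectory")
    m = traj.dist.degrees.size
    pk = traj.dist.probabilities
    y = traj.y.copy()
    y[(y < 0) & (y > -10 * traj.atol)] = 0.0
    out = {"t": traj.times}
    for i, name in enumerate(("S", "I", "Q", "R")):
        out[name] = y[:, i * m : (i + 1) * m] @ pk
    return pd.DataFrame(out)


@dataclass
class InvariantRegionReport:
    """Diagnostics for the forward-invariant region Gamma."""

    bound: float  # b / (b + d)
    max_total: float  # max over times and degrees of S_k+I_k+Q_k+R_k
    max_total_final: float  # same, at the last reported time
    min_entry: float  # most negative density seen
    within_bound_all_times: bool
    within_bound_tail: bool
    has_negative: bool


def check_invariant_region(traj: Trajectory, tol: float = 1e-6) -> InvariantRegionReport:
    """Check the trajectory against the invariant region Gamma.

    Gamma bounds every per-degree total S_k+I_k+Q_k+R_k by b/(b+d); a
    trajectory started inside must stay inside (up to tol), and one started
    outside must fall below the bound eventually (checked via the final time).
    """
    m = traj.dist.degrees.size
    y = traj.y
    totals = y[:, :m] + y[:, m : 2 * m] + y[:, 2 * m : 3 * m] + y[:, 3 * m :]
    bound = traj.params.dfe_susceptible_level
    max_total = float(totals.max())
    max_final = float(totals[-1].max())
    min_entry = float(y.min())
    return InvariantRegionReport(
        bound=bound,
        max_total=max_total,
        max_total_final=max_final,
        min_entry=min_entry,
        within_bound_all_times=max_total <= bound + tol,
        within_bound_tail=max_final <= bound + tol,
        has_negative=min_entry < -tol,
    )
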