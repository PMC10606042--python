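"""Scenario configs, end-to-end runs, parameter sweeps and the Wuhan case.

A scenario bundles a parameter set, a degree distribution, an initial state
and an integration spec, optionally with a parameter sweep and a stochastic
comparison.  Running one computes R0 up front, integrates the mean field,
solves both equilibria, runs the stability checks and reports invariant-region
diagnostics; everything is logged as machine-parsable ``key=value`` lines.

Module-level defaults reproduce two studied settings:

* the base rate set b=0.4, mu=0.7, d=0.01, lambda=0.02, r=0.02, eta=0.3 on a
  k^-3 power-law network, with beta, p, gamma, delta varied to place R0 on
  either side of 1;
* an early-COVID-19 Wuhan setting (b=0.06, beta=0.1316, mu=0.9, d=0.01,
  lambda=0.05, delta=0.32, r=0.05, eta=0.3) started from S(0)=1470, I(0)=1,
  Q(0)=R(0)=0 on a 1471-individual scale and run for 29 days, used to probe
  the sensitivity of infection counts to the alertness parameters p and gamma.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .degree_distribution import (
    RENORMALIZED,
    DegreeDistribution,
    truncated_power_law,
)
from .equilibria import (
    EquilibriumResult,
    basic_reproduction_number,
    disease_free_equilibrium,
    solve_endemic,
)
from .model_core import (
    DegreeState,
    ModelParameters,
    Trajectory,
    aggregate,
    check_invariant_region,
    integrate,
)
from .stability import StabilityReport, dfe_stability, endemic_stability
from .stochastic import build_network, compare_to_meanfield, simulate

__all__ = [
    "BASE_RATES",
    "WUHAN_PARAMS",
    "WUHAN_POPULATION",
    "ScenarioConfig",
    "ScenarioBundle",
    "ConfigError",
    "run_scenario",
    "run_sweep",
    "run_wuhan_case",
    "generate_fixtures",
    "ParameterFixture",
]

logger = logging.getLogger("siqrs")

#: base rate set used throughout the threshold studies.
BASE_RATES = {"b": 0.4, "mu": 0.7, "d": 0.01, "lam": 0.02, "r": 0.02, "eta": 0.3}

#: early-outbreak Wuhan parameter set (p and gamma are the swept inputs).
WUHAN_PARAMS = {
    "b": 0.06,
    "beta": 0.1316,
    "gamma": 0.04,
    "mu": 0.9,
    "d": 0.01,
    "lam": 0.05,
    "delta": 0.32,
    "r": 0.05,
    "eta": 0.3,
}

#: initial head count S(0) + I(0) used to convert densities to counts.
WUHAN_POPULATION = 1471


class ConfigError(ValueError):
    """Raised with the full list of offending config keys."""

    def __init__(self, errors: list[str]):
        super().__init__("invalid scenario config:\n  " + "\n  ".join(errors))
        self.errors = errors


_PARAM_KEYS = ("b", "d", "r", "beta", "p", "gamma", "delta", "lam", "eta", "mu")
# accept the spelled-out key too (lambda is a Python keyword)
_PARAM_ALIASES = {"lambda": "lam"}


@dataclass
class ScenarioConfig:
    params: ModelParameters
    dist: DegreeDistribution
    init_mode: str = "uniform_seed"  # or "explicit"
    i0: float = 0.01
    init_state: Optional[DegreeState] = None
    t_end: float = 2000.0
    rtol: float = 1e-8
    atol: float = 1e-10
    n_report: int = 201
    method: str = "LSODA"
    sweep_parameter: Optional[str] = None
    sweep_values: Optional[Sequence[float]] = None
    abm_n: Optional[int] = None
    abm_replicates: int = 20
    abm_seed: int = 0
    population_scale: float = 1.0

    @classmethod
    def from_dict(cls, raw: dict) -> "ScenarioConfig":
        errors: list[str] = []

        pdict = dict(raw.get("params") or {})
        for alias, target in _PARAM_ALIASES.items():
            if alias in pdict:
                pdict[target] = pdict.pop(alias)
        missing = [k for k in _PARAM_KEYS if k not in pdict]
        unknown = [k for k in pdict if k not in _PARAM_KEYS]
        if missing:
            errors.append(f"params: missing keys {missing}")
        if unknown:
            errors.append(f"params: unknown keys {unknown}")
        params = None
        if not errors:
            try:
                params = ModelParameters(**{k: float(pdict[k]) for k in _PARAM_KEYS})
            except (TypeError, ValueError) as exc:
                errors.append(f"params: {exc}")

        ddict = dict(raw.get("degree_distribution") or {})
        exponent = ddict.get("exponent", 3.0)
        max_degree = ddict.get("max_degree", 500)
        normalization = ddict.get("normalization", RENORMALIZED)
        dist = None
        try:
            dist = truncated_power_law(exponent, max_degree, normalization)
        except (TypeError, ValueError) as exc:
            errors.append(f"degree_distribution: {exc}")

        idict = dict(raw.get("init") or {})
        init_mode = idict.get("mode", "uniform_seed")
        if init_mode not in ("uniform_seed", "explicit"):
            errors.append(f"init.mode: unknown mode {init_mode!r}")
        i0 = float(idict.get("I0", 0.01))
        init_state = None
        if init_mode == "explicit":
            path = idict.get("file")
            if path is None:
                errors.append("init.file: required for explicit init mode")
            else:
                try:
                    frame = pd.read_csv(path)
                    init_state = DegreeState(
                        S=frame["S"].to_numpy(),
                        I=frame["I"].to_numpy(),
                        Q=frame["Q"].to_numpy(),
                        R=frame["R"].to_numpy(),
                    )
                except Exception as exc:  # noqa: BLE001 - report with key
                    errors.append(f"init.file: {exc}")

        gdict = dict(raw.get("integration") or {})
        t_end = float(gdict.get("t_end", 2000.0))
        if t_end <= 0:
            errors.append("integration.t_end: must be positive")
        rtol = float(gdict.get("rtol", 1e-8))
        atol = float(gdict.get("atol", 1e-10))
        n_report = int(gdict.get("n_report", 201))
        method = str(gdict.get("method", "LSODA"))

        sweep_parameter = None
        sweep_values = None
        if raw.get("sweep"):
            sdict = dict(raw["sweep"])
            sweep_parameter = sdict.get("parameter")
            sweep_parameter = _PARAM_ALIASES.get(sweep_parameter, sweep_parameter)
            if sweep_parameter not in _PARAM_KEYS:
                errors.append(f"sweep.parameter: must name a rate parameter, got {sweep_parameter!r}")
            sweep_values = list(map(float, sdict.get("values") or []))
            if not sweep_values:
                errors.append("sweep.values: must be a non-empty list")

        abm_n = None
        abm_replicates = 20
        abm_seed = 0
        if raw.get("abm"):
            adict = dict(raw["abm"])
            abm_n = int(adict.get("N", 10000))
            if abm_n < 2:
                errors.append("abm.N: must be at least 2")
            abm_replicates = int(adict.get("replicates", 20))
            abm_seed = int(adict.get("seed", 0))

        population_scale = float(raw.get("population_scale", 1.0))
        if population_scale <= 0:
            errors.append("population_scale: must be positive")

        if errors:
            raise ConfigError(errors)
        return cls(
            params=params,
            dist=dist,
            init_mode=init_mode,
            i0=i0,
            init_state=init_state,
            t_end=t_end,
            rtol=rtol,
            atol=atol,
            n_report=n_report,
            method=method,
            sweep_parameter=sweep_parameter,
            sweep_values=sweep_values,
            abm_n=abm_n,
            abm_replicates=abm_replicates,
            abm_seed=abm_seed,
            population_scale=population_scale,
        )

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def initial_state(self) -> DegreeState:
        if self.init_mode == "explicit":
            if self.init_state is None:
                raise ConfigError(["init: explicit mode without a state"])
            return self.init_state.copy()
        return DegreeState.uniform_seed(self.params, self.dist.degrees.size, self.i0)


@dataclass
class ScenarioBundle:
    """Everything one scenario run produces."""

    config: ScenarioConfig
    r0: float
    trajectory: Trajectory
    dfe: EquilibriumResult
    endemic: Optional[EquilibriumResult]
    stability_dfe: StabilityReport
    stability_endemic: Optional[StabilityReport]
    invariant_report: object
    abm_comparison: Optional[pd.DataFrame] = None

    def aggregates(self) -> pd.DataFrame:
        return aggregate(self.trajectory)


def run_scenario(cfg: ScenarioConfig, skip_stability: bool = False) -> ScenarioBundle:
    """Integrate, solve equilibria, verify stability, optionally run the ABM."""
    r0 = basic_reproduction_number(cfg.params, cfg.dist)
    logger.info("r0=%.6g", r0)
    init = cfg.initial_state()
    traj = integrate(
        cfg.params,
        cfg.dist,
        init,
        cfg.t_end,
        rtol=cfg.rtol,
        atol=cfg.atol,
        n_report=cfg.n_report,
        method=cfg.method,
    )
    logger.info("converged=%s final_derivative_norm=%.3e", traj.converged, traj.final_derivative_norm)
    dfe = disease_free_equilibrium(cfg.params, cfg.dist)
    endemic = solve_endemic(cfg.params, cfg.dist) if r0 > 1 else None
    logger.info("equilibrium_kind=%s", "endemic" if endemic is not None else "disease_free")
    stab_dfe = stab_end = None
    if not skip_stability:
        stab_dfe = dfe_stability(cfg.params, cfg.dist)
        logger.info("dfe_verdict=%s spectral_abscissa=%.6g", stab_dfe.verdict, stab_dfe.spectral_abscissa)
        if endemic is not None:
            stab_end = endemic_stability(cfg.params, cfg.dist)
            logger.info(
                "endemic_verdict=%s spectral_abscissa=%.6g",
                stab_end.verdict,
                stab_end.spectral_abscissa,
            )
    inv = check_invariant_region(traj)
    logger.info(
        "invariant_bound=%.6g max_total=%.6g within_bound_tail=%s",
        inv.bound,
        inv.max_total,
        inv.within_bound_tail,
    )
    abm_cmp = None
    if cfg.abm_n:
        net = build_network(cfg.dist, cfg.abm_n, seed=cfg.abm_seed)
        runs = [
            simulate(
                net,
                cfg.params,
                init_infected_fraction=cfg.i0,
                t_end=cfg.t_end,
                seed=cfg.abm_seed + 1 + rep,
                n_report=min(cfg.n_report, 101),
            )
            for rep in range(cfg.abm_replicates)
        ]
        abm_cmp = compare_to_meanfield(runs, traj)
        logger.info("abm_max_I_error=%.6g", abm_cmp.loc["I", "max_abs_error"])
    return ScenarioBundle(
        config=cfg,
        r0=r0,
        trajectory=traj,
        dfe=dfe,
        endemic=endemic,
        stability_dfe=stab_dfe,
        stability_endemic=stab_end,
        invariant_report=inv,
        abm_comparison=abm_cmp,
    )


def run_sweep(cfg: ScenarioConfig) -> pd.DataFrame:
    """Re-run the scenario for each sweep value; long-format aggregates.

    Columns: sweep_value, t, S, I, Q, R.
    """
    if not cfg.sweep_parameter or not cfg.sweep_values:
        raise ConfigError(["sweep: scenario has no sweep block"])
    frames = []
    for value in cfg.sweep_values:
        sub = dataclasses.replace(
            cfg,
            params=cfg.params.replace(**{cfg.sweep_parameter: value}),
            sweep_parameter=None,
            sweep_values=None,
            abm_n=None,
        )
        bundle = run_scenario(sub, skip_stability=True)
        frame = bundle.aggregates()
        frame.insert(0, "sweep_value", value)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def run_wuhan_case(
    p_values: Sequence[float] = (0.3, 0.32, 0.35),
    gamma_values: Sequence[float] = (0.01, 0.025, 0.04),
    p_for_gamma_sweep: float = 0.2,
    t_end: float = 29.0,
    n_report: int = 59,
    dist: Optional[DegreeDistribution] = None,
    population_scale: float = WUHAN_POPULATION,
) -> pd.DataFrame:
    """Infected counts over the outbreak window for each alertness setting.

    Runs the Wuhan parameter set once per p in ``p_values`` (gamma fixed at
    its base value) and once per gamma in ``gamma_values`` (p fixed at
    ``p_for_gamma_sweep``), starting from S(0) = 1470/1471, I(0) = 1/1471 in
    every degree class.  Densities are scaled to head counts by
    ``population_scale``.  Returns long-format rows
    (sweep, value, t, infected_count).
    """
    if not len(p_values) or not len(gamma_values):
        raise ValueError("p_values and gamma_values must be non-empty")
    if dist is None:
        dist = truncated_power_law(3.0, 500, RENORMALIZED)
    m = dist.degrees.size
    i0 = 1.0 / population_scale
    s0 = (population_scale - 1.0) / population_scale
    init = DegreeState(
        S=np.full(m, s0), I=np.full(m, i0), Q=np.zeros(m), R=np.zeros(m)
    )
    frames = []
    settings = [("p", float(v), {"p": float(v)}) for v in p_values]
    settings += [
        ("gamma", float(v), {"p": p_for_gamma_sweep, "gamma": float(v)})
        for v in gamma_values
    ]
    for sweep_name, value, override in settings:
        params = ModelParameters(**{**WUHAN_PARAMS, "p": 0.0, **override})
        r0 = basic_reproduction_number(params, dist)
        logger.info("wuhan sweep=%s value=%.4g r0=%.6g", sweep_name, value, r0)
        traj = integrate(params, dist, init.copy(), t_end, n_report=n_report)
        agg = aggregate(traj)
        frames.append(
            pd.DataFrame(
                {
                    "sweep": sweep_name,
                    "value": value,
                    "t": agg["t"],
                    "infected_count": agg["I"] * population_scale,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass
class ParameterFixture:
    params: ModelParameters
    r0: float

    def to_dict(self) -> dict:
        return {
            "params": {k: getattr(self.params, k) for k in _PARAM_KEYS},
            "r0": self.r0,
        }


def generate_fixtures(
    seed: int,
    n_sets: int,
    dist: Optional[DegreeDistribution] = None,
    base_rates: Optional[dict] = None,
    r0_low: tuple[float, float] = (0.1, 0.9),
    r0_high: tuple[float, float] = (1.1, 5.0),
) -> list[ParameterFixture]:
    """Deterministic random parameter sets straddling the R0 = 1 threshold.

    Half the sets land in the sub-threshold stratum ``r0_low`` and half in the
    super-threshold stratum ``r0_high``.  p, gamma, delta are drawn uniformly
    and beta is then solved from the (linear) R0 formula so each set hits a
    target R0 drawn uniformly inside its stratum — every emitted set is valid
    and exactly stratified.
    """
    if n_sets < 2:
        raise ValueError("n_sets must be at least 2")
    if dist is None:
        dist = truncated_power_law(3.0, 50, RENORMALIZED)
    rates = dict(BASE_RATES if base_rates is None else base_rates)
    rng = np.random.default_rng(seed)
    n_low = n_sets // 2
    fixtures = []
    for index in range(n_sets):
        lo, hi = r0_low if index < n_low else r0_high
        target_r0 = rng.uniform(lo, hi)
        p = rng.uniform(0.0, 1.0)
        gamma = rng.uniform(0.0, 1.0)
        delta = rng.uniform(0.0, 0.5)
        probe = ModelParameters(beta=1.0, p=p, gamma=gamma, delta=delta, **rates)
        r0_at_unit_beta = basic_reproduction_number(probe, dist)
        beta = target_r0 / r0_at_unit_beta
        params = probe.replace(beta=beta)
        fixtures.append(
            ParameterFixture(params=params, r0=basic_reproduction_number(params, dist))
        )
    return fixtures


def fixtures_to_json(fixtures: list[ParameterFixture], path) -> None:
    with open(path, "w") as fh:
        json.dump([f.to_dict() for f in fixtures], fh, indent=2)


def fixtures_from_json(path) -> list[ParameterFixture]:
    with open(path) as fh:
        raw = json.load(fh)
    return [
        ParameterFixture(params=ModelParameters(**item["params"]), r0=float(item["r0"]))
        for item in raw
    ]
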