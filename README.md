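# siqrs

Degree-based mean-field **SIQRS** epidemics with demography, quarantine and
individual alertness on scale-free contact networks — with exact closed-form
equilibria, spectral stability verification, and an agent-based
configuration-model simulator as an independent finite-N check.

## The model

Consider a static network whose N sites are empty (V) or occupied by one
individual who is susceptible (S), infected (I), quarantined (Q) or
recovered (R). Births fill empty sites with susceptibles at rate b; natural
death (rate d) and removal of infected/quarantined individuals (rate
r = d + α, with α the disease-induced death rate) empty sites again, so the
degree distribution p(k) never changes. A susceptible who notices an
infected neighbour becomes *alert* with probability p and is then infected
per contact at the attenuated rate γβ instead of β, giving the effective
transmission rate β̃ = (1 − p + pγ)β.

Grouping nodes by degree k = 1..M (heterogeneous mean field), the
per-degree densities obey

    dS_k/dt = b(1 − S_k − I_k − Q_k − R_k) − β̃ k S_k θ + μR_k − dS_k
    dI_k/dt = β̃ k S_k θ − (λ + δ + r) I_k
    dQ_k/dt = δ I_k − (r + η) Q_k
    dR_k/dt = λ I_k + η Q_k − (μ + d) R_k

coupled only through θ = Σ_k k p(k) I_k / ⟨k⟩, the probability that a random
edge points at an infected node. δ is the quarantine rate, λ and η the
recovery rates of infected and quarantined individuals, μ the rate of
immunity loss. The basic reproduction number is

    R0 = b β̃ / ((b + d)(λ + δ + r)) · ⟨k²⟩/⟨k⟩ .

Below threshold (R0 < 1) the disease-free state S_k = b/(b+d) is the global
attractor (verified spectrally and with Lyapunov functions along
trajectories); above threshold a unique endemic equilibrium exists, obtained
in closed form from the fixed point θ* of a scalar self-consistency map, and
is locally stable. The package computes all of this and cross-checks the
mean field against an exact event-driven stochastic simulation on
configuration-model networks.

## Worked example

```python
import numpy as np
from siqrs import (truncated_power_law, ModelParameters, basic_reproduction_number,
                   solve_endemic, DegreeState, integrate, aggregate, dfe_stability)

dist = truncated_power_law(3.0, 50)          # p(k) ~ k^-3 on 1..50
params = ModelParameters(b=0.4, d=0.01, r=0.02, beta=0.4, p=0.3, gamma=0.5,
                         delta=0.1, lam=0.02, eta=0.3, mu=0.7)
print(f"R0 = {basic_reproduction_number(params, dist):.4f}")
eq = solve_endemic(params, dist)
print(f"theta* = {eq.theta_star:.4f}")
print(f"endemic prevalence = {float(np.dot(dist.probabilities, eq.state.I)):.4f}")
init = DegreeState.uniform_seed(params, 50, i0=0.01)
traj = integrate(params, dist, init, 2000.0)
print(f"I(t_end) = {aggregate(traj)['I'].iloc[-1]:.4f}")
rep = dfe_stability(params, dist)
print(f"DFE verdict = {rep.verdict}, leading eigenvalue = {rep.spectral_abscissa:.4f}")
```

prints

```
R0 = 6.5595
theta* = 0.4612
endemic prevalence = 0.4266
I(t_end) = 0.4266
DFE verdict = unstable, leading eigenvalue = 0.7783
```

With R0 ≈ 6.6 the disease-free state is unstable (its leading Jacobian
eigenvalue equals (λ+δ+r)(R0−1) ≈ 0.778) and the integrated trajectory
settles exactly at the closed-form endemic prevalence Σ_k p(k) I_k* ≈ 0.427.

A command-line interface wraps the same functions:

```
siqrs r0 --config examples/endemic.yaml
siqrs simulate --config examples/endemic.yaml --out traj.csv
siqrs equilibrium --config examples/endemic.yaml --out eq.csv
siqrs stability --config examples/endemic.yaml --at dfe
siqrs sweep --config examples/quarantine_sweep.yaml --out sweep.csv
siqrs wuhan --out wuhan.csv
```

`siqrs wuhan` runs the early-outbreak case study (29-day window, head-count
scale 1471) showing that infected counts decrease pointwise in the alertness
probability p and increase in the attenuation factor γ.

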