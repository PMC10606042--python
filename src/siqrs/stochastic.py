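"""Agent-based SIQRS simulation on a configuration-model network.

This is the finite-N, quenched-network counterpart of the mean-field system
and serves as its independent check.  Each of the N sites is empty (V) or
holds one individual in state S, I, Q or R; births fill empty sites so the
network topology — and hence the degree distribution — never changes.

Event rates per node:

* V -> S at rate b (birth of a susceptible);
* S -> V at rate d; S -> I at rate (gamma*beta if alert else beta) per
  currently infected neighbour;
* I -> Q at rate delta, I -> R at rate lambda, I -> V at rate r;
* Q -> R at rate eta, Q -> V at rate r;
* R -> S at rate mu, R -> V at rate d.

Quarantined neighbours are non-infectious.  The alertness coin (probability
p) is flipped once whenever a susceptible's infected-neighbour count rises
from zero; the flag persists while that count stays positive and is cleared
when it returns to zero, matching the mean-field picture in which a fraction
p of exposed susceptibles transmit at the attenuated rate gamma*beta.

Sampling is exact and event-driven (Gillespie direct method): per-node total
rates are kept in a Fenwick tree, giving O(log N) draws and updates with no
time-discretisation bias.  All randomness flows through one seeded generator,
so runs are reproducible bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Union

import networkx as nx
import numpy as np
import pandas as pd

from .degree_distribution import DegreeDistribution
from .model_core import ModelParameters, Trajectory, aggregate

__all__ = [
    "ContactNetwork",
    "AbmSeries",
    "build_network",
    "simulate",
    "compare_to_meanfield",
]

# node state codes
_V, _S, _I, _Q, _R = 0, 1, 2, 3, 4
_STATE_NAMES = ("V", "S", "I", "Q", "R")


@dataclass
class ContactNetwork:
    """A simple undirected contact graph with per-node target degrees.

    ``degrees`` are the degrees drawn from the target distribution before
    stub matching; the realised degrees can be slightly lower because
    self-loops and multi-edges are discarded.  Degree classes in the output
    densities refer to the drawn degrees so they align with p(k).
    """

    N: int
    adjacency: list
    degrees: np.ndarray
    seed: int

    @property
    def realized_degrees(self) -> np.ndarray:
        return np.array([len(a) for a in self.adjacency], dtype=np.int64)

    def edge_list(self) -> list[tuple[int, int]]:
        edges = []
        for i, nbrs in enumerate(self.adjacency):
            for j in nbrs:
                if i < j:
                    edges.append((i, j))
        return edges

    def export_edge_list(self, path) -> None:
        """Two-column whitespace-separated edge list with a header comment."""
        with open(path, "w") as fh:
            fh.write(f"# N={self.N} seed={self.seed}\n")
            for i, j in self.edge_list():
                fh.write(f"{i} {j}\n")


def build_network(dist: DegreeDistribution, N: int, seed: int) -> ContactNetwork:
    """Configuration-model network with degrees i.i.d. from ``dist``.

    Degrees are drawn from p(k) (renormalised for sampling if the retained
    mass is below 1); if their sum is odd one degree is resampled.  Stubs are
    paired uniformly at random and self-loops/multi-edges discarded.
    Deterministic for a fixed seed.
    """
    N = int(N)
    if N < 2:
        raise ValueError("N must be at least 2")
    rng = np.random.default_rng(seed)
    probs = dist.probabilities / dist.probabilities.sum()
    degrees = rng.choice(dist.degrees, size=N, p=probs)
    while degrees.sum() % 2:
        degrees[rng.integers(N)] = rng.choice(dist.degrees, p=probs)
    if degrees.sum() == 0:
        raise ValueError("degree sequence sums to zero")
    G = nx.configuration_model(degrees.tolist(), seed=int(rng.integers(2**31)))
    G = nx.Graph(G)  # collapse multi-edges
    G.remove_edges_from(nx.selfloop_edges(G))
    adjacency = [sorted(G.neighbors(i)) for i in range(N)]
    return ContactNetwork(N=N, adjacency=adjacency, degrees=degrees, seed=int(seed))


@dataclass
class AbmSeries:
    """Per-degree-class density time series from one stochastic run."""

    times: np.ndarray
    degree_classes: np.ndarray  # distinct drawn degrees, ascending
    class_sizes: np.ndarray  # node count per class
    densities: dict  # compartment -> array (n_times, n_classes)
    state_counts: np.ndarray  # (n_times, 5) raw counts in V,S,I,Q,R order
    N: int
    seed: int

    def aggregate(self) -> pd.DataFrame:
        """Occupancy fractions of the whole network at each sampled time."""
        out = {"t": self.times}
        for idx, name in enumerate(_STATE_NAMES):
            out[name] = self.state_counts[:, idx] / self.N
        return pd.DataFrame(out)


class _Fenwick:
    """Fenwick (binary indexed) tree over per-node event rates."""

    __slots__ = ("n", "tree")

    def __init__(self, rates):
        n = len(rates)
        tree = [0.0] * (n + 1)
        for i, r in enumerate(rates):
            tree[i + 1] += r
            parent = i + 1 + ((i + 1) & -(i + 1))
            if parent <= n:
                tree[parent] += tree[i + 1]
        self.n = n
        self.tree = tree

    def add(self, i, delta):
        i += 1
        tree = self.tree
        n = self.n
        while i <= n:
            tree[i] += delta
            i += i & -i

    def total(self):
        i = self.n
        tree = self.tree
        s = 0.0
        while i > 0:
            s += tree[i]
            i -= i & -i
        return s

    def find(self, value):
        """Largest index whose prefix sum is <= value; returns the node index."""
        idx = 0
        bitmask = 1 << (self.n.bit_length())
        tree = self.tree
        n = self.n
        while bitmask:
            nxt = idx + bitmask
            if nxt <= n and tree[nxt] <= value:
                idx = nxt
                value -= tree[nxt]
            bitmask >>= 1
        return min(idx, n - 1)


def simulate(
    net: ContactNetwork,
    params: ModelParameters,
    init_infected_fraction: float,
    t_end: float,
    seed: int,
    n_report: int = 101,
) -> AbmSeries:
    """Exact stochastic simulation; densities sampled on an even time grid.

    Starts with round(init_infected_fraction * N) infected nodes chosen
    uniformly (at least one), the rest susceptible, no empty sites.
    """
    if not 0.0 < init_infected_fraction < 1.0:
        raise ValueError("init_infected_fraction must lie in (0, 1)")
    if not t_end > 0:
        raise ValueError("t_end must be positive")
    N = net.N
    rng = np.random.default_rng(seed)

    b, d, r = params.b, params.d, params.r
    beta, gb, p = params.beta, params.gamma * params.beta, params.p
    lam, delta, eta, mu = params.lam, params.delta, params.eta, params.mu
    i_exit = lam + delta + r

    classes, class_of = np.unique(net.degrees, return_inverse=True)
    class_sizes = np.bincount(class_of, minlength=classes.size)
    class_of = class_of.tolist()
    n_classes = classes.size

    adj = [list(a) for a in net.adjacency]
    state = [_S] * N
    n_inf0 = max(1, int(round(init_infected_fraction * N)))
    for i in rng.choice(N, size=n_inf0, replace=False):
        state[int(i)] = _I
    inf_nb = [0] * N
    for i in range(N):
        if state[i] == _I:
            for j in adj[i]:
                inf_nb[j] += 1
    alert = [False] * N
    for i in range(N):
        if state[i] == _S and inf_nb[i] > 0:
            alert[i] = rng.random() < p

    def node_rate(i):
        s = state[i]
        if s == _S:
            return d + inf_nb[i] * (gb if alert[i] else beta)
        if s == _I:
            return i_exit
        if s == _V:
            return b
        if s == _Q:
            return eta + r
        return mu + d  # _R

    rates = [node_rate(i) for i in range(N)]
    fw = _Fenwick(rates)

    counts = np.zeros((5, n_classes), dtype=np.int64)
    for i in range(N):
        counts[state[i], class_of[i]] += 1

    grid = np.linspace(0.0, float(t_end), int(n_report))
    dens = {name: np.zeros((grid.size, n_classes)) for name in _STATE_NAMES[1:]}
    totals = np.zeros((grid.size, 5), dtype=np.int64)

    def record(gi):
        totals[gi] = counts.sum(axis=1)
        for si, name in enumerate(_STATE_NAMES):
            if si == _V:
                continue
            dens[name][gi] = counts[si] / class_sizes

    def set_state(i, new):
        counts[state[i], class_of[i]] -= 1
        counts[new, class_of[i]] += 1
        state[i] = new

    def update_rate(i):
        new = node_rate(i)
        fw.add(i, new - rates[i])
        rates[i] = new

    def enter_infectious(i):
        for j in adj[i]:
            inf_nb[j] += 1
            if state[j] == _S:
                if inf_nb[j] == 1:
                    alert[j] = rng.random() < p
                update_rate(j)

    def leave_infectious(i):
        for j in adj[i]:
            inf_nb[j] -= 1
            if state[j] == _S:
                if inf_nb[j] == 0:
                    alert[j] = False
                update_rate(j)

    def enter_susceptible(i):
        alert[i] = (inf_nb[i] > 0) and (rng.random() < p)

    t = 0.0
    gi = 0
    while gi < grid.size:
        total = fw.total()
        if total <= 0.0:
            while gi < grid.size:
                record(gi)
                gi += 1
            break
        t_next = t + rng.exponential(1.0 / total)
        while gi < grid.size and grid[gi] <= t_next:
            record(gi)
            gi += 1
        if gi >= grid.size:
            break
        i = fw.find(rng.random() * total)
        u = rng.random() * rates[i]
        s = state[i]
        if s == _V:
            set_state(i, _S)
            enter_susceptible(i)
        elif s == _S:
            if u < d:
                set_state(i, _V)
            else:
                set_state(i, _I)
                enter_infectious(i)
        elif s == _I:
            leave_infectious(i)
            if u < lam:
                set_state(i, _R)
            elif u < lam + delta:
                set_state(i, _Q)
            else:
                set_state(i, _V)
        elif s == _Q:
            set_state(i, _R if u < eta else _V)
        else:  # _R
            if u < mu:
                set_state(i, _S)
                enter_susceptible(i)
            else:
                set_state(i, _V)
        update_rate(i)
        t = t_next

    return AbmSeries(
        times=grid,
        degree_classes=classes,
        class_sizes=class_sizes,
        densities=dens,
        state_counts=totals,
        N=N,
        seed=int(seed),
    )


def compare_to_meanfield(
    abm: Union[AbmSeries, Sequence[AbmSeries]],
    mf_trajectory: Trajectory,
) -> pd.DataFrame:
    """Aggregate-density errors between stochastic runs and the mean field.

    The mean-field aggregates are interpolated onto the stochastic time grid.
    Returns one row per compartment with the max and time-averaged absolute
    difference of the replicate-mean series, plus the largest replicate
    standard error (0 for a single run).
    """
    series = [abm] if isinstance(abm, AbmSeries) else list(abm)
    if not series:
        raise ValueError("need at least one stochastic series")
    times = series[0].times
    for s in series[1:]:
        if s.times.shape != times.shape or not np.allclose(s.times, times):
            raise ValueError("replicates must share a common time grid")
    mf = aggregate(mf_trajectory)
    rows = []
    for name in ("S", "I", "Q", "R"):
        reps = np.stack([s.aggregate()[name].to_numpy() for s in series])
        mean = reps.mean(axis=0)
        if reps.shape[0] > 1:
            se = reps.std(axis=0, ddof=1) / math.sqrt(reps.shape[0])
        else:
            se = np.zeros_like(mean)
        mf_interp = np.interp(times, mf["t"].to_numpy(), mf[name].to_numpy())
        err = np.abs(mean - mf_interp)
        rows.append(
            {
                "compartment": name,
                "max_abs_error": float(err.max()),
                "mean_abs_error": float(err.mean()),
                "max_replicate_se": float(se.max()),
            }
        )
    return pd.DataFrame(rows).set_index("compartment")
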