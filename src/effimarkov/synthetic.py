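"""Synthetic ground-truth generators for every pipeline stage.

Three generators endow the pipeline with instances whose answers are known
by construction rather than by running the method under test:

* :func:`gen_dea_panel` builds a DEA panel whose efficient set is exactly a
  chosen set of frontier units: each frontier unit is the strict global
  extreme of one dedicated input or output coordinate (so no convex
  combination of peers can weakly dominate it), and every non-frontier unit
  is a frontier unit with all inputs inflated by a factor > 1 (so it is
  strictly dominated).
* :func:`gen_markov_panel` simulates unit chains from a known row-stochastic
  kernel — or four lag-conditioned kernels on a supplied graph — and emits
  continuous scores drawn strictly inside each state's value band so that
  classification recovers the simulated states exactly.
* :func:`gen_adjacency` builds small connected contiguity graphs (ring,
  grid, random geometric).

All generators are pure functions of their spec: the seed feeds a
``numpy.random.default_rng`` (PCG64) generator, so outputs are reproducible
across runs and platforms. Generators target statistical structure, not the
magnitudes of real yearbook data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .jenks import StateBreaks
from .markov import StatePanel
from .panels import AdjacencyMap, EfficiencyPanel, IndicatorPanel


@dataclass(frozen=True)
class FrontierSpec:
    n_dmu: int = 6
    n_inputs: int = 3
    n_outputs: int = 3
    n_efficient: int = 2
    inefficiency_range: tuple[float, float] = (1.3, 2.0)
    n_years: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_efficient <= self.n_dmu:
            raise ValueError("n_efficient must be in 1..n_dmu")
        if self.n_efficient > self.n_inputs + self.n_outputs:
            raise ValueError(
                "frontier construction needs n_efficient <= n_inputs + n_outputs"
            )
        if self.inefficiency_range[0] < 1:
            raise ValueError("inefficiency factors must be >= 1")


def gen_dea_panel(spec: FrontierSpec) -> tuple[IndicatorPanel, pd.DataFrame]:
    """Generate a DEA panel with a known efficient frontier.

    Returns the panel and a truth table ``unit, efficient, parent, factor``.
    With an inefficiency range of exactly (1, 1) every unit duplicates a
    frontier unit and all units are efficient.
    """
    rng = np.random.default_rng(spec.seed)
    m, q = spec.n_inputs, spec.n_outputs
    units = [f"dmu{i:02d}" for i in range(spec.n_dmu)]
    rows, truth = [], []
    for year in range(2000, 2000 + spec.n_years):
        X = rng.uniform(8.0, 12.0, size=(spec.n_efficient, m))
        Y = rng.uniform(8.0, 12.0, size=(spec.n_efficient, q))
        for f in range(spec.n_efficient):
            # dedicate one coordinate per frontier unit: strict global
            # extreme that no convex combination of the others can match
            if f < q:
                Y[f, f] = rng.uniform(25.0, 30.0)
            else:
                X[f, f - q] = rng.uniform(0.5, 1.0)
        lo, hi = spec.inefficiency_range
        for u, unit in enumerate(units):
            if u < spec.n_efficient:
                x, y = X[u], Y[u]
                parent, factor = unit, 1.0
            else:
                p = int(rng.integers(spec.n_efficient))
                factor = float(rng.uniform(lo, hi))
                x, y = X[p] * factor, Y[p].copy()
                parent = units[p]
            rows.append({"unit": unit, "year": year, "region": "synthetic",
                         **{f"x{i+1}": x[i] for i in range(m)},
                         **{f"y{r+1}": y[r] for r in range(q)}})
            if year == 2000:
                truth.append({"unit": unit, "efficient": factor == 1.0,
                              "parent": parent, "factor": factor})
    return IndicatorPanel(pd.DataFrame(rows)), pd.DataFrame(truth)


@dataclass(frozen=True)
class ChainSpec:
    """Simulation spec for (optionally lag-conditioned) 4-state chains."""

    kernels: np.ndarray | dict[int, np.ndarray]
    n_units: int = 100
    n_years: int = 20
    pi0: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    adjacency: AdjacencyMap | None = None
    band_margin: float = 0.05
    seed: int = 0
    k: int = field(default=4)

    def __post_init__(self) -> None:
        kernels = self.kernels
        mats = kernels.values() if isinstance(kernels, dict) else [kernels]
        for P in mats:
            P = np.asarray(P, float)
            if P.shape != (self.k, self.k) or (P < 0).any() or \
                    not np.allclose(P.sum(axis=1), 1, atol=1e-9):
                raise ValueError("kernels must be row-stochastic k x k matrices")
        if not np.isclose(sum(self.pi0), 1) or any(p < 0 for p in self.pi0):
            raise ValueError("pi0 must lie on the simplex")
        if isinstance(kernels, dict) and self.adjacency is None:
            raise ValueError("lag-conditioned kernels need an adjacency graph")


#: Canonical value bands: state s occupies [s-1, s); scores are drawn inside
#: a margin so neighbor averages never sit exactly on a cut.
def chain_breaks(k: int = 4) -> StateBreaks:
    return StateBreaks(tuple(float(c) for c in range(1, k)))


def gen_markov_panel(spec: ChainSpec
                     ) -> tuple[StatePanel, EfficiencyPanel, StatePanel | None]:
    """Simulate state chains and matching continuous scores.

    Returns ``(states, values, lag_states)``; ``lag_states`` is the panel of
    lag classes actually used to pick kernels (None for the unconditional
    chain). Scores for state s are uniform on
    [s - 1 + margin, s - margin], strictly inside the class band, so
    ``chain_breaks().classify`` recovers the states exactly.
    """
    rng = np.random.default_rng(spec.seed)
    k = spec.k
    conditioned = isinstance(spec.kernels, dict)
    if conditioned:
        units = sorted(spec.adjacency.units)
        kernels = {N: np.asarray(P, float) for N, P in spec.kernels.items()}
        W = spec.adjacency.weights.loc[units, units].to_numpy()
        if spec.adjacency.isolated:
            raise ValueError("lag conditioning requires a graph with no isolates")
    else:
        units = [f"u{i:04d}" for i in range(spec.n_units)]
        kernels = None
        W = None
    n = len(units)
    years = list(range(2000, 2000 + spec.n_years))
    breaks = chain_breaks(k)

    def draw_values(states_row: np.ndarray) -> np.ndarray:
        lo = states_row - 1 + spec.band_margin
        hi = states_row - spec.band_margin
        return rng.uniform(lo, hi)

    states = np.zeros((n, spec.n_years), int)
    values = np.zeros((n, spec.n_years))
    lag_states = np.zeros((n, spec.n_years), int) if conditioned else None
    states[:, 0] = rng.choice(np.arange(1, k + 1), size=n, p=np.asarray(spec.pi0))
    values[:, 0] = draw_values(states[:, 0])
    for t in range(1, spec.n_years):
        if conditioned:
            lag_val = W @ values[:, t - 1]
            lag_cls = breaks.classify(lag_val)
            lag_states[:, t - 1] = lag_cls
            u = rng.random(n)
            for N, P in kernels.items():
                sel = lag_cls == N
                if not sel.any():
                    continue
                cum = P.cumsum(axis=1)
                states[sel, t] = 1 + (
                    u[sel, None] > cum[states[sel, t - 1] - 1]
                ).sum(axis=1)
        else:
            P = np.asarray(spec.kernels, float)
            u = rng.random(n)
            cum = P.cumsum(axis=1)
            states[:, t] = 1 + (u[:, None] > cum[states[:, t - 1] - 1]).sum(axis=1)
        values[:, t] = draw_values(states[:, t])
    if conditioned:  # lag class of the final year (no transition uses it)
        lag_states[:, -1] = breaks.classify(W @ values[:, -1])

    def long(arr, col):
        return pd.DataFrame(
            [{"unit": u, "year": y, col: arr[i, t]}
             for i, u in enumerate(units) for t, y in enumerate(years)]
        )

    sp = StatePanel(long(states, "state"), k=k)
    vals = long(values, "rho")
    vals["region"] = "synthetic"
    ep = EfficiencyPanel(vals)
    lp = StatePanel(long(lag_states, "state"), k=k) if conditioned else None
    return sp, ep, lp


def gen_adjacency(n_units: int, model: str = "ring", seed: int = 0,
                  retry_cap: int = 50) -> AdjacencyMap:
    """Connected synthetic contiguity graph: 'ring', 'grid' or
    'random_geometric' (radius grows until connected, seeded)."""
    if n_units < 2:
        raise ValueError("need at least 2 units")
    names = [f"u{i:04d}" for i in range(n_units)]
    if model == "ring":
        g = nx.cycle_graph(n_units)
    elif model == "grid":
        side = int(np.ceil(np.sqrt(n_units)))
        g = nx.grid_2d_graph(side, side)
        nodes = sorted(g.nodes)[:n_units]
        g = g.subgraph(nodes).copy()
        g = nx.relabel_nodes(g, {n: i for i, n in enumerate(sorted(g.nodes))})
    elif model == "random_geometric":
        rng = np.random.default_rng(seed)
        g = None
        for attempt in range(retry_cap):
            pos = {i: tuple(rng.random(2)) for i in range(n_units)}
            cand = nx.random_geometric_graph(
                n_units, radius=1.5 * np.sqrt(1.0 / n_units), pos=pos)
            if nx.is_connected(cand):
                g = cand
                break
        if g is None:
            raise RuntimeError(
                f"no connected geometric graph in {retry_cap} draws"
            )
    else:
        raise ValueError(f"unknown adjacency model {model!r}")
    g = nx.relabel_nodes(g, dict(enumerate(names)))
    g.remove_edges_from(nx.selfloop_edges(g))
    return AdjacencyMap(g, names)
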