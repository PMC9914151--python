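"""Traditional and spatial-lag-conditioned Markov chain analysis.

Efficiency scores are discretized into k = 4 ordered states (low,
medium-low, medium-high, high) by Fisher-Jenks natural breaks, fitted
either per year (each cross-section classified by its own breaks — the
replication default, which treats states as relative positions within the
year) or once on the pooled panel. One-step transitions between
consecutive years are tabulated into a row-stochastic kernel
P_ij = n_ij / n_i, where n_ij counts moves from state i at t to state j at
t+1 and n_i is the origin-state total.

The spatial variant conditions each transition on the *spatial lag* of the
moving unit in the origin year: the row-standardized neighbor average of
the efficiency score, itself discretized into the same 4 states. This
splits the kernel into four conditional matrices whose counts sum to the
traditional counts.

Long-run prediction iterates pi_{t+1} = pi_t P to its limit. For
irreducible aperiodic kernels the limit is the unique stationary
distribution; for reducible kernels (absorbing or closed classes) it
depends on the start vector and is returned as such.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .jenks import StateBreaks, jenks_breaks
from .panels import AdjacencyMap, EfficiencyPanel

Breaks = StateBreaks | dict[int, StateBreaks]


@dataclass(frozen=True)
class StatePanel:
    """Balanced unit x year panel of 1-based discrete states."""

    data: pd.DataFrame  # columns: unit, year, state
    k: int = 4

    def __post_init__(self) -> None:
        df = self.data[["unit", "year", "state"]].copy()
        df["year"] = df["year"].astype(int)
        df["state"] = df["state"].astype(int)
        if not df["state"].between(1, self.k).all():
            raise ValueError(f"states must lie in 1..{self.k}")
        object.__setattr__(
            self, "data",
            df.sort_values(["unit", "year"], kind="mergesort").reset_index(drop=True),
        )

    @property
    def units(self) -> list[str]:
        return sorted(self.data["unit"].unique())

    @property
    def years(self) -> list[int]:
        return sorted(self.data["year"].unique())

    def pivot(self) -> pd.DataFrame:
        return self.data.pivot(index="unit", columns="year", values="state")


@dataclass
class TransitionMatrix:
    """One-step transition counts and row-normalized probabilities."""

    counts: np.ndarray
    k: int = 4
    probs: np.ndarray = field(init=False)
    origin_totals: np.ndarray = field(init=False)
    undefined_rows: list[int] = field(init=False)

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, float)
        if c.shape != (self.k, self.k) or (c < 0).any():
            raise ValueError(f"counts must be a nonnegative {self.k}x{self.k} matrix")
        self.counts = c.astype(int)
        self.origin_totals = self.counts.sum(axis=1)
        self.probs = np.zeros((self.k, self.k))
        nz = self.origin_totals > 0
        self.probs[nz] = self.counts[nz] / self.origin_totals[nz, None]
        # empty origin rows stay all-zero and are flagged, never renormalized
        self.undefined_rows = [int(i) + 1 for i in np.flatnonzero(~nz)]

    def to_frame(self, decimals: int = 4) -> pd.DataFrame:
        idx = [f"state_{i}" for i in range(1, self.k + 1)]
        return pd.DataFrame(np.round(self.probs, decimals), index=idx, columns=idx)


@dataclass
class SpatialTransitionSet:
    """One conditional TransitionMatrix per spatial-lag state."""

    conditionals: dict[int, TransitionMatrix]
    lag_states: StatePanel

    def total_counts(self) -> np.ndarray:
        return sum(m.counts for m in self.conditionals.values())


def fit_state_breaks(panel: EfficiencyPanel, k: int = 4,
                     pool: str = "per_year") -> Breaks:
    """Fit Fisher-Jenks breaks on the panel's scores.

    ``pool='per_year'`` fits one set of breaks per cross-section (a dict
    keyed by year); ``pool='pooled'`` fits a single set on all unit-years.
    """
    if pool == "pooled":
        return jenks_breaks(panel.data["rho"], k)
    if pool == "per_year":
        return {y: jenks_breaks(panel.values_in(y), k) for y in panel.years}
    raise ValueError("pool must be 'per_year' or 'pooled'")


def classify_states(panel: EfficiencyPanel, breaks: Breaks) -> StatePanel:
    """Discretize every unit-year score under shared or per-year breaks."""
    df = panel.data.copy()
    if isinstance(breaks, StateBreaks):
        df["state"] = breaks.classify(df["rho"])
        k = breaks.k
    else:
        df["state"] = [
            int(breaks[y].classify([r])[0]) for y, r in zip(df["year"], df["rho"])
        ]
        k = next(iter(breaks.values())).k
    return StatePanel(df[["unit", "year", "state"]], k=k)


def transition_matrix(states: StatePanel) -> TransitionMatrix:
    """Tabulate all one-step (t -> t+1) transitions in the panel."""
    years = states.years
    if len(years) < 2:
        raise ValueError("need at least two years to count transitions")
    piv = states.pivot()
    counts = np.zeros((states.k, states.k), int)
    for a, b in zip(years[:-1], years[1:]):
        for i, j in zip(piv[a], piv[b]):
            counts[i - 1, j - 1] += 1
    return TransitionMatrix(counts, k=states.k)


def initial_distribution(states: StatePanel,
                         origin_years: list[int] | None = None) -> np.ndarray:
    """State occupancy shares over the origin-year window.

    Defaults to all years but the last — the window over which transition
    origins are counted.
    """
    if origin_years is None:
        origin_years = states.years[:-1]
    sub = states.data[states.data["year"].isin(origin_years)]
    if sub.empty:
        raise ValueError("empty origin-year window")
    occ = np.bincount(sub["state"], minlength=states.k + 1)[1:]
    return occ / occ.sum()


def transition_type_map(states: StatePanel, start_year: int,
                        end_year: int) -> pd.Series:
    """Label each unit upward / downward / unchanged between two years."""
    piv = states.pivot()
    for y in (start_year, end_year):
        if y not in piv.columns:
            raise KeyError(f"year {y} not in state panel")
    diff = piv[end_year] - piv[start_year]
    return diff.map(lambda d: "upward" if d > 0 else
                    "downward" if d < 0 else "unchanged").rename("transition_type")


def row_standardize(adjacency: AdjacencyMap) -> pd.DataFrame:
    """Row-standardized contiguity weights (equal weight per neighbor)."""
    return adjacency.weights


def spatial_lag_values(panel: EfficiencyPanel,
                       adjacency: AdjacencyMap) -> pd.DataFrame:
    """Neighbor-averaged score of every unit-year (units x years).

    Isolated units (no in-sample neighbor) yield NaN and a warning.
    """
    amap = adjacency.restrict(panel.units)
    w = amap.weights
    piv = panel.pivot().loc[w.index]
    lag = w.to_numpy() @ piv.to_numpy()
    out = pd.DataFrame(lag, index=w.index, columns=piv.columns)
    if amap.isolated:
        warnings.warn(f"isolated units excluded from spatial lag: {amap.isolated}")
        out.loc[amap.isolated] = np.nan
    return out


def spatial_lag_states(panel: EfficiencyPanel, adjacency: AdjacencyMap,
                       breaks: Breaks | None = None, k: int = 4,
                       classification: str = "refit") -> StatePanel:
    """Discretize spatial-lag values into lag states.

    classification='refit' (replication default) fits fresh Fisher-Jenks
    breaks on the lag values themselves (per year when the panel's own
    states use per-year breaks); 'shared' reuses ``breaks`` fitted on the
    own values.
    """
    lag = spatial_lag_values(panel, adjacency)
    if lag.isna().any().any():
        raise ValueError(
            "isolated units have no spatial lag; restrict the panel or "
            "drop them before conditioning"
        )
    long = lag.stack().rename("rho").reset_index()
    long.columns = ["unit", "year", "rho"]
    long["region"] = "n/a"
    lag_panel = EfficiencyPanel(long)
    if classification == "refit":
        pool = "pooled" if isinstance(breaks, StateBreaks) else "per_year"
        breaks = fit_state_breaks(lag_panel, k=k, pool=pool)
    elif classification != "shared":
        raise ValueError("classification must be 'refit' or 'shared'")
    elif breaks is None:
        raise ValueError("classification='shared' requires breaks")
    return classify_states(lag_panel, breaks)


def spatial_transition_set(states: StatePanel,
                           lag_states: StatePanel) -> SpatialTransitionSet:
    """Bin one-step transitions by the origin-year lag state."""
    piv = states.pivot()
    lag_piv = lag_states.pivot().loc[piv.index]
    years = states.years
    k = states.k
    counts = {N: np.zeros((k, k), int) for N in range(1, k + 1)}
    for a, b in zip(years[:-1], years[1:]):
        for i, j, N in zip(piv[a], piv[b], lag_piv[a]):
            counts[N][i - 1, j - 1] += 1
    return SpatialTransitionSet(
        {N: TransitionMatrix(c, k=k) for N, c in counts.items()}, lag_states
    )


def _as_stochastic(P: np.ndarray, renormalize: bool) -> np.ndarray:
    P = np.asarray(P, float)
    if P.ndim != 2 or P.shape[0] != P.shape[1] or (P < 0).any():
        raise ValueError("P must be a square nonnegative matrix")
    sums = P.sum(axis=1)
    if renormalize:
        # tolerate rounded published tables: rescale rows to sum exactly 1
        nz = sums > 0
        P = P.copy()
        P[nz] /= sums[nz, None]
        sums = P.sum(axis=1)
    bad = np.flatnonzero((sums > 0) & (np.abs(sums - 1) > 1e-9))
    if bad.size:
        raise ValueError(f"rows {bad + 1} are not stochastic (sums {sums[bad]})")
    return P


def limiting_distribution(P: np.ndarray, pi0: np.ndarray, tol: float = 1e-12,
                          max_iter: int = 1_000_000, cesaro: bool = False,
                          renormalize_rows: bool = True) -> np.ndarray:
    """Long-run distribution lim pi0 P^n by power iteration.

    Convergence is declared when the L1 change between successive iterates
    falls below ``tol``. For reducible chains the limit depends on ``pi0``
    and is returned as such. Periodic chains do not converge; ``cesaro=True``
    iterates the running Cesaro average instead, which always converges for
    finite chains. Rows of rounded published tables are renormalized to sum
    exactly to 1 (``renormalize_rows``); rows that are identically zero
    (empty origin states) are only acceptable if they receive no mass.
    """
    P = _as_stochastic(P, renormalize_rows)
    pi = np.asarray(pi0, float)
    if pi.ndim != 1 or len(pi) != P.shape[0] or (pi < 0).any():
        raise ValueError("pi0 must be a nonnegative vector matching P")
    if abs(pi.sum() - 1) > 1e-6:
        raise ValueError("pi0 must sum to 1")
    pi = pi / pi.sum()
    empty = P.sum(axis=1) == 0
    if cesaro:
        # Cesaro limit via doubling: M_k = mean of P^j over j < 2^k obeys
        # M_{k+1} = (M_k + P^{2^k} M_k) / 2, which converges geometrically
        # even for periodic chains
        M = np.eye(P.shape[0])
        Q = P.copy()
        for _ in range(200):
            M_next = (M + M @ Q) / 2
            Q = Q @ Q
            if np.abs(pi @ M_next - pi @ M).sum() < tol:
                return pi @ M_next
            M = M_next
        raise RuntimeError("Cesaro averaging did not converge")
    for _ in range(max_iter):
        if (pi[empty] > 1e-15).any():
            raise ValueError(
                "probability mass reached a state with an undefined "
                "(all-zero) transition row; the limit is undefined"
            )
        nxt = pi @ P
        delta = np.abs(nxt - pi).sum()
        pi = nxt
        if delta < tol:
            return pi
    raise RuntimeError(
        f"power iteration did not converge in {max_iter} steps; "
        "the chain may be periodic — retry with cesaro=True"
    )


def stationary_distribution(P: np.ndarray,
                            renormalize_rows: bool = True) -> np.ndarray:
    """Stationary distribution pi = pi P by linear solve.

    Solves the singular system (P' - I) pi = 0 with the normalization
    sum(pi) = 1 via least squares. Unique only for chains with a single
    recurrent class; for reducible chains use
    :func:`limiting_distribution` with an explicit start vector.
    """
    P = _as_stochastic(P, renormalize_rows)
    n = P.shape[0]
    A = np.vstack([P.T - np.eye(n), np.ones(n)])
    b = np.concatenate([np.zeros(n), [1.0]])
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0, None)
    return pi / pi.sum()
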