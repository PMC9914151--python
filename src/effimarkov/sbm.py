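"""Slack-based measure (SBM) DEA with super-efficiency scoring.

The non-oriented SBM of a DMU k against technology ``(X, Y)`` is the
fractional program

    min  rho = (1 - (1/m) sum_i s-_i / x_ki) / (1 + (1/q) sum_r s+_r / y_kr)
    s.t. x_k = X' lam + s-,   y_k = Y' lam - s+,   lam, s-, s+ >= 0,
         sum(lam) = 1 under variable returns to scale (VRS).

rho lies in (0, 1]; rho = 1 exactly when no slack is possible, i.e. the DMU
is on the efficient frontier. Efficient DMUs are then re-scored by the
super-efficiency SBM, which excludes the evaluated DMU from the reference
set and measures the minimal input expansion / output contraction needed to
reach the technology spanned by its peers; super scores are >= 1 and rank
efficient DMUs among themselves.

Both programs are solved exactly as linear programs after the standard
Charnes-Cooper change of variables (multiply all variables by a scale t > 0
chosen to normalize the denominator). ``scipy.optimize.linprog`` (HiGHS)
is the LP engine; it is deterministic and seedless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .panels import EfficiencyPanel, IndicatorPanel

Status = Literal["efficient", "inefficient", "super_infeasible"]


class SolverError(RuntimeError):
    """LP solver did not return an optimal solution."""


@dataclass(frozen=True)
class DEAConfig:
    """Model configuration.

    returns_to_scale
        "vrs" adds the convexity constraint sum(lambda) = 1; "crs" omits it.
    frontier_pool
        "per_year" evaluates each year's cross-section against itself (the
        replication default); "pooled" forms one intertemporal frontier.
    epsilon
        classification tolerance on the optimal slack sum: a DMU is
        efficient when its SBM score exceeds 1 - epsilon.
    """

    returns_to_scale: Literal["vrs", "crs"] = "vrs"
    frontier_pool: Literal["per_year", "pooled"] = "per_year"
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if not 0 < self.epsilon <= 1e-4:
            raise ValueError("epsilon must be in (0, 1e-4]")
        if self.returns_to_scale not in ("vrs", "crs"):
            raise ValueError("returns_to_scale must be 'vrs' or 'crs'")
        if self.frontier_pool not in ("per_year", "pooled"):
            raise ValueError("frontier_pool must be 'per_year' or 'pooled'")


@dataclass
class SBMSolution:
    unit_id: str
    year: int | None
    rho: float
    input_slacks: np.ndarray
    output_slacks: np.ndarray
    lambdas: np.ndarray
    status: Status
    reference_units: list[str] = field(default_factory=list)


_LP_OPTS = {"presolve": True}


def _solve(c, A_eq, b_eq, A_ub=None, b_ub=None, bounds=None):
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=bounds, method="highs", options=_LP_OPTS)
    return res


def sbm_lp(X: np.ndarray, Y: np.ndarray, k: int, *, vrs: bool = True
           ) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Solve the SBM program for row ``k`` of technology ``(X, Y)``.

    Returns ``(rho, input_slacks, output_slacks, lambdas)`` in the original
    (un-scaled) variables.

    Charnes-Cooper linearization: with t > 0 and T = t*lam, S = t*s,
        min  t - (1/m) sum_i S-_i / x_ki
        s.t. t + (1/q) sum_r S+_r / y_kr = 1
             X' T + S- = t x_k,   Y' T - S+ = t y_k,   sum(T) = t  (VRS)
    which is exact for this program class (the denominator is positive).
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    n, m = X.shape
    q = Y.shape[1]
    xk, yk = X[k], Y[k]
    # variables: [t, T (n), S- (m), S+ (q)]
    nv = 1 + n + m + q
    c = np.zeros(nv)
    c[0] = 1.0
    c[1 + n:1 + n + m] = -1.0 / (m * xk)

    rows, rhs = [], []
    r0 = np.zeros(nv)
    r0[0] = 1.0
    r0[1 + n + m:] = 1.0 / (q * yk)
    rows.append(r0)
    rhs.append(1.0)
    for i in range(m):
        r = np.zeros(nv)
        r[0] = -xk[i]
        r[1:1 + n] = X[:, i]
        r[1 + n + i] = 1.0
        rows.append(r)
        rhs.append(0.0)
    for r_ in range(q):
        r = np.zeros(nv)
        r[0] = -yk[r_]
        r[1:1 + n] = Y[:, r_]
        r[1 + n + m + r_] = -1.0
        rows.append(r)
        rhs.append(0.0)
    if vrs:
        r = np.zeros(nv)
        r[0] = -1.0
        r[1:1 + n] = 1.0
        rows.append(r)
        rhs.append(0.0)

    res = _solve(c, np.array(rows), np.array(rhs))
    if res.status != 0:
        raise SolverError(f"SBM LP failed (status {res.status}: {res.message})")
    t = res.x[0]
    if t <= 0:
        raise SolverError("SBM LP returned nonpositive scale t")
    lam = res.x[1:1 + n] / t
    s_in = res.x[1 + n:1 + n + m] / t
    s_out = res.x[1 + n + m:] / t
    return float(res.fun), s_in, s_out, lam


def super_sbm_lp(X: np.ndarray, Y: np.ndarray, k: int, *, vrs: bool = True
                 ) -> tuple[float, np.ndarray, np.ndarray, np.ndarray] | None:
    """Solve the super-efficiency SBM for row ``k``, excluding it from the
    reference set.

    Returns ``(delta, x_target, y_target, lambdas)`` where the targets are
    the projected point on the peer technology, or ``None`` when the
    exclusion program is infeasible (possible for extreme units under VRS).
    ``lambdas`` has length n with a structural zero at position k.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    n, m = X.shape
    q = Y.shape[1]
    xk, yk = X[k], Y[k]
    peers = [j for j in range(n) if j != k]
    if not peers:
        raise ValueError("super-efficiency needs at least one peer DMU")
    Xp, Yp = X[peers], Y[peers]
    p = len(peers)
    # variables: [t, T (p), Xbar (m), Ybar (q)] (all already t-scaled)
    nv = 1 + p + m + q
    c = np.zeros(nv)
    c[1 + p:1 + p + m] = 1.0 / (m * xk)

    eq_rows, eq_rhs = [], []
    r0 = np.zeros(nv)
    r0[1 + p + m:] = 1.0 / (q * yk)
    eq_rows.append(r0)
    eq_rhs.append(1.0)
    if vrs:
        r = np.zeros(nv)
        r[0] = -1.0
        r[1:1 + p] = 1.0
        eq_rows.append(r)
        eq_rhs.append(0.0)

    ub_rows, ub_rhs = [], []
    for i in range(m):  # Xbar_i >= sum_j T_j x_ji
        r = np.zeros(nv)
        r[1:1 + p] = Xp[:, i]
        r[1 + p + i] = -1.0
        ub_rows.append(r)
        ub_rhs.append(0.0)
    for r_ in range(q):  # Ybar_r <= sum_j T_j y_jr
        r = np.zeros(nv)
        r[1:1 + p] = -Yp[:, r_]
        r[1 + p + m + r_] = 1.0
        ub_rows.append(r)
        ub_rhs.append(0.0)
    for i in range(m):  # Xbar_i >= t x_ki
        r = np.zeros(nv)
        r[0] = xk[i]
        r[1 + p + i] = -1.0
        ub_rows.append(r)
        ub_rhs.append(0.0)
    for r_ in range(q):  # Ybar_r <= t y_kr
        r = np.zeros(nv)
        r[0] = -yk[r_]
        r[1 + p + m + r_] = 1.0
        ub_rows.append(r)
        ub_rhs.append(0.0)

    res = _solve(c, np.array(eq_rows), np.array(eq_rhs),
                 A_ub=np.array(ub_rows), b_ub=np.array(ub_rhs))
    if res.status == 2:  # infeasible
        return None
    if res.status != 0:
        raise SolverError(
            f"super-SBM LP failed (status {res.status}: {res.message})"
        )
    t = res.x[0]
    if t <= 0:
        raise SolverError("super-SBM LP returned nonpositive scale t")
    lam = np.zeros(n)
    lam[peers] = res.x[1:1 + p] / t
    xbar = res.x[1 + p:1 + p + m] / t
    ybar = res.x[1 + p + m:] / t
    return float(res.fun), xbar, ybar, lam


def _pool(panel: IndicatorPanel, year: int, config: DEAConfig):
    pool_year = year if config.frontier_pool == "per_year" else None
    X, Y, labels = panel.matrices(pool_year)
    return X, Y, labels, pool_year


def sbm_score(panel: IndicatorPanel, unit: str, year: int,
              config: DEAConfig = DEAConfig()) -> SBMSolution:
    """Score one unit-year by the (non-super) SBM against its frontier pool."""
    X, Y, labels, pool_year = _pool(panel, year, config)
    label = unit if pool_year is not None else f"{unit}@{year}"
    if label not in labels:
        raise KeyError(f"unit {unit!r} (year {year}) not in frontier pool")
    k = labels.index(label)
    rho, s_in, s_out, lam = sbm_lp(X, Y, k, vrs=config.returns_to_scale == "vrs")
    status: Status = "efficient" if rho >= 1 - config.epsilon else "inefficient"
    return SBMSolution(unit, year, rho, s_in, s_out, lam, status,
                       reference_units=[labels[j] for j in np.flatnonzero(lam > 1e-9)])


def super_sbm_score(panel: IndicatorPanel, unit: str, year: int,
                    config: DEAConfig = DEAConfig()) -> SBMSolution:
    """Super-efficiency score of an SBM-efficient unit-year (rho >= 1)."""
    base = sbm_score(panel, unit, year, config)
    if base.status != "efficient":
        raise ValueError(
            f"super-efficiency requires an SBM-efficient unit; "
            f"{unit}@{year} has rho={base.rho:.4f}"
        )
    X, Y, labels, pool_year = _pool(panel, year, config)
    label = unit if pool_year is not None else f"{unit}@{year}"
    k = labels.index(label)
    out = super_sbm_lp(X, Y, k, vrs=config.returns_to_scale == "vrs")
    if out is None:
        return SBMSolution(unit, year, float("nan"),
                           np.zeros(X.shape[1]), np.zeros(Y.shape[1]),
                           np.zeros(X.shape[0]), "super_infeasible")
    delta, xbar, ybar, lam = out
    sol = SBMSolution(unit, year, max(delta, 1.0),
                      np.maximum(xbar - X[k], 0.0),
                      np.maximum(Y[k] - ybar, 0.0), lam, "efficient",
                      reference_units=[labels[j] for j in np.flatnonzero(lam > 1e-9)])
    return sol


def efficiency_table(panel: IndicatorPanel, config: DEAConfig = DEAConfig()
                     ) -> tuple[EfficiencyPanel, pd.DataFrame]:
    """Score every unit-year: SBM if inefficient, else super-efficiency SBM.

    Returns the efficiency panel and a slack/status report. Unit-years whose
    super-efficiency program is infeasible are reported with status
    ``super_infeasible`` and rho = NaN in the report, and are scored 1.0 in
    the panel only if that never occurs (otherwise an error is raised so an
    infeasibility is never silently replaced by a number).
    """
    region = dict(zip(panel.data["unit"], panel.data["region"]))
    rows, report = [], []
    for year in panel.years:
        for unit in panel.units:
            sol = sbm_score(panel, unit, year, config)
            if sol.status == "efficient":
                sol = super_sbm_score(panel, unit, year, config)
            report.append({
                "unit": unit, "year": year, "status": sol.status,
                **{f"s{i+1}-": s for i, s in enumerate(sol.input_slacks)},
                **{f"s{r+1}+": s for r, s in enumerate(sol.output_slacks)},
            })
            if sol.status == "super_infeasible":
                raise SolverError(
                    f"super-efficiency infeasible for {unit}@{year}; "
                    "no score substituted (see slack report)"
                )
            rows.append({"unit": unit, "year": year,
                         "region": region[unit], "rho": sol.rho})
    return EfficiencyPanel(pd.DataFrame(rows)), pd.DataFrame(report)
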