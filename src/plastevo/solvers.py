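"""FBA, MOMA and MOMA-b solvers.

All three problems share the steady-state polytope {v : S v = 0, lb <= v <= ub}.

* FBA maximizes the biomass rate c'v over the polytope (linear program,
  solved with scipy's HiGHS interior-point backend, a barrier-style method).
* MOMA minimizes the squared flux distance ||v - v0||^2 to a reference flux
  v0 (strictly convex quadratic program, solved with OSQP and polishing).
* MOMA-b is MOMA with the additional equality c'v = b pinning the biomass
  rate, typically at the FBA optimum of the same environment.

Solutions are returned as :class:`FluxSolution`; the ``residual`` field
reports max|S v| so callers can check the steady-state invariant against the
global tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import osqp
import scipy.sparse as sp
from scipy.optimize import linprog

from .model import EPS, MetabolicModel

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
ERROR = "error"


class SolverError(RuntimeError):
    """Numerical failure with solver diagnostics attached."""


@dataclass
class FluxSolution:
    """A steady-state flux vector with its objective and diagnostics.

    ``objective`` is the biomass production rate for FBA and MOMA-b, and the
    squared flux distance for MOMA; ``biomass`` always carries the biomass
    rate c'v of the returned vector.
    """

    fluxes: np.ndarray | None
    objective: float | None
    status: str
    residual: float | None
    biomass: float | None = None
    distance: float | None = None  # squared flux distance (MOMA/MOMA-b)

    @property
    def ok(self) -> bool:
        return self.status == OPTIMAL

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "objective": self.objective,
            "biomass": self.biomass,
            "residual": self.residual,
        }


def _residual(model: MetabolicModel, v: np.ndarray) -> float:
    return float(np.abs(model.S @ v).max()) if v.size else 0.0


def _clean(v: np.ndarray) -> np.ndarray:
    """Zero out entries below the global numeric tolerance."""
    v = np.asarray(v, dtype=float).copy()
    v[np.abs(v) < EPS] = 0.0
    return v


def fba(model: MetabolicModel) -> FluxSolution:
    """Maximize biomass production at steady state (linear program)."""
    bounds = list(zip(model.lower, model.upper))
    res = linprog(
        c=-model.objective,
        A_eq=model.S,
        b_eq=np.zeros(model.n_metabolites),
        bounds=bounds,
        method="highs-ipm",
    )
    if res.status == 2:
        return FluxSolution(None, None, INFEASIBLE, None)
    if not res.success:
        raise SolverError(f"FBA failed: {res.message} (status {res.status})")
    v = _clean(res.x)
    biomass = float(model.objective @ v)
    return FluxSolution(v, biomass, OPTIMAL, _residual(model, v), biomass)


def _solve_qp(
    model: MetabolicModel,
    v0: np.ndarray,
    extra_rows: sp.spmatrix | None = None,
    extra_l: np.ndarray | None = None,
    extra_u: np.ndarray | None = None,
) -> FluxSolution:
    n = model.n_reactions
    v0 = np.asarray(v0, dtype=float)
    if v0.shape != (n,):
        raise ValueError(f"v0 has shape {v0.shape}, expected ({n},)")

    P = sp.eye(n, format="csc") * 2.0
    q = -2.0 * v0
    blocks = [sp.csc_matrix(model.S), sp.eye(n, format="csc")]
    l = [np.zeros(model.n_metabolites), model.lower]
    u = [np.zeros(model.n_metabolites), model.upper]
    if extra_rows is not None:
        blocks.append(sp.csc_matrix(extra_rows))
        l.append(np.asarray(extra_l, dtype=float))
        u.append(np.asarray(extra_u, dtype=float))
    A = sp.vstack(blocks, format="csc")

    prob = osqp.OSQP()
    prob.setup(
        P,
        q,
        A,
        np.concatenate(l),
        np.concatenate(u),
        eps_abs=1e-9,
        eps_rel=1e-9,
        eps_prim_inf=1e-8,
        eps_dual_inf=1e-8,
        max_iter=400_000,
        polishing=True,
        verbose=False,
    )
    res = prob.solve(raise_error=False)
    status = res.info.status
    if "infeasible" in status:
        return FluxSolution(None, None, INFEASIBLE, None)
    if status not in ("solved", "solved inaccurate"):
        raise SolverError(f"QP failed: OSQP status {status!r}")
    v = _clean(res.x)
    dist = float(np.sum((v - v0) ** 2))
    biomass = float(model.objective @ v)
    return FluxSolution(v, dist, OPTIMAL, _residual(model, v), biomass, dist)


def moma(model: MetabolicModel, v0: np.ndarray) -> FluxSolution:
    """Minimize ||v - v0||^2 at steady state (MOMA quadratic program).

    The objective is strictly convex, so the optimal flux vector is unique.
    ``objective`` is the squared distance; ``biomass`` the rate c'v.
    """
    return _solve_qp(model, v0)


def moma_b(model: MetabolicModel, v0: np.ndarray, b: float) -> FluxSolution:
    """MOMA with the biomass rate pinned: minimize ||v - v0||^2 s.t. c'v = b.

    Infeasible when *b* exceeds the FBA optimum of the environment.
    """
    row = sp.csc_matrix(model.objective.reshape(1, -1))
    bb = np.array([float(b)])
    sol = _solve_qp(model, v0, extra_rows=row, extra_l=bb, extra_u=bb)
    if sol.ok:
        # like FBA, MOMA-b reports the biomass rate as its headline objective
        sol.objective = sol.biomass
    return sol
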