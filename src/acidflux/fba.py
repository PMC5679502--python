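"""Flux balance LP solving and the two-stage (double) optimisation.

Each simulation step solves the LP ``max c.v  s.t.  S.v = 0, l <= v <= u``
twice: first maximising growth, then — with growth pinned near its optimum —
maximising a secondary objective chosen by a phosphate-limitation test:
phosphate storage while external phosphate supply exceeds growth demand,
external proton production once growth is phosphate-limited.

Two interchangeable backends are provided.  GLPK (via swiglpk) is the
reference configuration; scipy's HiGHS solver is an independent fallback
used in cross-validation tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .network import MetabolicNetwork, Tag

try:  # pragma: no cover - availability probe
    import swiglpk as _glpk

    _HAVE_GLPK = True
except ImportError:  # pragma: no cover
    _HAVE_GLPK = False

__all__ = [
    "FluxSolution",
    "SecondaryObjective",
    "solve_fba",
    "choose_secondary_objective",
    "double_optimize",
    "InfeasibleError",
    "DEFAULT_BACKEND",
]

DEFAULT_BACKEND = "glpk" if _HAVE_GLPK else "scipy"

#: Relative slack when pinning growth in the second optimisation.
GROWTH_SLACK = 1e-6
#: Relative tolerance for the phosphate-limitation boolean.
PIE_TOL = 1e-6
#: Tiny penalty on sugar uptake and acid secretion in the second LP; breaks
#: degenerate alternate optima so trajectories are deterministic and free of
#: spurious secretion.
SECONDARY_EPSILON = 1e-7


class InfeasibleError(RuntimeError):
    """Raised when an LP that must be solvable is infeasible/unbounded."""


class SecondaryObjective:
    PHOSPHATE_STORAGE = "PHOSPHATE_STORAGE"
    PROTON_PRODUCTION = "PROTON_PRODUCTION"


@dataclass
class FluxSolution:
    objective_value: float
    fluxes: dict[str, float]
    status: str  # optimal | infeasible | unbounded
    meta: dict = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def _assemble(
    net: MetabolicNetwork,
    bounds: Mapping[str, tuple[float, float]] | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    lb, ub = net.bounds_arrays()
    rxn_ids = [r.id for r in net.reactions]
    if bounds:
        index = {rid: j for j, rid in enumerate(rxn_ids)}
        for rid, (lo, hi) in bounds.items():
            if rid not in index:
                raise KeyError(f"unknown reaction in bounds: {rid}")
            if lo > hi:
                raise ValueError(f"bounds for {rid}: lower {lo} > upper {hi}")
            lb[index[rid]] = lo
            ub[index[rid]] = hi
    S = net.stoichiometric_matrix()
    return S, lb, ub, rxn_ids


def _objective_vector(
    objective: str | Mapping[str, float], rxn_ids: list[str]
) -> np.ndarray:
    c = np.zeros(len(rxn_ids))
    index = {rid: j for j, rid in enumerate(rxn_ids)}
    if isinstance(objective, str):
        if objective not in index:
            raise KeyError(f"unknown objective reaction {objective}")
        c[index[objective]] = 1.0
    else:
        for rid, coeff in objective.items():
            if rid not in index:
                raise KeyError(f"unknown objective reaction {rid}")
            c[index[rid]] = coeff
    return c


def _solve_glpk(S, lb, ub, c, maximize):  # pragma: no cover - exercised via API
    g = _glpk
    m, n = S.shape
    lp = g.glp_create_prob()
    try:
        g.glp_set_obj_dir(lp, g.GLP_MAX if maximize else g.GLP_MIN)
        if m:
            g.glp_add_rows(lp, m)
            for i in range(m):
                g.glp_set_row_bnds(lp, i + 1, g.GLP_FX, 0.0, 0.0)
        g.glp_add_cols(lp, n)
        for j in range(n):
            lo, hi = float(lb[j]), float(ub[j])
            if lo == hi:
                g.glp_set_col_bnds(lp, j + 1, g.GLP_FX, lo, hi)
            else:
                g.glp_set_col_bnds(lp, j + 1, g.GLP_DB, lo, hi)
            if c[j]:
                g.glp_set_obj_coef(lp, j + 1, float(c[j]))
        rows, cols = np.nonzero(S)
        nnz = len(rows)
        ia = g.intArray(nnz + 1)
        ja = g.intArray(nnz + 1)
        ar = g.doubleArray(nnz + 1)
        for k in range(nnz):
            ia[k + 1] = int(rows[k]) + 1
            ja[k + 1] = int(cols[k]) + 1
            ar[k + 1] = float(S[rows[k], cols[k]])
        g.glp_load_matrix(lp, nnz, ia, ja, ar)
        parm = g.glp_smcp()
        g.glp_init_smcp(parm)
        parm.msg_lev = g.GLP_MSG_OFF
        # default bound tolerance (1e-7) is visible in pool mass balances
        parm.tol_bnd = 1e-10
        parm.tol_dj = 1e-10
        ret = g.glp_simplex(lp, parm)
        status = g.glp_get_status(lp)
        if ret != 0 and status != g.GLP_OPT:
            return None, "infeasible"
        if status == g.GLP_OPT:
            v = np.array([g.glp_get_col_prim(lp, j + 1) for j in range(n)])
            return v, "optimal"
        if status == g.GLP_UNBND:
            return None, "unbounded"
        return None, "infeasible"
    finally:
        g.glp_delete_prob(lp)


def _solve_scipy(S, lb, ub, c, maximize):
    from scipy.optimize import linprog

    sign = -1.0 if maximize else 1.0
    res = linprog(
        sign * c,
        A_eq=S if S.shape[0] else None,
        b_eq=np.zeros(S.shape[0]) if S.shape[0] else None,
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    if res.status == 0:
        return res.x, "optimal"
    if res.status == 3:
        return None, "unbounded"
    return None, "infeasible"


class GlpkProblem:
    """Persistent GLPK problem for hot loops (one instance per run).

    The constraint matrix is loaded once; bounds and the objective are
    rewritten in place each solve and GLPK warm-starts from the previous
    basis.  ``sync_metabolite_row`` re-reads a metabolite's row from the
    network after in-place stoichiometry edits (the per-step rewrite of
    dissociation proton coefficients).
    """

    def __init__(self, net: MetabolicNetwork):
        if not _HAVE_GLPK:
            raise RuntimeError("swiglpk is unavailable")
        g = _glpk
        self.net = net
        self.rxn_ids = [r.id for r in net.reactions]
        self._col = {rid: j + 1 for j, rid in enumerate(self.rxn_ids)}
        self._row = {m.id: i + 1 for i, m in enumerate(net.balanced_metabolites)}
        self._default_lb, self._default_ub = net.bounds_arrays()
        n, m = len(self.rxn_ids), len(self._row)
        self._lp = g.glp_create_prob()
        g.glp_set_obj_dir(self._lp, g.GLP_MAX)
        g.glp_add_rows(self._lp, m)
        for i in range(m):
            g.glp_set_row_bnds(self._lp, i + 1, g.GLP_FX, 0.0, 0.0)
        g.glp_add_cols(self._lp, n)
        S = net.stoichiometric_matrix()
        rows, cols = S.nonzero()
        nnz = len(rows)
        ia, ja, ar = g.intArray(nnz + 1), g.intArray(nnz + 1), g.doubleArray(nnz + 1)
        for k in range(nnz):
            ia[k + 1] = int(rows[k]) + 1
            ja[k + 1] = int(cols[k]) + 1
            ar[k + 1] = float(S[rows[k], cols[k]])
        g.glp_load_matrix(self._lp, nnz, ia, ja, ar)
        self._parm = g.glp_smcp()
        g.glp_init_smcp(self._parm)
        self._parm.msg_lev = g.GLP_MSG_OFF
        self._parm.tol_bnd = 1e-10
        self._parm.tol_dj = 1e-10
        self._obj_cols: set[int] = set()
        self._scratch_ind = g.intArray(n + 1)
        self._scratch_val = g.doubleArray(n + 1)

    def __del__(self):  # pragma: no cover
        try:
            _glpk.glp_delete_prob(self._lp)
        except Exception:
            pass

    def sync_metabolite_row(self, met_id: str) -> None:
        g = _glpk
        i = self._row[met_id]
        count = 0
        for rxn in self.net.reactions:
            coeff = rxn.stoichiometry.get(met_id)
            if coeff:
                count += 1
                self._scratch_ind[count] = self._col[rxn.id]
                self._scratch_val[count] = float(coeff)
        g.glp_set_mat_row(self._lp, i, count, self._scratch_ind, self._scratch_val)

    def solve(
        self,
        bounds: Mapping[str, tuple[float, float]] | None,
        objective: Mapping[str, float],
        maximize: bool = True,
    ) -> FluxSolution:
        g = _glpk
        lp = self._lp
        overrides = bounds or {}
        for j, rid in enumerate(self.rxn_ids):
            lo, hi = overrides.get(
                rid, (self._default_lb[j], self._default_ub[j])
            )
            if lo > hi:
                raise ValueError(f"bounds for {rid}: lower {lo} > upper {hi}")
            kind = g.GLP_FX if lo == hi else g.GLP_DB
            g.glp_set_col_bnds(lp, j + 1, kind, float(lo), float(hi))
        new_cols = {self._col[rid] for rid in objective}
        for j in self._obj_cols - new_cols:
            g.glp_set_obj_coef(lp, j, 0.0)
        for rid, coeff in objective.items():
            g.glp_set_obj_coef(lp, self._col[rid], float(coeff))
        self._obj_cols = new_cols
        g.glp_set_obj_dir(lp, g.GLP_MAX if maximize else g.GLP_MIN)
        ret = g.glp_simplex(lp, self._parm)
        status = g.glp_get_status(lp)
        if ret != 0 and status != g.GLP_OPT:
            # stale basis can trip the warm start; retry cold
            g.glp_std_basis(lp)
            ret = g.glp_simplex(lp, self._parm)
            status = g.glp_get_status(lp)
        if status == g.GLP_OPT:
            fluxes = {
                rid: g.glp_get_col_prim(lp, j + 1)
                for j, rid in enumerate(self.rxn_ids)
            }
            value = sum(coeff * fluxes[rid] for rid, coeff in objective.items())
            return FluxSolution(float(value), fluxes, "optimal")
        if status == g.GLP_UNBND:
            return FluxSolution(float("nan"), {}, "unbounded")
        return FluxSolution(float("nan"), {}, "infeasible")


def solve_fba(
    net: MetabolicNetwork,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    objective: str | Mapping[str, float] = "BIOMASS",
    sense: str = "maximize",
    backend: str | None = None,
) -> FluxSolution:
    """Solve one flux balance LP.

    ``objective`` is a reaction id or a {reaction id: coefficient} mapping;
    ``bounds`` overrides the network's per-reaction bounds for this solve.
    Infeasibility/unboundedness is reported in ``status``, never silently
    zeroed.
    """
    if sense not in ("maximize", "minimize"):
        raise ValueError("sense must be 'maximize' or 'minimize'")
    backend = backend or DEFAULT_BACKEND
    S, lb, ub, rxn_ids = _assemble(net, bounds)
    c = _objective_vector(objective, rxn_ids)
    maximize = sense == "maximize"
    if backend == "glpk":
        if not _HAVE_GLPK:
            raise RuntimeError("GLPK backend requested but swiglpk is unavailable")
        v, status = _solve_glpk(S, lb, ub, c, maximize)
    elif backend == "scipy":
        v, status = _solve_scipy(S, lb, ub, c, maximize)
    else:
        raise ValueError(f"unknown solver backend {backend!r}")
    if status != "optimal":
        return FluxSolution(float("nan"), {}, status)
    return FluxSolution(float(c @ v), dict(zip(rxn_ids, map(float, v))), "optimal")


def choose_secondary_objective(
    sol: FluxSolution,
    pie_constraint: float,
    pie_reaction_id: str = "T_PIE",
    tol: float = PIE_TOL,
) -> str:
    """Phosphate-limitation boolean deciding the second objective.

    Phosphate storage iff the external phosphate flux of the growth solution
    is strictly below its constraint (with relative tolerance ``tol``);
    otherwise the flux sits at its constraint — growth is phosphate-limited —
    and the second objective is proton production.
    """
    if pie_constraint < 0:
        raise ValueError("pie_constraint must be non-negative")
    if pie_reaction_id not in sol.fluxes:
        raise KeyError(f"solution carries no flux for {pie_reaction_id}")
    flux = sol.fluxes[pie_reaction_id]
    if flux < pie_constraint * (1.0 - tol):
        return SecondaryObjective.PHOSPHATE_STORAGE
    return SecondaryObjective.PROTON_PRODUCTION


def _merge_bounds(base, extra):
    out = dict(base) if base else {}
    out.update(extra)
    return out


def double_optimize(
    net: MetabolicNetwork,
    bounds: Mapping[str, tuple[float, float]] | None,
    pie_constraint: float,
    backend: str | None = None,
    delta: float = GROWTH_SLACK,
    epsilon: float = SECONDARY_EPSILON,
    problem: "GlpkProblem | None" = None,
) -> FluxSolution:
    """Growth-first, secondary-objective-second optimisation for one step.

    Step 1 maximises growth with the stored-phosphate *storage* direction
    closed and phosphate sourcing canonicalised to draw external phosphate
    before stored phosphate (ties in the growth LP are otherwise arbitrary).
    Step 2 re-opens storage, pins growth to at least ``mu*(1-delta)`` and
    maximises either net phosphate storage or proton output.  The returned
    solution is the step-2 optimum; ``objective_value`` is the secondary
    flux and ``meta`` records the growth rate and chosen objective.
    """
    biomass_id = net.tagged(Tag.BIOMASS).id
    pie_id = net.tagged(Tag.EXTERNAL_P_IN).id
    pi_rxn = net.tagged(Tag.STORED_P_IN)
    hpe_id = net.tagged(Tag.PROTON_OUT).id

    if problem is not None:
        _solve = lambda bnds, obj: problem.solve(bnds, obj, maximize=True)
    else:
        _solve = lambda bnds, obj: solve_fba(net, bnds, obj, "maximize", backend)

    merged = dict(bounds) if bounds else {}
    pi_lb, pi_ub = merged.get(pi_rxn.id, (pi_rxn.lower_bound, pi_rxn.upper_bound))

    step1_bounds = _merge_bounds(merged, {pi_rxn.id: (max(0.0, pi_lb), pi_ub)})
    sol1 = _solve(step1_bounds, {biomass_id: 1.0})
    if not sol1.optimal:
        raise InfeasibleError(f"growth LP {sol1.status}")
    mu = sol1.objective_value

    # canonical phosphate sourcing: external phosphate first
    pie_ub = merged.get(pie_id, None)
    pie_bound = pie_ub[1] if pie_ub else net.reaction(pie_id).upper_bound
    total_p_in = sol1.fluxes[pie_id] + max(0.0, sol1.fluxes[pi_rxn.id])
    canon = dict(sol1.fluxes)
    canon[pie_id] = min(pie_bound, total_p_in)
    canon[pi_rxn.id] = total_p_in - canon[pie_id]
    sol1_canon = FluxSolution(mu, canon, "optimal")

    secondary = choose_secondary_objective(sol1_canon, pie_bound, pie_id)

    # tiny penalties kill degenerate spurious fluxes (uptake and secretion)
    penalty: dict[str, float] = {}
    for rxn in net.reactions:
        if rxn.tag in (Tag.GLUCOSE_EX, Tag.XYLOSE_EX, Tag.ACID_SECRETION):
            penalty[rxn.id] = -epsilon
    if secondary == SecondaryObjective.PHOSPHATE_STORAGE:
        objective = {pi_rxn.id: -1.0, **penalty}
        secondary_id = pi_rxn.id
    else:
        objective = {hpe_id: 1.0, **penalty}
        secondary_id = hpe_id

    for slack in (delta, max(delta, 1e-4)):
        step2_bounds = _merge_bounds(
            merged,
            {
                pi_rxn.id: (pi_lb, pi_ub),
                biomass_id: (mu * (1.0 - slack), _upper(merged, net, biomass_id)),
            },
        )
        sol2 = _solve(step2_bounds, objective)
        if sol2.optimal:
            secondary_value = (
                -sol2.fluxes[secondary_id]
                if secondary == SecondaryObjective.PHOSPHATE_STORAGE
                else sol2.fluxes[secondary_id]
            )
            sol2.objective_value = float(secondary_value)
            sol2.meta = {
                "secondary": secondary,
                "growth_rate": sol2.fluxes[biomass_id],
                "mu_max": mu,
                "pie_constraint": pie_bound,
                "pie_flux_step1": sol1_canon.fluxes[pie_id],
            }
            return sol2
    raise InfeasibleError(
        f"secondary LP infeasible after growth fixing (mu={mu}, {secondary})"
    )


def _upper(bounds, net, rxn_id):
    if rxn_id in bounds:
        return bounds[rxn_id][1]
    return net.reaction(rxn_id).upper_bound
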