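"""Flux-balance analysis with molecular crowding (FBAwMC).

The LP solved here is the core of the whole simulator::

    maximize   f_objective                 (ATP hydrolysis rate)
    subject to S·f = 0                     (steady state)
               lb <= f <= ub               (irreversible bounds, uptake caps)
               sum_i a_i f_i <= V_prot     (molecular crowding)

where ``a_i`` is the crowding coefficient of reaction i (enzyme volume
fraction needed per unit flux) and ``V_prot`` the volume fraction of the cell
available for metabolic enzymes.  With ``V_prot = None`` (or infinity) the
crowding row is dropped and the problem reduces to standard FBA.

The growth rate is derived from the ATP production rate (mu = ATP/27.2, the
ATP coefficient of the source model's biomass equation) and optionally capped
by an empirical rate-yield trade-off (mu_max as a function of the carbon
uptake rate in glucose equivalents).

GLPK (via swiglpk) is used as the LP engine with one persistent problem per
network structure; only bounds, the crowding row and the objective are
rewritten between solves, which makes the evolutionary simulations tractable
(tens of microseconds per solve).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional

import numpy as np
import swiglpk as glp

from .network import MetabolicNetwork

_INF = float("inf")


class SolverError(RuntimeError):
    """LP solver failure (reports the GLPK status)."""


@dataclass
class SolverConfig:
    """Configuration of the FBAwMC solve and the growth conversion.

    Parameters
    ----------
    V_prot
        Enzyme volume fraction budget (0..1); ``None`` disables the crowding
        constraint (standard FBA).
    secondary_objective
        ``"min_total_flux"``: lexicographic two-phase solve returning, among
        ATP optima, the flux vector of minimal total flux (deterministic
        exchange fluxes).  ``"penalty"``: single-phase approximation
        maximizing ATP - penalty_eps * sum(f).  ``"none"``: plain solve.
    tradeoff
        ``"saturating"`` applies the empirical rate-yield cap in
        :func:`apply_rate_yield_cap`; ``"off"`` disables it.
    tradeoff_form
        ``"yield"``: mu_max = G_up/(alpha*G_up + beta) (the empirical yield
        curve); ``"intext"``: mu_max = 1/(alpha*G_up).
    """

    V_prot: Optional[float] = 0.2
    lp_tolerance: float = 1e-9
    secondary_objective: str = "min_total_flux"
    penalty_eps: float = 1e-6
    tradeoff: str = "saturating"
    tradeoff_form: str = "yield"
    alpha: float = 3.9
    beta: float = 2.8
    include_exchange_in_crowding: bool = False

    def __post_init__(self) -> None:
        if self.V_prot is not None and not (0.0 <= self.V_prot):
            raise ValueError("V_prot must be >= 0")
        if self.secondary_objective not in ("none", "min_total_flux", "penalty"):
            raise ValueError(f"unknown secondary objective {self.secondary_objective!r}")
        if self.tradeoff not in ("off", "saturating"):
            raise ValueError(f"unknown tradeoff mode {self.tradeoff!r}")
        if self.tradeoff_form not in ("yield", "intext"):
            raise ValueError(f"unknown tradeoff form {self.tradeoff_form!r}")


#: ATP coefficient of the source biomass equation; mu = ATP rate / 27.2
ATP_PER_BIOMASS = 27.2


@dataclass
class FluxSolution:
    """Result of one FBAwMC solve.

    ``exchange_fluxes`` maps extracellular metabolite -> net flux with the
    community convention: uptake < 0, excretion > 0 (mmol·gDW^-1·h^-1).
    """

    fluxes: np.ndarray
    exchange_fluxes: Dict[str, float]
    atp_rate: float
    growth_rate: float
    status: str
    reaction_ids: tuple = field(default=(), repr=False)

    @property
    def uptake(self) -> Dict[str, float]:
        return {m: -f for m, f in self.exchange_fluxes.items() if f < 0}

    @property
    def excretion(self) -> Dict[str, float]:
        return {m: f for m, f in self.exchange_fluxes.items() if f > 0}

    def flux(self, reaction_id: str) -> float:
        return float(self.fluxes[self.reaction_ids.index(reaction_id)])


# ---------------------------------------------------------------------------
# persistent GLPK problem per network structure
# ---------------------------------------------------------------------------

class _GlpkProblem:
    """GLPK problem for a fixed stoichiometry; bounds/crowding/objective are
    rewritten before every solve."""

    def __init__(self, S: np.ndarray) -> None:
        n_m, n_r = S.shape
        self.n_m, self.n_r = n_m, n_r
        lp = glp.glp_create_prob()
        glp.glp_add_rows(lp, n_m + 1)  # +1: crowding row
        for i in range(1, n_m + 1):
            glp.glp_set_row_bnds(lp, i, glp.GLP_FX, 0.0, 0.0)
        glp.glp_set_row_bnds(lp, n_m + 1, glp.GLP_FR, 0.0, 0.0)
        glp.glp_add_cols(lp, n_r)
        nnz = int(np.count_nonzero(S))
        ia = glp.intArray(nnz + 1)
        ja = glp.intArray(nnz + 1)
        ar = glp.doubleArray(nnz + 1)
        k = 0
        rows, cols = np.nonzero(S)
        for i, j in zip(rows, cols):
            k += 1
            ia[k], ja[k], ar[k] = int(i) + 1, int(j) + 1, float(S[i, j])
        glp.glp_load_matrix(lp, k, ia, ja, ar)
        self.lp = lp
        self._ind = glp.intArray(n_r + 1)
        self._val = glp.doubleArray(n_r + 1)
        self.parm = glp.glp_smcp()
        glp.glp_init_smcp(self.parm)
        self.parm.msg_lev = glp.GLP_MSG_OFF

    def __del__(self) -> None:  # pragma: no cover - interpreter teardown
        try:
            glp.glp_delete_prob(self.lp)
        except Exception:
            pass

    def set_col_bounds(self, lb: np.ndarray, ub: np.ndarray) -> None:
        lp = self.lp
        for j in range(self.n_r):
            lo, hi = float(lb[j]), float(ub[j])
            if hi < lo:
                raise ValueError(f"inconsistent bounds on column {j}: {lo} > {hi}")
            if lo == hi:
                glp.glp_set_col_bnds(lp, j + 1, glp.GLP_FX, lo, hi)
            else:
                glp.glp_set_col_bnds(lp, j + 1, glp.GLP_DB, lo, hi)

    def set_crowding(self, coeffs: np.ndarray, v_prot: Optional[float]) -> None:
        lp = self.lp
        row = self.n_m + 1
        if v_prot is None or math.isinf(v_prot):
            glp.glp_set_mat_row(lp, row, 0, self._ind, self._val)
            glp.glp_set_row_bnds(lp, row, glp.GLP_FR, 0.0, 0.0)
            return
        k = 0
        for j in np.nonzero(coeffs)[0]:
            k += 1
            self._ind[k] = int(j) + 1
            self._val[k] = float(coeffs[j])
        glp.glp_set_mat_row(lp, row, k, self._ind, self._val)
        glp.glp_set_row_bnds(lp, row, glp.GLP_UP, 0.0, float(v_prot))

    def set_objective(self, coeffs: np.ndarray, maximize: bool) -> None:
        lp = self.lp
        glp.glp_set_obj_dir(lp, glp.GLP_MAX if maximize else glp.GLP_MIN)
        for j in range(self.n_r):
            glp.glp_set_obj_coef(lp, j + 1, float(coeffs[j]))

    def solve(self) -> None:
        # start from the standard basis so that identical inputs give
        # bit-identical solutions regardless of solve history
        glp.glp_std_basis(self.lp)
        ret = glp.glp_simplex(self.lp, self.parm)
        status = glp.glp_get_status(self.lp)
        if ret != 0 or status != glp.GLP_OPT:
            names = {glp.GLP_INFEAS: "infeasible", glp.GLP_NOFEAS: "no feasible solution",
                     glp.GLP_UNBND: "unbounded", glp.GLP_UNDEF: "undefined"}
            raise SolverError(f"GLPK failed: ret={ret}, "
                              f"status={names.get(status, status)}")

    def get_fluxes(self) -> np.ndarray:
        return np.array([glp.glp_get_col_prim(self.lp, j + 1)
                         for j in range(self.n_r)])


def _problem_for(net: MetabolicNetwork) -> _GlpkProblem:
    if net.structure.lp is None:
        net.structure.lp = _GlpkProblem(net.structure.S)
    return net.structure.lp


# ---------------------------------------------------------------------------
# solver front end
# ---------------------------------------------------------------------------

def effective_upper_bounds(
    net: MetabolicNetwork, uptake_caps: Mapping[str, float]
) -> np.ndarray:
    """Upper bounds with per-metabolite uptake caps applied to the uptake
    direction of each exchange pair.  Metabolites absent from the map are
    capped at zero (no supply); freely available inorganics are uncapped."""
    ub = net.ub.copy()
    for met_id, cols in net.structure.uptake_cols.items():
        if met_id in net.freely_available:
            continue
        cap = float(uptake_caps.get(met_id, 0.0))
        if cap < 0:
            raise ValueError(f"negative uptake cap for {met_id}")
        for j in cols:
            ub[j] = min(ub[j], cap)
    return ub


def solve_fbawmc(
    net: MetabolicNetwork,
    uptake_caps: Mapping[str, float],
    cfg: Optional[SolverConfig] = None,
) -> FluxSolution:
    """Solve the crowding-constrained FBA problem for one metabacterium.

    ``net`` must be irreversible (run :func:`gutflux.network.split_reversible`
    first).  ``uptake_caps`` maps extracellular metabolite id to the maximum
    uptake flux granted by the environment.
    """
    cfg = cfg or SolverConfig()
    if not net.is_irreversible():
        raise ValueError("network must be split to irreversible reactions first")
    if np.any(net.lb > net.ub):
        bad = int(np.argmax(net.lb > net.ub))
        raise ValueError(f"inconsistent bounds on reaction "
                         f"{net.reactions[bad].id!r}: lb > ub")
    prob = _problem_for(net)
    ub = effective_upper_bounds(net, uptake_caps)
    prob.set_col_bounds(net.lb, ub)

    crowd = net.crowding.copy()
    if not cfg.include_exchange_in_crowding:
        crowd[net.structure.exchange_mask] = 0.0
    prob.set_crowding(crowd, cfg.V_prot)

    n_r = net.n_reactions
    obj_idx = net.objective_index
    obj = np.zeros(n_r)
    obj[obj_idx] = 1.0
    if cfg.secondary_objective == "penalty":
        obj -= cfg.penalty_eps
        obj[obj_idx] = 1.0 - cfg.penalty_eps
    prob.set_objective(obj, maximize=True)
    prob.solve()
    fluxes = prob.get_fluxes()
    atp = float(fluxes[obj_idx])

    if cfg.secondary_objective == "min_total_flux" and atp > cfg.lp_tolerance:
        # phase 2: among ATP optima, minimize total flux.  The objective is a
        # single column, so fixing the optimum is a bound change.
        saved_lb = net.lb[obj_idx]
        lb2 = net.lb.copy()
        lb2[obj_idx] = atp * (1.0 - 1e-9)
        prob.set_col_bounds(lb2, ub)
        prob.set_objective(np.ones(n_r), maximize=False)
        prob.solve()
        fluxes = prob.get_fluxes()
        atp = float(fluxes[obj_idx])
        del saved_lb

    exchange: Dict[str, float] = {}
    st = net.structure
    ext_ids = set(st.uptake_cols) | set(st.excretion_cols)
    for met_id in ext_ids:
        out = sum(fluxes[j] for j in st.excretion_cols.get(met_id, ()))
        inn = sum(fluxes[j] for j in st.uptake_cols.get(met_id, ()))
        exchange[met_id] = float(out - inn)

    atp = max(atp, 0.0)
    status = "zero" if atp <= cfg.lp_tolerance * 10 else "optimal"
    if status == "zero":
        atp = 0.0
    return FluxSolution(
        fluxes=fluxes,
        exchange_fluxes=exchange,
        atp_rate=atp,
        growth_rate=growth_from_atp(atp),
        status=status,
        reaction_ids=tuple(r.id for r in net.reactions),
    )


# ---------------------------------------------------------------------------
# growth conversion and rate-yield trade-off
# ---------------------------------------------------------------------------

def growth_from_atp(atp_rate: float) -> float:
    """Growth rate (h^-1) from the ATP production rate: mu = ATP / 27.2."""
    if atp_rate < 0:
        raise ValueError("ATP production rate must be >= 0")
    return atp_rate / ATP_PER_BIOMASS


def carbon_uptake_rate(net: MetabolicNetwork, sol: FluxSolution) -> float:
    """Total carbon uptake (mmol C·gDW^-1·h^-1): sum of uptake flux times
    carbon count over uptaken metabolites (unknown carbon counts as zero)."""
    total = 0.0
    for met_id, up in sol.uptake.items():
        cc = net.metabolites[net.met_index[met_id]].carbon_count
        if cc:
            total += cc * up
    return total


def apply_rate_yield_cap(
    mu: float, carbon_uptake: float, cfg: Optional[SolverConfig] = None
) -> float:
    """Cap the growth rate by the empirical rate-yield trade-off.

    The carbon uptake rate is converted to glucose equivalents,
    G_up = carbon_uptake/6, and the maximal allowed growth rate is
    mu_max = G_up/(alpha*G_up + beta) (the empirical maximum-yield curve
    1/(alpha*G_up + beta) times the uptake rate), defaults alpha=3.9,
    beta=2.8.  Returns min(mu, mu_max); the asymptotic maximum is
    1/alpha ~ 0.256 h^-1.
    """
    cfg = cfg or SolverConfig()
    if mu < 0 or carbon_uptake < 0:
        raise ValueError("growth and carbon uptake rates must be >= 0")
    if cfg.tradeoff == "off":
        return mu
    g_up = carbon_uptake / 6.0
    if cfg.tradeoff_form == "yield":
        mu_max = g_up / (cfg.alpha * g_up + cfg.beta) if g_up > 0 else 0.0
    else:  # "intext" variant
        mu_max = _INF if g_up == 0 else 1.0 / (cfg.alpha * g_up)
    return min(mu, mu_max)


def capped_growth_rate(
    net: MetabolicNetwork, sol: FluxSolution, cfg: Optional[SolverConfig] = None
) -> float:
    """Convenience: growth rate of a solution after the rate-yield cap."""
    return apply_rate_yield_cap(sol.growth_rate, carbon_uptake_rate(net, sol), cfg)


# ---------------------------------------------------------------------------
# uptake caps
# ---------------------------------------------------------------------------

def uptake_caps_wellmixed(
    concentrations: Mapping[str, float], total_biomass: float, dt: float
) -> Dict[str, float]:
    """Per-metabolite maximum uptake flux in a well-mixed medium:
    cap_j = c_j / (dt * total_biomass), so that the community cannot take up
    more than is present within one Euler step."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if total_biomass < 0:
        raise ValueError("total biomass must be >= 0")
    if total_biomass == 0:
        return {m: 0.0 for m in concentrations}
    return {m: max(float(c), 0.0) / (dt * total_biomass)
            for m, c in concentrations.items()}


def uptake_caps_spatial(
    c_i: float, V1: float, V2: float, dt: float, dens_max: float
) -> float:
    """Shared per-gDW uptake cap for the (at most two) cells on one patch:
    cap = 4 c_i / (dt * DENS_MAX * (V1 + V2))."""
    if V1 + V2 <= 0:
        raise ValueError("uptake cap undefined on an empty patch (V1+V2 must be > 0)")
    if dt <= 0 or dens_max <= 0:
        raise ValueError("dt and DENS_MAX must be > 0")
    return 4.0 * max(c_i, 0.0) / (dt * dens_max * (V1 + V2))
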