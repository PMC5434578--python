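"""Well-mixed dynamic multi-species metabolic model (DMMM).

N metabacteria share one medium.  Each Euler step of length ``dt`` (default
0.1 h):

1. per-metabolite uptake caps  cap_j = c_j / (dt * sum_i B_i)  guarantee the
   community cannot overdraw the medium;
2. every member is solved with FBAwMC, yielding exchange fluxes F_ij and a
   growth rate mu_i = ATP_i / 27.2;
3. concentrations update as  c_j += dt * sum_i F_ij B_i  and biomasses as
   B_i += mu_i B_i dt;
4. cumulative per-member mole ledgers (uptake / excretion per metabolite, in
   mmol per litre of medium) are accumulated as left-Riemann sums — these
   feed the cross-feeding statistics.

The run stops when the total growth flux sum_i mu_i B_i falls below a
threshold ("the metabacteria have stopped growing") or at ``max_time``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .fbawmc import SolverConfig, solve_fbawmc, uptake_caps_wellmixed
from .network import CrowdingSampler, MetabolicNetwork, sample_crowding


def default_wellmixed_config() -> SolverConfig:
    """Well-mixed runs use the plain FBAwMC growth rate; the empirical
    rate-yield cap belongs to the evolutionary (spatial) model."""
    return SolverConfig(tradeoff="off")


@dataclass
class Member:
    net: MetabolicNetwork
    biomass: float  # gDW / l
    growth_rate: float = 0.0


@dataclass
class CommunityState:
    """Shared medium plus the member metabacteria and their mole ledgers."""

    time: float
    concentrations: Dict[str, float]  # mM
    members: List[Member]
    ext_ids: List[str]
    # cumulative mmol/l taken up / excreted, shape (n_members, n_ext)
    ledger_uptake: np.ndarray
    ledger_excretion: np.ndarray

    @property
    def total_biomass(self) -> float:
        return float(sum(m.biomass for m in self.members))

    @property
    def total_growth_flux(self) -> float:
        """sum_i mu_i B_i (h^-1 · gDW/l); the stopping criterion."""
        return float(sum(m.growth_rate * m.biomass for m in self.members))

    def excreted_species(self, threshold: float = 1e-9) -> set:
        """Metabolites with community-wide cumulative excretion above
        ``threshold`` mmol/l (gross excretion; freely-available inorganics
        are not counted as fermentation products)."""
        free = self.members[0].net.freely_available if self.members else set()
        totals = self.ledger_excretion.sum(axis=0)
        return {m for m, t in zip(self.ext_ids, totals)
                if t > threshold and m not in free}

    def ledger_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(len(self.members)):
            for j, met in enumerate(self.ext_ids):
                rows.append({
                    "member": i, "metabolite": met,
                    "uptake": self.ledger_uptake[i, j],
                    "excretion": self.ledger_excretion[i, j],
                })
        return pd.DataFrame(rows)


def init_community(
    base_net: MetabolicNetwork,
    n: int = 1000,
    total_biomass: float = 0.01,
    glucose_mM: float = 1.0,
    sampler: Optional[CrowdingSampler] = None,
    rng: Optional[np.random.Generator] = None,
    glucose_id: str = "glc",
) -> CommunityState:
    """Community of ``n`` members, biomass divided equally, glucose-only
    medium (inorganics are implicit: unlimited influx in the solver)."""
    if n < 1:
        raise ValueError("need at least one member")
    if not base_net.is_irreversible():
        raise ValueError("base network must be split to irreversible reactions")
    sampler = sampler or CrowdingSampler()
    rng = rng if rng is not None else np.random.default_rng(sampler.seed)
    ext_ids = sorted(set(base_net.structure.uptake_cols)
                     | set(base_net.structure.excretion_cols))
    if glucose_id not in ext_ids:
        raise ValueError(f"{glucose_id!r} is not an exchangeable metabolite")
    members = [Member(sample_crowding(base_net, sampler, rng), total_biomass / n)
               for _ in range(n)]
    conc = {m: 0.0 for m in ext_ids}
    conc[glucose_id] = glucose_mM
    return CommunityState(
        time=0.0, concentrations=conc, members=members, ext_ids=ext_ids,
        ledger_uptake=np.zeros((n, len(ext_ids))),
        ledger_excretion=np.zeros((n, len(ext_ids))),
    )


def step(state: CommunityState, dt: float = 0.1,
         cfg: Optional[SolverConfig] = None) -> CommunityState:
    """One forward-Euler step; caps are computed once from start-of-step
    concentrations for all members (simultaneous update).  Mutates and
    returns ``state``."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    cfg = cfg or default_wellmixed_config()
    idx = {m: j for j, m in enumerate(state.ext_ids)}
    caps = uptake_caps_wellmixed(state.concentrations, state.total_biomass, dt)
    delta = np.zeros(len(state.ext_ids))
    for i, member in enumerate(state.members):
        sol = solve_fbawmc(member.net, caps, cfg)
        member.growth_rate = sol.growth_rate
        for met, f in sol.exchange_fluxes.items():
            j = idx[met]
            delta[j] += f * member.biomass
            if f < 0:
                state.ledger_uptake[i, j] += -f * member.biomass * dt
            elif f > 0:
                state.ledger_excretion[i, j] += f * member.biomass * dt
    tol = max(cfg.lp_tolerance * 1e3, 1e-9)
    free = state.members[0].net.freely_available if state.members else set()
    for met, j in idx.items():
        if met in free:
            continue  # externally buffered (unlimited influx): pinned
        c = state.concentrations[met] + dt * delta[j]
        if c < -tol * max(1.0, abs(state.concentrations[met])):
            raise RuntimeError(
                f"concentration of {met} went negative ({c:.3e}); "
                "uptake caps violated — reduce the step size")
        state.concentrations[met] = max(c, 0.0)
    for member in state.members:
        member.biomass += member.growth_rate * member.biomass * dt
    state.time += dt
    return state


@dataclass
class Trajectory:
    """Sampled trajectory of a well-mixed run."""

    times: List[float] = field(default_factory=list)
    concentrations: List[Dict[str, float]] = field(default_factory=list)
    biomasses: List[np.ndarray] = field(default_factory=list)
    growth_rates: List[np.ndarray] = field(default_factory=list)
    final_state: Optional[CommunityState] = None

    def record(self, state: CommunityState) -> None:
        self.times.append(state.time)
        self.concentrations.append(dict(state.concentrations))
        self.biomasses.append(np.array([m.biomass for m in state.members]))
        self.growth_rates.append(np.array([m.growth_rate for m in state.members]))

    def concentration_frame(self) -> pd.DataFrame:
        rows = [{"time": t, "metabolite": met, "concentration": c}
                for t, conc in zip(self.times, self.concentrations)
                for met, c in conc.items()]
        return pd.DataFrame(rows)

    def biomass_frame(self) -> pd.DataFrame:
        rows = []
        for t, bs, mus in zip(self.times, self.biomasses, self.growth_rates):
            for i, (b, mu) in enumerate(zip(bs, mus)):
                rows.append({"time": t, "member": i, "biomass": b,
                             "growth_rate": mu})
        return pd.DataFrame(rows)

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.concentration_frame().to_csv(outdir / "concentrations.csv", index=False)
        self.biomass_frame().to_csv(outdir / "biomass.csv", index=False)
        if self.final_state is not None:
            self.final_state.ledger_frame().to_csv(outdir / "ledger.csv", index=False)


def run(
    state: CommunityState,
    dt: float = 0.1,
    cfg: Optional[SolverConfig] = None,
    eps_growth: float = 1e-6,
    max_time: float = 48.0,
    record_every: int = 1,
) -> Trajectory:
    """Iterate :func:`step` until total growth flux < ``eps_growth`` or
    ``max_time`` is reached; returns the sampled trajectory."""
    cfg = cfg or default_wellmixed_config()
    traj = Trajectory()
    traj.record(state)
    n = 0
    while state.time < max_time - 1e-12:
        step(state, dt, cfg)
        n += 1
        if n % record_every == 0:
            traj.record(state)
        if state.total_growth_flux < eps_growth:
            break
    if traj.times[-1] != state.time:
        traj.record(state)
    traj.final_state = state
    return traj
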