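"""Spatially explicit, evolutionary gut-tube model.

The colon is a 2-D lattice (default 150 columns x 10 rows of 1 cm patches)
with two cell "slots" per patch.  Each time step (default 3 min), in this
fixed order:

1. **meals** — every TIME_FOOD hours a glucose pulse ~Normal(FOOD_IN, 20%)
   mmol (truncated at 0) enters the proximal column, spread uniformly;
2. **metabolism** — per occupied patch, shared uptake caps
   ``4 c_i/(dt·DENS_MAX·(V1+V2))``; each cell solved with FBAwMC; growth
   capped by the empirical rate-yield trade-off; concentrations updated via
   ``dc_i = dt·sum_n F_{i,n}·V_n·DENS_MAX/4`` and cell volumes via
   ``V += V·mu·dt``; per-cell mole ledgers accumulated;
3. **death** — each cell dies with probability ``DEATH_RATE·dt`` where
   ``DEATH_RATE = DEATH_BASAL + DEATH_DENS·neighbours/max_neighbours``
   (neighbours = occupied slots in the 8 Moore patches plus the other slot
   of the own patch; max 17 in the interior);
4. **division & mutation** — cells with V >= 2 and a free slot split volume
   equally; each daughter genome is mutated per reaction (deletion
   ub -> 0 w.p. mu_DEL, reintroduction ub -> 999999 w.p. mu_BIRTH, crowding
   a -> a·10^step, step ~ Normal(0, mu_POINT_STEP), w.p. mu_POINT);
   cells with V >= 2 and no free slot stop growing (V clamped at 2);
5. **movement** — every slot (occupied or not) swaps with a random slot of a
   random Moore-neighbour patch with probability P_MOVECELL, at most one
   move per slot per turn;
6. **advection** — every TIME_DRIFT minutes all metabolite columns shift one
   patch distally (distal column exits: open boundary; proximal column
   refills with zeros); with probability P_CELL_FLOW the cells shift too,
   re-entering proximally (periodic);
7. **diffusion** — explicit 4-neighbour scheme with no-flux walls,
   stable for D·dt/L² < 0.25 (default 0.0252).
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field, fields as dc_fields
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .fbawmc import (SolverConfig, capped_growth_rate, solve_fbawmc,
                     uptake_caps_spatial)
from .network import (CrowdingSampler, MetabolicNetwork, REINTRODUCED_UB,
                      build_toy_network, sample_crowding, split_reversible)

logger = logging.getLogger(__name__)

#: short-chain fatty acids affected by the (default no-op) host-uptake hook
SCFA_IDS = ("ac", "ppa", "but")


class ConfigError(ValueError):
    pass


@dataclass
class SpatialConfig:
    """Parameters of the tube model (defaults = the full-scale stated values).

    Units: times in the names (``dt_min`` minutes, ``t_end_h`` hours),
    lengths in cm, concentrations mM, density gDW/l.
    """

    dt_min: float = 3.0
    patch_length_cm: float = 1.0
    grid_length: int = 150
    grid_height: int = 10
    t_end_h: float = 4000.0
    slots_per_patch: int = 2
    dens_max: float = 1.0
    initial_occupancy: float = 0.5
    time_food_h: float = 8.0
    food_in_mmol: float = 42.0
    food_rel_sd: float = 0.2
    diffusion_um2_s: float = 14000.0
    p_movecell: float = 0.05
    death_basal: float = 0.025
    death_dens: float = 2.0
    time_drift_min: float = 15.0
    p_cell_flow: float = 0.0
    uptake_host: float = 0.0
    mu_del: float = 0.002
    mu_birth: float = 0.0002
    mu_point: float = 0.002
    mu_point_step: float = 0.2
    patch_volume_l: float = 1.0
    glucose_id: str = "glc"
    exchange_mutable: bool = False
    seed: int = 0
    solver: SolverConfig = field(
        default_factory=lambda: SolverConfig(secondary_objective="penalty"))

    #: Table-1 style aliases accepted by :meth:`from_mapping`
    _ALIASES = {
        "dens_max": "dens_max", "time_food": "time_food_h",
        "food_in": "food_in_mmol", "p_movecell": "p_movecell",
        "death_basal": "death_basal", "death_dens": "death_dens",
        "time_drift": "time_drift_min", "p_cell_flow": "p_cell_flow",
        "uptake_host": "uptake_host",
        "mu_del": "mu_del", "μ_del": "mu_del",
        "mu_birth": "mu_birth", "μ_birth": "mu_birth",
        "mu_point": "mu_point", "μ_point": "mu_point",
        "mu_point_step": "mu_point_step", "μ_point_step": "mu_point_step",
        "time_end": "t_end_h", "grid_length": "grid_length",
        "grid_height": "grid_height", "initial_density": "initial_occupancy",
        "diffusion_constant": "diffusion_um2_s", "dt": "dt_min",
    }

    # -- derived quantities ------------------------------------------------
    @property
    def dt_h(self) -> float:
        return self.dt_min / 60.0

    @property
    def n_steps(self) -> int:
        return int(round(self.t_end_h / self.dt_h))

    @property
    def steps_per_food(self) -> int:
        return max(1, int(round(self.time_food_h / self.dt_h)))

    @property
    def steps_per_drift(self) -> int:
        return max(1, int(round(self.time_drift_min / self.dt_min)))

    @property
    def diffusion_number(self) -> float:
        """D·dt/L² of the explicit scheme (must stay below 0.25)."""
        d_cm2_s = self.diffusion_um2_s * 1e-8
        return d_cm2_s * (self.dt_min * 60.0) / self.patch_length_cm ** 2

    @property
    def transit_time_h(self) -> float:
        """Tracer passage time: grid_length advection shifts."""
        return self.grid_length * self.time_drift_min / 60.0

    def validate(self) -> None:
        for name in ("initial_occupancy", "p_movecell", "p_cell_flow",
                     "mu_del", "mu_birth", "mu_point", "uptake_host"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be a probability in [0,1], got {v}")
        if self.slots_per_patch != 2:
            raise ConfigError("the model is defined for exactly 2 slots per patch")
        if self.diffusion_number >= 0.25:
            raise ConfigError(
                f"explicit diffusion scheme unstable: D·dt/L² = "
                f"{self.diffusion_number:.4f} >= 0.25")

    def __post_init__(self) -> None:
        self.validate()

    @classmethod
    def scaled_down(cls, seed: int = 0, **overrides) -> "SpatialConfig":
        """Desk-scale tube (20 x 4 patches, 200 h) for tests and examples.

        Two quantities are rescaled together with the tube length so the
        model stays in the same transport regime as the full-scale tube:
        the meal period (the full tube holds ~4.7 meal pulses at a time,
        ratio TIME_FOOD/transit = 8/37.5; the 20-column tube has a 5 h
        transit, so meals arrive hourly) and the meal size (4.2 mmol,
        keeping the entry-column concentration at the ~1 mM scale of the
        well-mixed model).  This satisfies the stated calibration rule for
        the meal size: nutrients are mostly consumed during passage while
        the population is sustained.  All rates, probabilities and the
        mutation model keep their full-scale values.
        """
        params = dict(grid_length=20, grid_height=4, t_end_h=200.0,
                      time_food_h=1.0, food_in_mmol=4.2, seed=seed)
        params.update(overrides)
        return cls(**params)

    @classmethod
    def from_mapping(cls, mapping: Dict) -> "SpatialConfig":
        """Build from a config dict; accepts Table-1 parameter names verbatim
        (DENS_MAX, TIME_FOOD, FOOD_IN, ..., case-insensitive) as well as the
        dataclass field names."""
        valid = {f.name for f in dc_fields(cls)}
        kwargs, bad = {}, []
        for key, value in mapping.items():
            k = str(key).strip().lower()
            k = cls._ALIASES.get(k, k)
            if k in valid:
                if k == "solver" and isinstance(value, dict):
                    value = SolverConfig(**value)
                kwargs[k] = value
            else:
                bad.append(str(key))
        if bad:
            raise ConfigError(f"unknown configuration keys: {sorted(bad)}")
        return cls(**kwargs)


@dataclass
class Cell:
    """One metabacterium: own genome (bounds + crowding on a shared
    structure), dimensionless volume in (0, 2], and cumulative mole ledgers
    (mmol per litre of patch volume) for the cross-feeding statistic."""

    net: MetabolicNetwork
    volume: float = 1.0
    ledger_uptake: Optional[np.ndarray] = None
    ledger_excretion: Optional[np.ndarray] = None

    def genome_size(self) -> int:
        return self.net.genome_size()


class GridState:
    """Concentration fields (n_ext, H, W), cell slots (H, W, 2) and the
    global mole audit (meals in, advective outflow)."""

    def __init__(self, cfg: SpatialConfig, base_net: MetabolicNetwork) -> None:
        self.cfg = cfg
        self.base_net = base_net
        self.ext_ids: List[str] = sorted(
            set(base_net.structure.uptake_cols)
            | set(base_net.structure.excretion_cols))
        self.ext_index = {m: j for j, m in enumerate(self.ext_ids)}
        self.free_mask = np.array(
            [m in base_net.freely_available for m in self.ext_ids])
        H, W = cfg.grid_height, cfg.grid_length
        self.conc = np.zeros((len(self.ext_ids), H, W))
        self.cells = np.empty((H, W, 2), dtype=object)
        self.time_h = 0.0
        self.step_count = 0
        self.food_in_total = np.zeros(len(self.ext_ids))      # mmol
        self.advected_out_total = np.zeros(len(self.ext_ids))  # mmol

    # -- bookkeeping -------------------------------------------------------
    def occupancy(self) -> np.ndarray:
        """Occupied-slot count per patch, shape (H, W)."""
        return np.vectorize(lambda c: c is not None, otypes=[int])(
            self.cells).sum(axis=2)

    def iter_cells(self):
        H, W, _ = self.cells.shape
        for r in range(H):
            for c in range(W):
                for s in range(2):
                    cell = self.cells[r, c, s]
                    if cell is not None:
                        yield (r, c, s), cell

    @property
    def n_cells(self) -> int:
        return sum(1 for _ in self.iter_cells())

    def total_moles(self) -> np.ndarray:
        """Moles of each metabolite currently in the tube (mmol)."""
        return self.conc.sum(axis=(1, 2)) * self.cfg.patch_volume_l

    def mean_genome_size(self) -> float:
        sizes = [cell.genome_size() for _, cell in self.iter_cells()]
        return float(np.mean(sizes)) if sizes else float("nan")

    def cell_table(self) -> pd.DataFrame:
        rows = []
        for cid, ((r, c, s), cell) in enumerate(self.iter_cells()):
            rows.append({"id": cid, "row": r, "column": c, "slot": s,
                         "volume": cell.volume,
                         "genome_size": cell.genome_size()})
        return pd.DataFrame(rows,
                            columns=["id", "row", "column", "slot", "volume",
                                     "genome_size"])

    def digest(self) -> str:
        """SHA-256 over concentrations, cell positions, volumes and genomes —
        the reproducibility fingerprint of a run."""
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.conc).tobytes())
        for (r, c, s), cell in self.iter_cells():
            h.update(np.array([r, c, s], dtype=np.int64).tobytes())
            h.update(np.float64(cell.volume).tobytes())
            h.update(cell.net.state_key())
        return h.hexdigest()


def max_neighbours(cfg: SpatialConfig, row: int, col: int) -> int:
    """Maximum occupied-neighbour count at a patch: 2 slots per existing
    Moore-adjacent patch plus the own patch's other slot (17 interior)."""
    n_patches = 0
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            r, c = row + dr, col + dc
            if 0 <= r < cfg.grid_height and 0 <= c < cfg.grid_length:
                n_patches += 1
    return 2 * n_patches + 1


# ---------------------------------------------------------------------------
# initialization and the seven sub-steps
# ---------------------------------------------------------------------------

def init_grid(
    cfg: SpatialConfig,
    base_net: MetabolicNetwork,
    sampler: CrowdingSampler,
    rng: np.random.Generator,
) -> GridState:
    """Each slot independently occupied with probability
    ``initial_occupancy`` by a volume-1 cell carrying the full reaction set
    with freshly sampled crowding coefficients; all concentrations zero."""
    state = GridState(cfg, base_net)
    n_ext = len(state.ext_ids)
    H, W = cfg.grid_height, cfg.grid_length
    for r in range(H):
        for c in range(W):
            for s in range(2):
                if rng.random() < cfg.initial_occupancy:
                    net = sample_crowding(base_net, sampler, rng)
                    state.cells[r, c, s] = Cell(
                        net, 1.0, np.zeros(n_ext), np.zeros(n_ext))
    return state


def meal_input(state: GridState, cfg: SpatialConfig,
               rng: np.random.Generator) -> GridState:
    """Glucose pulse ~ Normal(FOOD_IN, rel_sd·FOOD_IN) mmol, truncated at 0
    by redrawing, spread uniformly over the proximal column."""
    amount = -1.0
    while amount <= 0:
        amount = rng.normal(cfg.food_in_mmol, cfg.food_rel_sd * cfg.food_in_mmol)
    j = state.ext_index[cfg.glucose_id]
    per_patch_mM = amount / (cfg.grid_height * cfg.patch_volume_l)
    state.conc[j, :, 0] += per_patch_mM
    state.food_in_total[j] += amount
    return state


def metabolism_step(state: GridState, cfg: SpatialConfig) -> GridState:
    """FBAwMC for every cell with the shared per-patch caps; Euler update of
    concentrations, volumes and ledgers."""
    dt = cfg.dt_h
    H, W = cfg.grid_height, cfg.grid_length
    scfa = [state.ext_index[m] for m in SCFA_IDS if m in state.ext_index]
    for r in range(H):
        for c in range(W):
            slot_cells = [state.cells[r, c, s] for s in range(2)
                          if state.cells[r, c, s] is not None]
            if not slot_cells:
                continue
            v_tot = sum(cell.volume for cell in slot_cells)
            patch_conc = state.conc[:, r, c]
            caps = {met: uptake_caps_spatial(patch_conc[j], v_tot, 0.0,
                                             dt, cfg.dens_max)
                    for met, j in state.ext_index.items()}
            delta = np.zeros(len(state.ext_ids))
            for cell in slot_cells:
                sol = solve_fbawmc(cell.net, caps, cfg.solver)
                mu = capped_growth_rate(cell.net, sol, cfg.solver)
                w = cell.volume * cfg.dens_max / 4.0
                for met, fflux in sol.exchange_fluxes.items():
                    j = state.ext_index[met]
                    delta[j] += fflux * w
                    if fflux < 0:
                        cell.ledger_uptake[j] += -fflux * w * dt
                    elif fflux > 0:
                        cell.ledger_excretion[j] += fflux * w * dt
                cell.volume += cell.volume * mu * dt
            new = patch_conc + dt * delta
            # freely-available inorganics are externally buffered: pinned
            new[state.free_mask] = patch_conc[state.free_mask]
            tol = 1e-6
            if np.any(new < -tol * np.maximum(1.0, np.abs(patch_conc))):
                j_bad = int(np.argmin(new))
                raise RuntimeError(
                    f"concentration of {state.ext_ids[j_bad]} went negative "
                    f"at patch ({r},{c}): {new[j_bad]:.3e}")
            state.conc[:, r, c] = np.maximum(new, 0.0)
    if cfg.uptake_host > 0 and scfa:
        # host uptake hook: wall-adjacent rows lose a fraction of SCFA
        for j in scfa:
            state.conc[j, 0, :] *= (1.0 - cfg.uptake_host)
            state.conc[j, -1, :] *= (1.0 - cfg.uptake_host)
    return state


def death_step(state: GridState, cfg: SpatialConfig,
               rng: np.random.Generator) -> GridState:
    """Density-dependent death: Eq.-style rate
    DEATH_BASAL + DEATH_DENS·neighbours/max_neighbours, converted to a
    per-step probability by multiplying with dt (clamped at 1)."""
    occ = state.occupancy()
    H, W = occ.shape
    padded = np.zeros((H + 2, W + 2), dtype=int)
    padded[1:-1, 1:-1] = occ
    moore = sum(padded[1 + dr:H + 1 + dr, 1 + dc:W + 1 + dc]
                for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                if not (dr == 0 and dc == 0))
    clamp_warned = False
    for (r, c, s), cell in list(state.iter_cells()):
        neighbours = int(moore[r, c]) + (occ[r, c] - 1)
        rate = cfg.death_basal + cfg.death_dens * neighbours / max_neighbours(cfg, r, c)
        p = rate * cfg.dt_h
        if p > 1.0:
            if not clamp_warned:
                logger.warning("death probability %.3f > 1 clamped", p)
                clamp_warned = True
            p = 1.0
        if rng.random() < p:
            state.cells[r, c, s] = None
    return state


def _mutate_genome(net: MetabolicNetwork, cfg: SpatialConfig,
                   rng: np.random.Generator) -> None:
    """Per-reaction mutations at a division event (in place)."""
    n = net.n_reactions
    mutable = np.ones(n, dtype=bool)
    if not cfg.exchange_mutable:
        mutable &= ~net.structure.exchange_mask
    mutable[net.objective_index] = False
    # fixed draw order: deletion, reintroduction, point — one uniform each
    u_del = rng.random(n)
    u_birth = rng.random(n)
    u_point = rng.random(n)
    steps = rng.normal(0.0, cfg.mu_point_step, size=n)
    delete = mutable & (u_del < cfg.mu_del)
    birth = mutable & (u_birth < cfg.mu_birth)
    point = mutable & (u_point < cfg.mu_point)
    net.ub[delete] = 0.0
    net.ub[birth] = REINTRODUCED_UB
    net.crowding[point] *= 10.0 ** steps[point]


def division_mutation_step(state: GridState, cfg: SpatialConfig,
                           rng: np.random.Generator) -> GridState:
    """Cells with V >= 2 divide into the free slot of their patch (volume and
    ledgers split equally; both daughters mutated independently); without a
    free slot the volume is clamped at 2 (local carrying capacity)."""
    H, W = cfg.grid_height, cfg.grid_length
    for r in range(H):
        for c in range(W):
            for s in range(2):
                cell = state.cells[r, c, s]
                if cell is None or cell.volume < 2.0:
                    continue
                other = 1 - s
                if state.cells[r, c, other] is None:
                    half_v = cell.volume / 2.0
                    daughter = Cell(cell.net.copy(), half_v,
                                    cell.ledger_uptake / 2.0,
                                    cell.ledger_excretion / 2.0)
                    cell.volume = half_v
                    cell.ledger_uptake /= 2.0
                    cell.ledger_excretion /= 2.0
                    _mutate_genome(cell.net, cfg, rng)
                    _mutate_genome(daughter.net, cfg, rng)
                    state.cells[r, c, other] = daughter
                else:
                    cell.volume = 2.0
    return state


def _moore_neighbours(cfg: SpatialConfig, r: int, c: int) -> List[Tuple[int, int]]:
    out = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            rr, cc = r + dr, c + dc
            if 0 <= rr < cfg.grid_height and 0 <= cc < cfg.grid_length:
                out.append((rr, cc))
    return out


def movement_step(state: GridState, cfg: SpatialConfig,
                  rng: np.random.Generator) -> GridState:
    """Random slot swaps with Moore-neighbour patches; every slot (occupied
    or not) attempts at most one move per turn."""
    if cfg.p_movecell <= 0:
        return state
    H, W = cfg.grid_height, cfg.grid_length
    moved = np.zeros((H, W, 2), dtype=bool)
    slots = [(r, c, s) for r in range(H) for c in range(W) for s in range(2)]
    order = rng.permutation(len(slots))
    for k in order:
        r, c, s = slots[k]
        if moved[r, c, s]:
            continue
        if rng.random() >= cfg.p_movecell:
            continue
        nbs = _moore_neighbours(cfg, r, c)
        rr, cc = nbs[rng.integers(len(nbs))]
        ss = int(rng.integers(2))
        if moved[rr, cc, ss]:
            continue  # target already moved this turn: attempt fails
        state.cells[r, c, s], state.cells[rr, cc, ss] = \
            state.cells[rr, cc, ss], state.cells[r, c, s]
        moved[r, c, s] = True
        moved[rr, cc, ss] = True
    return state


def advection_step(state: GridState, cfg: SpatialConfig,
                   rng: np.random.Generator) -> GridState:
    """Shift all metabolite columns one patch distally (open distal boundary,
    zero-filled proximal column); with probability P_CELL_FLOW the cells
    shift too, with periodic re-entry."""
    out = state.conc[:, :, -1].sum(axis=1) * cfg.patch_volume_l
    state.advected_out_total += out
    state.conc[:, :, 1:] = state.conc[:, :, :-1]
    state.conc[:, :, 0] = 0.0
    if cfg.p_cell_flow > 0 and rng.random() < cfg.p_cell_flow:
        state.cells = np.roll(state.cells, 1, axis=1)
    return state


def diffusion_step(state: GridState, cfg: SpatialConfig) -> GridState:
    """Explicit 4-neighbour diffusion with no-flux boundaries on all sides
    (transport along the tube is advection's job)."""
    d = cfg.diffusion_number
    c = state.conc
    padded = np.pad(c, ((0, 0), (1, 1), (1, 1)), mode="edge")
    lap = (padded[:, :-2, 1:-1] + padded[:, 2:, 1:-1]
           + padded[:, 1:-1, :-2] + padded[:, 1:-1, 2:] - 4.0 * c)
    state.conc = c + d * lap
    return state


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

@dataclass
class Snapshot:
    time_h: float
    mean_genome_size: float
    n_cells: int
    conc: Optional[np.ndarray]  # (n_ext, H, W)
    cell_rows: List[int]
    cell_cols: List[int]
    cell_volumes: List[float]
    cell_genome_sizes: List[int]
    cell_ledger_uptake: List[np.ndarray]
    cell_ledger_excretion: List[np.ndarray]


def take_snapshot(state: GridState, keep_conc: bool = True) -> Snapshot:
    rows, cols, vols, sizes, lups, lexs = [], [], [], [], [], []
    for (r, c, _s), cell in state.iter_cells():
        rows.append(r)
        cols.append(c)
        vols.append(cell.volume)
        sizes.append(cell.genome_size())
        lups.append(cell.ledger_uptake.copy())
        lexs.append(cell.ledger_excretion.copy())
    return Snapshot(
        time_h=state.time_h,
        mean_genome_size=float(np.mean(sizes)) if sizes else float("nan"),
        n_cells=len(vols),
        conc=state.conc.copy() if keep_conc else None,
        cell_rows=rows, cell_cols=cols, cell_volumes=vols,
        cell_genome_sizes=sizes,
        cell_ledger_uptake=lups, cell_ledger_excretion=lexs,
    )


@dataclass
class SpatialResult:
    cfg: SpatialConfig
    ext_ids: List[str]
    snapshots: List[Snapshot]
    final: GridState

    def genome_size_series(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": [s.time_h for s in self.snapshots],
            "mean_genome_size": [s.mean_genome_size for s in self.snapshots],
            "n_cells": [s.n_cells for s in self.snapshots],
        })

    def save(self, outdir) -> None:
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.genome_size_series().to_csv(outdir / "genome_size.csv", index=False)
        self.final.cell_table().to_csv(outdir / "cells_final.csv", index=False)
        # dense concentration field of the final state, tidy long format
        rows = []
        n_ext, H, W = self.final.conc.shape
        for j, met in enumerate(self.ext_ids):
            for r in range(H):
                for c in range(W):
                    rows.append({"metabolite": met, "row": r, "column": c,
                                 "concentration": self.final.conc[j, r, c]})
        pd.DataFrame(rows).to_csv(outdir / "concentrations_final.csv", index=False)


def run_spatial(
    cfg: SpatialConfig,
    base_net: Optional[MetabolicNetwork] = None,
    sampler: Optional[CrowdingSampler] = None,
    snapshot_every_h: Optional[float] = None,
    keep_conc: bool = True,
) -> SpatialResult:
    """Run the full tube simulation; reproducible from (cfg, seed) alone.

    RNG draw order per step: meals, death, mutation, movement, advection —
    all from the single run generator seeded with ``cfg.seed``.
    """
    cfg.validate()
    if base_net is None:
        base_net = split_reversible(build_toy_network())
    if not base_net.is_irreversible():
        base_net = split_reversible(base_net)
    sampler = sampler or CrowdingSampler(seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed)
    state = init_grid(cfg, base_net, sampler, rng)
    if snapshot_every_h is None:
        snapshot_every_h = max(cfg.t_end_h / 40.0, cfg.dt_h)
    snap_every = max(1, int(round(snapshot_every_h / cfg.dt_h)))
    snapshots = [take_snapshot(state, keep_conc)]
    n_steps = cfg.n_steps
    for step in range(n_steps):
        if step % cfg.steps_per_food == 0:
            meal_input(state, cfg, rng)
        metabolism_step(state, cfg)
        death_step(state, cfg, rng)
        division_mutation_step(state, cfg, rng)
        movement_step(state, cfg, rng)
        if (step + 1) % cfg.steps_per_drift == 0:
            advection_step(state, cfg, rng)
        diffusion_step(state, cfg)
        state.step_count += 1
        state.time_h = (step + 1) * cfg.dt_h
        if (step + 1) % snap_every == 0:
            snapshots.append(take_snapshot(state, keep_conc))
        if (step + 1) % 1000 == 0:
            logger.info("step %d/%d (t=%.1f h, %d cells)",
                        step + 1, n_steps, state.time_h, state.n_cells)
    if snapshots[-1].time_h != state.time_h:
        snapshots.append(take_snapshot(state, keep_conc))
    return SpatialResult(cfg, state.ext_ids, snapshots, state)
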