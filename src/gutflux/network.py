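"""Stoichiometric metabolic networks for "metabacterium" community models.

A metabacterium is a coarse-grained metapopulation of gut bacteria represented
by a single stoichiometric network.  This module holds the network container,
readers/writers (SBML via cobra, plus a two-sheet tabular dialect), the
reversible-reaction splitter, the built-in toy fermentation network that
mirrors the main carbohydrate fermentation pathways of the colon, and the
sampler for reaction crowding coefficients.

Conventions
-----------
* Fluxes are in mmol·gDW^-1·h^-1; after :func:`split_reversible` every
  reaction is irreversible (0 <= lb <= ub).
* Exchange reactions are written ``met -> (nothing)``; after splitting, the
  backward copy ``(nothing) -> met`` is the uptake direction.  Uptake caps are
  applied to those columns at solve time.
* Bounds and crowding coefficients live in numpy arrays on the network
  (``net.lb``, ``net.ub``, ``net.crowding``) and are the authoritative values
  after construction; :class:`Reaction` objects carry the static structure
  (id, stoichiometry, exchange flag) plus the *initial* bounds.
"""

from __future__ import annotations

import logging
import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

INTRACELLULAR = "intracellular"
EXTRACELLULAR = "extracellular"

#: upper bound used when a reaction is (re)introduced into a genome
REINTRODUCED_UB = 999999.0
#: upper bound of a deleted reaction
DELETED_UB = 0.0

#: metabolites with unlimited influx in every environment (inorganics; no carbon
#: except none of these carries carbon).  Matched against metabolite ids.
FREELY_AVAILABLE = frozenset(
    {"h2", "h2o", "na1", "nh4", "pi", "so4", "h",
     "h2_e", "h2o_e", "na1_e", "nh4_e", "pi_e", "so4_e", "h_e"}
)

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def carbon_count_from_formula(formula: Optional[str]) -> Optional[int]:
    """Number of carbon atoms in a chemical formula, or None if unparseable.

    Handles multi-letter elements correctly ("Ca", "Cl", "Co" contribute no
    carbon).
    """
    if not formula:
        return None
    total = 0
    matched_len = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        matched_len += len(m.group(0))
        if m.group(1) == "C":
            total += int(m.group(2) or 1)
    if matched_len != len(re.sub(r"[\s]", "", formula)):
        return None
    return total


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = INTRACELLULAR
    carbon_count: Optional[int] = None  # None = unknown

    def __post_init__(self) -> None:
        if self.carbon_count is not None and self.carbon_count < 0:
            raise ValueError(f"carbon_count of {self.id} must be >= 0")


@dataclass
class Reaction:
    """A (possibly reversible) reaction.  ``stoichiometry`` maps metabolite id
    to signed coefficient (< 0 consumed, > 0 produced)."""

    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = REINTRODUCED_UB
    crowding_coefficient: float = 0.0
    is_exchange: bool = False
    name: str = ""

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    def __post_init__(self) -> None:
        if self.crowding_coefficient < 0:
            raise ValueError(f"crowding coefficient of {self.id} must be >= 0")


class _Structure:
    """Immutable structural part of a network, shared between per-cell copies
    (stoichiometric matrix, exchange-column bookkeeping, LP cache slot)."""

    def __init__(self, net: "MetabolicNetwork") -> None:
        n_m, n_r = len(net.metabolites), len(net.reactions)
        S = np.zeros((n_m, n_r))
        for j, rxn in enumerate(net.reactions):
            for met_id, coef in rxn.stoichiometry.items():
                if met_id not in net.met_index:
                    raise ValueError(
                        f"reaction {rxn.id!r} references unknown metabolite {met_id!r}"
                    )
                S[net.met_index[met_id], j] = coef
        self.S = S
        self.exchange_mask = np.array([r.is_exchange for r in net.reactions])
        # For irreversible networks: map extracellular metabolite -> columns.
        self.uptake_cols: Dict[str, List[int]] = {}
        self.excretion_cols: Dict[str, List[int]] = {}
        for j, rxn in enumerate(net.reactions):
            if not rxn.is_exchange or len(rxn.stoichiometry) != 1:
                continue
            (met_id, coef), = rxn.stoichiometry.items()
            if coef > 0:
                self.uptake_cols.setdefault(met_id, []).append(j)
            else:
                self.excretion_cols.setdefault(met_id, []).append(j)
        self.lp = None  # persistent solver problem, owned by gutflux.fbawmc


class MetabolicNetwork:
    """Container for metabolites, reactions and the stoichiometric matrix S.

    Mutable per-instance state (numpy arrays, aligned with ``reactions``):

    ``lb``, ``ub``
        flux bounds; a deleted reaction has ``ub == 0``.
    ``crowding``
        crowding coefficients a_i (enzyme volume fraction per unit flux).
    """

    def __init__(
        self,
        metabolites: Sequence[Metabolite],
        reactions: Sequence[Reaction],
        objective_reaction_id: str,
        freely_available: Optional[Iterable[str]] = None,
        _structure: Optional[_Structure] = None,
    ) -> None:
        if not reactions:
            raise ValueError("a metabolic network must contain at least one reaction")
        ids = [m.id for m in metabolites]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate metabolite ids")
        rids = [r.id for r in reactions]
        if len(set(rids)) != len(rids):
            raise ValueError("duplicate reaction ids")
        self.metabolites = list(metabolites)
        self.reactions = list(reactions)
        self.met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self.rxn_index = {r.id: j for j, r in enumerate(self.reactions)}
        if objective_reaction_id not in self.rxn_index:
            raise ValueError(f"objective reaction {objective_reaction_id!r} not found")
        self.objective_reaction_id = objective_reaction_id
        self.freely_available = frozenset(
            freely_available if freely_available is not None else FREELY_AVAILABLE
        )
        self.lb = np.array([r.lower_bound for r in reactions], dtype=float)
        self.ub = np.array([r.upper_bound for r in reactions], dtype=float)
        self.crowding = np.array([r.crowding_coefficient for r in reactions], dtype=float)
        self.structure = _structure if _structure is not None else _Structure(self)

    # -- structure ---------------------------------------------------------
    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def stoichiometric_matrix(self) -> np.ndarray:
        return self.structure.S

    @property
    def objective_index(self) -> int:
        return self.rxn_index[self.objective_reaction_id]

    def extracellular_metabolites(self) -> List[Metabolite]:
        return [m for m in self.metabolites if m.compartment == EXTRACELLULAR]

    def carbon_counts(self) -> np.ndarray:
        """Per-metabolite carbon counts; NaN where unknown."""
        return np.array(
            [np.nan if m.carbon_count is None else float(m.carbon_count)
             for m in self.metabolites]
        )

    def is_irreversible(self) -> bool:
        return bool(np.all(self.lb >= 0))

    def genome_size(self) -> int:
        """Number of reactions carried by this genome (upper bound > 0)."""
        return int(np.count_nonzero(self.ub > 0))

    # -- per-cell state ----------------------------------------------------
    def copy(self) -> "MetabolicNetwork":
        """Cheap copy sharing structure; own bounds and crowding arrays."""
        new = object.__new__(MetabolicNetwork)
        new.metabolites = self.metabolites
        new.reactions = self.reactions
        new.met_index = self.met_index
        new.rxn_index = self.rxn_index
        new.objective_reaction_id = self.objective_reaction_id
        new.freely_available = self.freely_available
        new.lb = self.lb.copy()
        new.ub = self.ub.copy()
        new.crowding = self.crowding.copy()
        new.structure = self.structure
        return new

    def state_key(self) -> bytes:
        """Hashable digest of the mutable genome state (bounds + crowding)."""
        return self.lb.tobytes() + self.ub.tobytes() + self.crowding.tobytes()


# ---------------------------------------------------------------------------
# reversible splitting
# ---------------------------------------------------------------------------

def split_reversible(net: MetabolicNetwork) -> MetabolicNetwork:
    """Replace every reversible reaction by a forward/backward irreversible pair.

    The backward copy (suffix ``_rev``) has negated stoichiometry and inherits
    the crowding coefficient.  Already-irreversible reactions are kept as is.
    """
    out: List[Reaction] = []
    for j, rxn in enumerate(net.reactions):
        lb, ub, a = net.lb[j], net.ub[j], net.crowding[j]
        if lb >= 0:
            out.append(Reaction(rxn.id, dict(rxn.stoichiometry), lb, ub, a,
                                rxn.is_exchange, rxn.name))
        else:
            out.append(Reaction(rxn.id, dict(rxn.stoichiometry), 0.0, ub, a,
                                rxn.is_exchange, rxn.name))
            out.append(Reaction(
                rxn.id + "_rev",
                {m: -c for m, c in rxn.stoichiometry.items()},
                0.0, -lb, a, rxn.is_exchange, rxn.name,
            ))
    return MetabolicNetwork(net.metabolites, out, net.objective_reaction_id,
                            net.freely_available)


# ---------------------------------------------------------------------------
# toy network: central carbon fermentation of the gut microbiota
# ---------------------------------------------------------------------------

#: the eleven pathway switches of the toy fermentation network
TOY_PATHWAYS = (
    "glycolysis",
    "lactate_fermentation",
    "propionate_fermentation",
    "acrylate",
    "pyruvate_dehydrogenase",
    "pyruvate_formate_lyase",
    "butyrate_fermentation",
    "acetate_fermentation",
    "wood_ljungdahl",
    "ethanol_fermentation",
    "butyryl_coa_acetate_transferase",
)

_TOY_METS = [
    # id, name, compartment, carbons
    ("glc", "D-glucose", EXTRACELLULAR, 6),
    ("lac", "lactate", EXTRACELLULAR, 3),
    ("ac", "acetate", EXTRACELLULAR, 2),
    ("ppa", "propionate", EXTRACELLULAR, 3),
    ("but", "butyrate", EXTRACELLULAR, 4),
    ("etoh", "ethanol", EXTRACELLULAR, 2),
    ("for", "formate", EXTRACELLULAR, 1),
    ("co2", "carbon dioxide", EXTRACELLULAR, 1),
    ("h2", "hydrogen gas", EXTRACELLULAR, 0),
    ("pyr", "pyruvate", INTRACELLULAR, 3),
    ("accoa", "acetyl-CoA (acetyl moiety)", INTRACELLULAR, 2),
    ("atp", "ATP", INTRACELLULAR, 0),
    ("adp", "ADP", INTRACELLULAR, 0),
    ("nad", "NAD+", INTRACELLULAR, 0),
    ("nadh", "NADH", INTRACELLULAR, 0),
]

# (id, stoichiometry, reversible, pathway) -- redox closed via NAD(H), energy
# via ATP/ADP; CoA, water and phosphate are kept implicit so that every
# reaction is exactly carbon-balanced over the tracked carbon species.
_TOY_RXNS = [
    ("GLY", {"glc": -1, "adp": -2, "nad": -2, "pyr": 2, "atp": 2, "nadh": 2},
     False, "glycolysis"),
    ("LDH", {"pyr": -1, "nadh": -1, "lac": 1, "nad": 1},
     True, "lactate_fermentation"),
    ("PPF", {"pyr": -1, "nadh": -2, "ppa": 1, "nad": 2},
     True, "propionate_fermentation"),
    ("ACR", {"lac": -1, "nadh": -1, "ppa": 1, "nad": 1},
     True, "acrylate"),
    ("PDH", {"pyr": -1, "nad": -1, "accoa": 1, "co2": 1, "nadh": 1},
     False, "pyruvate_dehydrogenase"),
    ("PFL", {"pyr": -1, "accoa": 1, "for": 1},
     True, "pyruvate_formate_lyase"),
    ("BUT", {"accoa": -2, "nadh": -2, "adp": -1, "but": 1, "nad": 2, "atp": 1},
     False, "butyrate_fermentation"),
    ("ACK", {"accoa": -1, "adp": -1, "ac": 1, "atp": 1},
     True, "acetate_fermentation"),
    ("WLP", {"co2": -2, "nadh": -4, "adp": -1, "ac": 1, "nad": 4, "atp": 1},
     True, "wood_ljungdahl"),
    ("FDH", {"for": -1, "nad": -1, "co2": 1, "nadh": 1},
     True, "wood_ljungdahl"),
    ("ADHE", {"accoa": -1, "nadh": -2, "etoh": 1, "nad": 2},
     True, "ethanol_fermentation"),
    ("BCT", {"accoa": -1, "ac": -1, "nadh": -2, "but": 1, "nad": 2},
     False, "butyryl_coa_acetate_transferase"),
    ("HYD", {"nadh": -1, "nad": 1, "h2": 1}, True, None),   # hydrogenase
]

_TOY_EXCHANGE = ["glc", "lac", "ac", "ppa", "but", "etoh", "for", "co2", "h2"]


def build_toy_network(pathways: Optional[Iterable[str]] = None) -> MetabolicNetwork:
    """Small carbon- and redox-balanced fermentation network.

    Parameters
    ----------
    pathways
        Which of :data:`TOY_PATHWAYS` to include (default: all eleven).
        The hydrogenase, the ATP-hydrolysis objective and all exchange
        reactions are always present.

    The network is returned *unsplit* (reversible reactions intact); call
    :func:`split_reversible` before solving.
    """
    selected = set(TOY_PATHWAYS if pathways is None else pathways)
    unknown = selected - set(TOY_PATHWAYS)
    if unknown:
        raise ValueError(f"unknown toy pathways: {sorted(unknown)}")
    mets = [Metabolite(i, n, comp, c) for i, n, comp, c in _TOY_METS]
    rxns: List[Reaction] = []
    for rid, stoich, rev, pathway in _TOY_RXNS:
        if pathway is not None and pathway not in selected:
            continue
        rxns.append(Reaction(rid, dict(stoich),
                             -REINTRODUCED_UB if rev else 0.0, REINTRODUCED_UB))
    rxns.append(Reaction("ATPM", {"atp": -1, "adp": 1}, 0.0, REINTRODUCED_UB,
                         name="ATP hydrolysis objective"))
    for met in _TOY_EXCHANGE:
        rxns.append(Reaction(f"EX_{met}", {met: -1.0},
                             -REINTRODUCED_UB, REINTRODUCED_UB, is_exchange=True))
    net = MetabolicNetwork(mets, rxns, "ATPM")
    if not _atp_reachable_from_glucose(net):
        warnings.warn(
            "toy pathway selection admits no route from glucose to ATP; "
            "the network models a non-grower on glucose", stacklevel=2)
    return net


def _atp_reachable_from_glucose(net: MetabolicNetwork) -> bool:
    """BFS over reactions usable once all their substrates are reachable."""
    reachable = {"glc", "adp", "nad", "nadh", "h2"}
    changed = True
    while changed:
        changed = False
        for j, rxn in enumerate(net.reactions):
            if rxn.is_exchange or net.ub[j] <= 0:
                continue
            for stoich in ([rxn.stoichiometry]
                           + ([{m: -c for m, c in rxn.stoichiometry.items()}]
                              if net.lb[j] < 0 else [])):
                subs = {m for m, c in stoich.items() if c < 0}
                prods = {m for m, c in stoich.items() if c > 0}
                if subs <= reachable and not prods <= reachable:
                    reachable |= prods
                    changed = True
    return "atp" in reachable


# ---------------------------------------------------------------------------
# crowding coefficient sampling
# ---------------------------------------------------------------------------

@dataclass
class CrowdingSampler:
    """Random source of per-reaction crowding coefficients.

    ``empirical_table`` mode resamples (with replacement) from a table of
    measured coefficients; ``lognormal`` mode is the fallback, justified by the
    near-lognormal shape of the measured E. coli distribution.  Defaults put
    the median coefficient at 0.02 gDW·h·mmol^-1 (so a typical reaction at
    full crowding budget V_prot = 0.2 runs at ~10 mmol·gDW^-1·h^-1, the scale
    of measured glucose uptake) with a one-decade log-sd spread.
    """

    mode: str = "lognormal"
    table: Optional[np.ndarray] = None
    log_mean: float = math.log(0.02)
    log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("lognormal", "empirical_table"):
            raise ValueError(f"unknown sampler mode {self.mode!r}")
        if self.mode == "empirical_table":
            if self.table is None or len(self.table) == 0:
                raise ValueError("empirical_table mode requires a non-empty table")
            self.table = np.asarray(self.table, dtype=float)
            if np.any(self.table <= 0):
                raise ValueError("crowding coefficients must be > 0")

    def sample(self, n: int, rng: Optional[np.random.Generator] = None) -> np.ndarray:
        """Draw n positive coefficients.  Without an explicit generator a fresh
        one is seeded from ``self.seed``, so repeated calls reproduce exactly."""
        if rng is None:
            rng = np.random.default_rng(self.seed)
        if self.mode == "empirical_table":
            return rng.choice(self.table, size=n, replace=True)
        return np.exp(rng.normal(self.log_mean, self.log_sd, size=n))


def sample_crowding(
    net: MetabolicNetwork,
    sampler: CrowdingSampler,
    rng: Optional[np.random.Generator] = None,
    include_exchange: bool = False,
) -> MetabolicNetwork:
    """Return a copy of ``net`` with freshly sampled crowding coefficients.

    Exchange pseudo-reactions model transport availability rather than
    cytosolic enzyme volume and are excluded by default (coefficient 0).
    """
    new = net.copy()
    mask = np.ones(net.n_reactions, dtype=bool)
    if not include_exchange:
        mask &= ~net.structure.exchange_mask
    mask[net.objective_index] = False
    draws = sampler.sample(int(mask.sum()), rng)
    new.crowding = np.zeros(net.n_reactions)
    new.crowding[mask] = draws
    return new


# ---------------------------------------------------------------------------
# tabular dialect (two sheets: reactions / metabolites)
# ---------------------------------------------------------------------------

_ARROWS = ("<=>", "<->", "-->", "->", "=>")


def parse_equation(eq: str) -> tuple[Dict[str, float], bool]:
    """Parse "A + 2 B -> C" style equations.  "<=>"/"<->" marks reversible.

    An empty side denotes an exchange boundary, e.g. "glc_e ->".
    """
    eq = eq.strip()
    reversible = False
    arrow = None
    for a in _ARROWS:
        if a in eq:
            arrow = a
            reversible = a in ("<=>", "<->")
            break
    if arrow is None:
        raise ValueError(f"no reaction arrow in equation {eq!r}")
    left, right = eq.split(arrow, 1)
    stoich: Dict[str, float] = {}

    def add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            term = term.strip()
            if not term:
                raise ValueError(f"empty term in equation {eq!r}")
            parts = term.split()
            if len(parts) == 1:
                coef, met = 1.0, parts[0]
            elif len(parts) == 2:
                try:
                    coef = float(parts[0])
                except ValueError as exc:
                    raise ValueError(
                        f"bad stoichiometric coefficient in term {term!r}") from exc
                met = parts[1]
            else:
                raise ValueError(f"cannot parse term {term!r} in equation {eq!r}")
            stoich[met] = stoich.get(met, 0.0) + sign * coef

    add_side(left, -1.0)
    add_side(right, +1.0)
    if not stoich:
        raise ValueError(f"equation {eq!r} has no metabolites")
    return stoich, reversible


def format_equation(rxn: Reaction, reversible: bool) -> str:
    def side(items: Iterable[tuple[str, float]]) -> str:
        parts = []
        for met, coef in items:
            coef = abs(coef)
            parts.append(met if coef == 1 else f"{coef:g} {met}")
        return " + ".join(parts)

    subs = [(m, c) for m, c in rxn.stoichiometry.items() if c < 0]
    prods = [(m, c) for m, c in rxn.stoichiometry.items() if c > 0]
    arrow = "<=>" if reversible else "->"
    return f"{side(subs)} {arrow} {side(prods)}".strip()


def _infer_compartment(met_id: str, explicit: Optional[str]) -> str:
    if explicit:
        e = explicit.strip().lower()
        if e in ("e", "extracellular", "external"):
            return EXTRACELLULAR
        return INTRACELLULAR
    return EXTRACELLULAR if met_id.endswith("_e") else INTRACELLULAR


def load_tabular(path) -> MetabolicNetwork:
    """Read the two-sheet tabular dialect.

    ``path`` may be an .xls/.xlsx workbook with sheets named ``reactions``
    (columns: id, equation, reversibility) and ``metabolites`` (columns: id,
    name, formula), or a directory containing ``reactions.csv`` and
    ``metabolites.csv`` with the same columns.
    """
    path = Path(path)
    if path.is_dir():
        rxn_df = pd.read_csv(path / "reactions.csv")
        met_df = pd.read_csv(path / "metabolites.csv")
    else:
        try:
            rxn_df = pd.read_excel(path, sheet_name="reactions")
            met_df = pd.read_excel(path, sheet_name="metabolites")
        except ValueError as exc:
            raise ValueError(f"cannot read tabular network {path}: {exc}") from exc
    rxn_df.columns = [c.strip().lower() for c in rxn_df.columns]
    met_df.columns = [c.strip().lower() for c in met_df.columns]
    if rxn_df.empty:
        raise ValueError(f"{path}: reaction sheet is empty")

    mets: List[Metabolite] = []
    for _, row in met_df.iterrows():
        mid = str(row["id"]).strip()
        formula = row.get("formula")
        formula = None if pd.isna(formula) else str(formula)
        cc = carbon_count_from_formula(formula)
        if cc is None:
            logger.warning("metabolite %s: unknown carbon count (formula=%r)",
                           mid, formula)
        mets.append(Metabolite(
            mid,
            "" if pd.isna(row.get("name")) else str(row.get("name", "")),
            _infer_compartment(mid, row.get("compartment")
                               if "compartment" in met_df.columns else None),
            cc,
        ))
    known = {m.id for m in mets}

    rxns: List[Reaction] = []
    for _, row in rxn_df.iterrows():
        rid = str(row["id"]).strip()
        try:
            stoich, rev_eq = parse_equation(str(row["equation"]))
        except ValueError as exc:
            raise ValueError(f"reaction {rid!r}: {exc}") from exc
        missing = set(stoich) - known
        if missing:
            raise ValueError(
                f"reaction {rid!r} references unknown metabolites {sorted(missing)}")
        rev = rev_eq
        if "reversibility" in rxn_df.columns and not pd.isna(row["reversibility"]):
            raw = str(row["reversibility"]).strip().lower()
            rev = raw in ("1", "true", "yes", "reversible", "r")
        is_ex = all(c < 0 for c in stoich.values()) or all(c > 0 for c in stoich.values())
        rxns.append(Reaction(
            rid, stoich,
            -REINTRODUCED_UB if rev else 0.0, REINTRODUCED_UB, is_exchange=is_ex))

    objective = _find_or_append_objective(mets, rxns)
    return MetabolicNetwork(mets, rxns, objective)


def save_tabular(net: MetabolicNetwork, directory) -> None:
    """Write the network in the tabular dialect (two CSV files)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rxn_rows = []
    for j, rxn in enumerate(net.reactions):
        rev = net.lb[j] < 0
        rxn_rows.append({"id": rxn.id,
                         "equation": format_equation(rxn, rev),
                         "reversibility": int(rev)})
    met_rows = []
    for m in net.metabolites:
        formula = "" if m.carbon_count is None else (
            "C" if m.carbon_count == 1 else f"C{m.carbon_count}")
        met_rows.append({"id": m.id, "name": m.name, "formula": formula,
                         "compartment": m.compartment})
    pd.DataFrame(rxn_rows).to_csv(directory / "reactions.csv", index=False)
    pd.DataFrame(met_rows).to_csv(directory / "metabolites.csv", index=False)


def _find_or_append_objective(mets: List[Metabolite], rxns: List[Reaction]) -> str:
    """Designate the ATP-hydrolysis maintenance reaction as objective,
    appending one when the model lacks it."""
    atp_ids = [m.id for m in mets if m.id.lower() in ("atp", "atp_c", "atp[c]")]
    for rxn in rxns:
        if rxn.id.lower() in ("atpm", "r_atpm", "atp_maintenance") or \
                "maintenance" in rxn.name.lower():
            return rxn.id
    if not atp_ids:
        raise ValueError("cannot designate an objective: no ATP metabolite found")
    atp = atp_ids[0]
    adp = next((m.id for m in mets if m.id.lower().startswith("adp")), None)
    stoich = {atp: -1.0}
    if adp:
        stoich[adp] = 1.0
    rxns.append(Reaction("ATPM", stoich, 0.0, REINTRODUCED_UB,
                         name="ATP maintenance (appended objective)"))
    return "ATPM"


# ---------------------------------------------------------------------------
# SBML interop (through cobrapy)
# ---------------------------------------------------------------------------

def to_cobra(net: MetabolicNetwork):
    """Convert to a cobra.Model (for SBML export and cross-checks)."""
    import cobra

    model = cobra.Model("gutflux")
    cmets = {}
    for m in net.metabolites:
        cm = cobra.Metabolite(
            m.id, name=m.name,
            compartment="e" if m.compartment == EXTRACELLULAR else "c")
        if m.carbon_count is not None:
            cm.formula = f"C{m.carbon_count}" if m.carbon_count else ""
        cmets[m.id] = cm
    model.add_metabolites(list(cmets.values()))
    for j, rxn in enumerate(net.reactions):
        cr = cobra.Reaction(rxn.id, name=rxn.name,
                            lower_bound=float(net.lb[j]),
                            upper_bound=float(net.ub[j]))
        model.add_reactions([cr])
        cr.add_metabolites({cmets[m]: c for m, c in rxn.stoichiometry.items()})
    model.objective = net.objective_reaction_id
    return model


def from_cobra(model) -> MetabolicNetwork:
    mets = []
    for m in model.metabolites:
        cc = carbon_count_from_formula(m.formula)
        comp = EXTRACELLULAR if str(m.compartment).lower().startswith("e") \
            else INTRACELLULAR
        mets.append(Metabolite(m.id, m.name or "", comp, cc))
    boundary_ids = {r.id for r in model.boundary}
    rxns = []
    for r in model.reactions:
        rxns.append(Reaction(
            r.id, {m.id: c for m, c in r.metabolites.items()},
            float(r.lower_bound), float(r.upper_bound),
            is_exchange=r.id in boundary_ids, name=r.name or ""))
    objective = None
    for r in model.reactions:
        if r.objective_coefficient:
            objective = r.id
            break
    if objective is None:
        objective = _find_or_append_objective(mets, rxns)
    return MetabolicNetwork(mets, rxns, objective)


def load_sbml(path) -> MetabolicNetwork:
    import cobra.io

    try:
        model = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # noqa: BLE001 - surface parse errors uniformly
        raise ValueError(f"cannot parse SBML file {path}: {exc}") from exc
    return from_cobra(model)


def save_sbml(net: MetabolicNetwork, path) -> None:
    import cobra.io

    cobra.io.write_sbml_model(to_cobra(net), str(path))


def load_network(path, format: Optional[str] = None) -> MetabolicNetwork:
    """Load a network from SBML (.xml/.sbml) or the tabular dialect
    (.xls/.xlsx workbook or CSV directory).  Reversible reactions are kept
    intact; apply :func:`split_reversible` before solving."""
    path = Path(path)
    if format is None:
        if path.is_dir() or path.suffix.lower() in (".xls", ".xlsx"):
            format = "tabular"
        else:
            format = "sbml"
    if format == "sbml":
        return load_sbml(path)
    if format == "tabular":
        return load_tabular(path)
    raise ValueError(f"unknown network format {format!r}")
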