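"""Cross-feeding quantification, niche assays, phenotype clustering and
metabolite stratification.

The central statistic is the cross-feeding factor.  With cumulative mole
ledgers F_up,tot(i,j) and F_ex,tot(i,j) (total moles of metabolite j taken
up / excreted by species i over a time window), the carbon species i obtained
from other species is

    C(i) = sum_j c_C(j) * max(F_up,tot(i,j) - F_ex,tot(i,j), 0)
           - 6 * F_up,tot(i, glucose)

(c_C(j) = carbon atoms per molecule, c_C(glucose) = 6; the glucose term is
subtracted because glucose is the primary resource) and the community-level
fraction of cross-fed carbon is

    C_rel = sum_i C(i) / sum_i sum_j c_C(j) F_up,tot(i,j)   in [0, 1].

A species that eats only glucose has C(i) = 0; C_rel = 1 means all consumed
carbon came from community-excreted metabolites.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .fbawmc import SolverConfig, capped_growth_rate, solve_fbawmc
from .network import MetabolicNetwork

logger = logging.getLogger(__name__)

GLUCOSE_CARBON = 6.0


@dataclass
class CrossFeedingReport:
    """Per-species cross-fed carbon and the community C_rel."""

    species: List
    C: np.ndarray                 # floored at 0, mol C (per unit volume)
    C_unfloored: np.ndarray       # the raw value of the sum, for transparency
    carbon_uptake: np.ndarray     # sum_j c_C(j) F_up,tot(i,j)
    C_rel: float

    @property
    def per_species_factor(self) -> np.ndarray:
        """C(i) normalised by species i's own carbon uptake (0 when the
        species took up nothing)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(self.carbon_uptake > 0, self.C / self.carbon_uptake, 0.0)
        return f

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "species": self.species,
            "C": self.C,
            "C_unfloored": self.C_unfloored,
            "carbon_uptake": self.carbon_uptake,
            "factor": self.per_species_factor,
        })


def cross_feeding(
    uptake: np.ndarray,
    excretion: np.ndarray,
    ext_ids: Sequence[str],
    carbon_counts: Mapping[str, Optional[float]],
    glucose_id: str = "glc",
    species: Optional[Sequence] = None,
) -> CrossFeedingReport:
    """Cross-feeding report from cumulative mole ledgers.

    ``uptake`` and ``excretion`` are (n_species, n_metabolites) arrays of
    total moles per metabolite; metabolites with unknown carbon count are
    excluded (with a warning).  Negative C(i) — a glucose eater that excretes
    more non-glucose carbon than it re-consumes — is floored at 0 before the
    community sum (a species cannot cross-feed a negative amount); the
    unfloored value is reported for transparency.
    """
    uptake = np.asarray(uptake, dtype=float)
    excretion = np.asarray(excretion, dtype=float)
    if uptake.shape != excretion.shape or uptake.shape[1] != len(ext_ids):
        raise ValueError("ledger shapes do not match the metabolite list")
    cc = np.zeros(len(ext_ids))
    unknown = []
    for j, met in enumerate(ext_ids):
        val = carbon_counts.get(met)
        if val is None or (isinstance(val, float) and np.isnan(val)):
            unknown.append(met)
            cc[j] = 0.0
        else:
            cc[j] = float(val)
    if unknown:
        logger.warning("metabolites with unknown carbon count excluded from "
                       "cross-feeding ledger: %s", unknown)
    if glucose_id in ext_ids:
        j_glc = list(ext_ids).index(glucose_id)
        glc_up = uptake[:, j_glc]
    else:
        glc_up = np.zeros(uptake.shape[0])
    net_crossfed = np.maximum(uptake - excretion, 0.0) @ cc
    c_unfloored = net_crossfed - GLUCOSE_CARBON * glc_up
    c_floored = np.maximum(c_unfloored, 0.0)
    carbon_up = uptake @ cc
    denom = carbon_up.sum()
    c_rel = float(c_floored.sum() / denom) if denom > 0 else 0.0
    if species is None:
        species = list(range(uptake.shape[0]))
    return CrossFeedingReport(list(species), c_floored, c_unfloored,
                              carbon_up, c_rel)


def cross_feeding_from_frame(
    ledger: pd.DataFrame,
    carbon_counts: Mapping[str, Optional[float]],
    glucose_id: str = "glc",
) -> CrossFeedingReport:
    """Same, from a tidy ledger (columns: member/species, metabolite, uptake,
    excretion)."""
    key = "member" if "member" in ledger.columns else "species"
    up = ledger.pivot_table(index=key, columns="metabolite", values="uptake",
                            aggfunc="sum", fill_value=0.0)
    ex = ledger.pivot_table(index=key, columns="metabolite", values="excretion",
                            aggfunc="sum", fill_value=0.0).reindex_like(up).fillna(0.0)
    return cross_feeding(up.to_numpy(), ex.to_numpy(), list(up.columns),
                         carbon_counts, glucose_id, species=list(up.index))


def community_cross_feeding(state, carbon_counts=None,
                            glucose_id: str = "glc") -> CrossFeedingReport:
    """Cross-feeding of a finished well-mixed run (CommunityState)."""
    if carbon_counts is None:
        net = state.members[0].net
        carbon_counts = {m.id: m.carbon_count for m in net.metabolites}
    return cross_feeding(state.ledger_uptake, state.ledger_excretion,
                         state.ext_ids, carbon_counts, glucose_id)


# ---------------------------------------------------------------------------
# positional cross-feeding (tube profiles)
# ---------------------------------------------------------------------------

def positional_crossfeeding(
    result,
    window: Tuple[float, float],
    carbon_counts: Optional[Mapping[str, Optional[float]]] = None,
    glucose_id: str = "glc",
) -> pd.DataFrame:
    """Per-tube-column mean and SD of the cell-level cross-feeding factor,
    averaged over rows and over all snapshots whose time falls in ``window``
    (a (t0, t1] interval, hours).  Columns with no cells yield NaN.
    """
    t0, t1 = window
    snaps = [s for s in result.snapshots if t0 < s.time_h <= t1]
    if not snaps:
        raise ValueError(f"no snapshots in window ({t0}, {t1}]")
    if carbon_counts is None:
        net = result.final.base_net
        carbon_counts = {m.id: m.carbon_count for m in net.metabolites}
    ext_ids = result.ext_ids
    n_cols = result.cfg.grid_length
    values: List[List[float]] = [[] for _ in range(n_cols)]
    for snap in snaps:
        if not snap.cell_cols:
            continue
        up = np.array(snap.cell_ledger_uptake)
        ex = np.array(snap.cell_ledger_excretion)
        rep = cross_feeding(up, ex, ext_ids, carbon_counts, glucose_id)
        factors = rep.per_species_factor
        for col, f, cu in zip(snap.cell_cols, factors, rep.carbon_uptake):
            if cu > 0:
                values[col].append(float(f))
    rows = []
    for col in range(n_cols):
        v = values[col]
        rows.append({
            "column": col,
            "mean": float(np.mean(v)) if v else np.nan,
            "sd": float(np.std(v)) if v else np.nan,
            "n": len(v),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# niche assays
# ---------------------------------------------------------------------------

#: saturating uptake cap used in the homogeneous assay environments
SATURATING_CAP = 1000.0

#: the six homogeneous assay environments (test carbon source -> cap), each
#: solved in the presence of the unlimited inorganic set
DEFAULT_ENVIRONMENTS: Dict[str, Dict[str, float]] = {
    "glucose": {"glc": SATURATING_CAP},
    "acetate": {"ac": SATURATING_CAP},
    "formate": {"for": SATURATING_CAP},
    "lactate": {"lac": SATURATING_CAP},
    "propionate": {"ppa": SATURATING_CAP},
    "co2_h2": {"co2": SATURATING_CAP, "h2": SATURATING_CAP},
}


def niche_assay(
    nets: Iterable[MetabolicNetwork],
    environments: Optional[Mapping[str, Mapping[str, float]]] = None,
    cfg: Optional[SolverConfig] = None,
) -> pd.DataFrame:
    """Growth rate of each cell in each homogeneous environment.

    Each environment grants a saturating uptake cap on one carbon source
    (plus the always-unlimited inorganics); the growth rate is the FBAwMC
    rate after the rate-yield cap.  Returns a (cells x environments) frame.
    """
    environments = environments or DEFAULT_ENVIRONMENTS
    cfg = cfg or SolverConfig()
    rows = []
    for net in nets:
        row = {}
        for env_name, caps in environments.items():
            sol = solve_fbawmc(net, caps, cfg)
            row[env_name] = capped_growth_rate(net, sol, cfg)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(environments))


# ---------------------------------------------------------------------------
# phenotype clustering
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeClustering:
    linkage: np.ndarray      # scipy linkage matrix (average, euclidean)
    labels: np.ndarray       # cluster labels at the largest-relative-gap cut
    n_clusters: int
    leaf_names: List[str]

    def to_newick(self) -> str:
        """Dendrogram in Newick format (branch lengths from merge heights)."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.leaf_names[node.id]}:{length:g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:g}"

        return walk(tree, tree.dist) + ";"


def cluster_phenotypes(profiles: pd.DataFrame) -> PhenotypeClustering:
    """Agglomerative clustering of growth-rate profiles (average linkage,
    Euclidean distance), as used to identify metabolic "species".

    The reported flat cut is chosen at the largest relative gap between
    consecutive merge heights; the full dendrogram is always available.
    Input order determines leaf ids (scipy's deterministic tie-breaking).
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles to cluster")
    X = profiles.to_numpy(dtype=float)
    Z = hierarchy.linkage(X, method="average", metric="euclidean")
    heights = Z[:, 2]
    if np.allclose(heights, 0.0):
        labels = np.ones(len(profiles), dtype=int)
        n_clusters = 1
    else:
        eps = max(heights.max() * 1e-12, 1e-300)
        gaps = (heights[1:] - heights[:-1]) / np.maximum(heights[:-1], eps)
        k = int(np.argmax(gaps))
        threshold = 0.5 * (heights[k] + heights[k + 1])
        labels = hierarchy.fcluster(Z, t=threshold, criterion="distance")
        n_clusters = int(labels.max())
    names = [str(i) for i in (profiles.index if profiles.index is not None
                              else range(len(profiles)))]
    return PhenotypeClustering(Z, labels, n_clusters, names)


# ---------------------------------------------------------------------------
# metabolite stratification
# ---------------------------------------------------------------------------

def stratification_profile(result, window: Tuple[float, float]) -> pd.DataFrame:
    """Per-metabolite, per-column average concentration over rows and over
    the snapshots in ``window`` (tidy frame: metabolite, column, mean_concentration)."""
    t0, t1 = window
    snaps = [s for s in result.snapshots
             if t0 < s.time_h <= t1 and s.conc is not None]
    if not snaps:
        warnings.warn("no concentration snapshots in window; empty profile",
                      stacklevel=2)
        return pd.DataFrame(columns=["metabolite", "column", "mean_concentration"])
    stack = np.stack([s.conc for s in snaps])          # (T, n_ext, H, W)
    prof = stack.mean(axis=(0, 2))                      # (n_ext, W)
    rows = []
    for j, met in enumerate(result.ext_ids):
        for col in range(prof.shape[1]):
            rows.append({"metabolite": met, "column": col,
                         "mean_concentration": prof[j, col]})
    return pd.DataFrame(rows)
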