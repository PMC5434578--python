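"""Seeded fixture generators binding the modules into reproducible
experiments (and feeding the test suite)."""

from __future__ import annotations

from pathlib import Path
from typing import List

import numpy as np
import pandas as pd

from . import wellmixed
from .network import (CrowdingSampler, build_toy_network, save_sbml,
                      split_reversible)

FIXTURE_KINDS = ("toy_net", "two_zone_ledger", "three_archetype_population",
                 "wellmixed_small")


def two_zone_ledger_frame() -> pd.DataFrame:
    """The worked two-species ledger: species A (proximal) eats 1 mmol
    glucose and excretes 2 mmol acetate; species B (distal) eats that
    acetate.  By the cross-feeding definition C(A)=0, C(B)=4 mol C,
    total carbon uptake 10 mol C, hence C_rel = 0.4."""
    return pd.DataFrame([
        {"species": "A", "metabolite": "glc", "uptake": 1.0, "excretion": 0.0,
         "column": 1},
        {"species": "A", "metabolite": "ac", "uptake": 0.0, "excretion": 2.0,
         "column": 1},
        {"species": "B", "metabolite": "ac", "uptake": 2.0, "excretion": 0.0,
         "column": 18},
    ])


def three_archetype_profiles(seed: int = 0, n_per_class: int = 10) -> pd.DataFrame:
    """Synthetic growth-rate profiles of three metabolic archetypes (glucose
    specialists, secondary-metabolite consumers, acetate specialists) with
    small seeded noise; the true class is recoverable by a 3-cluster cut.
    Synthetic stand-in for an evolved population (not solved from networks)."""
    rng = np.random.default_rng(seed)
    envs = ["glucose", "acetate", "formate", "lactate", "propionate", "co2_h2"]
    archetypes = {
        "glucose_specialist": [0.24, 0.0, 0.0, 0.0, 0.0, 0.0],
        "secondary_consumer": [0.0, 0.0, 0.12, 0.15, 0.10, 0.12],
        "acetate_specialist": [0.0, 0.20, 0.0, 0.02, 0.0, 0.0],
    }
    rows, labels = [], []
    for name, mean in archetypes.items():
        for _ in range(n_per_class):
            rows.append(np.clip(rng.normal(mean, 0.005), 0.0, None))
            labels.append(name)
    df = pd.DataFrame(rows, columns=envs)
    df["true_class"] = labels
    return df


def generate_fixture(kind: str, seed: int, outdir) -> List[Path]:
    """Write the named fixture under ``outdir``; returns the files written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if kind == "toy_net":
        path = outdir / "toy_network.xml"
        save_sbml(build_toy_network(), path)
        return [path]
    if kind == "two_zone_ledger":
        path = outdir / "two_zone_ledger.csv"
        two_zone_ledger_frame().to_csv(path, index=False)
        return [path]
    if kind == "three_archetype_population":
        path = outdir / "three_archetype_profiles.csv"
        three_archetype_profiles(seed).to_csv(path, index=False)
        return [path]
    if kind == "wellmixed_small":
        net = split_reversible(build_toy_network())
        sampler = CrowdingSampler(seed=seed)
        state = wellmixed.init_community(
            net, n=10, total_biomass=0.01, glucose_mM=1.0,
            sampler=sampler, rng=np.random.default_rng(seed))
        traj = wellmixed.run(state, dt=0.1, max_time=12.0)
        traj.save(outdir)
        return [outdir / "concentrations.csv", outdir / "biomass.csv",
                outdir / "ledger.csv"]
    raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
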