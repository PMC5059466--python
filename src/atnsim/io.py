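"""Plain-text serialisation of communities, constants and result tables.

A community file is self-contained: a species table (guild, body mass,
per-plant nutrient half-saturations, strict-herbivore flag) plus key-value
blocks for the sampled constants and the nutrient model. Links are not
stored -- they are recomputed deterministically from masses and constants.
"""

from __future__ import annotations

import dataclasses
import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .community import Community, ParameterSet, build_food_web
from .rates import NutrientParameters

__all__ = ["save_community", "load_community", "trajectory_frame"]


def save_community(
    path: str | Path,
    community: Community,
    params: ParameterSet,
    nutrients: NutrientParameters,
) -> None:
    path = Path(path)
    def fmt(v) -> str:
        return repr(float(v))

    lines = ["[parameters]"]
    for f in dataclasses.fields(params):
        lines.append(f"{f.name} = {fmt(getattr(params, f.name))}")
    lines.append(f"prune_epsilon = {fmt(community.prune_epsilon)}")
    lines.append("")
    lines.append("[nutrients]")
    lines.append(f"D = {fmt(nutrients.D)}")
    lines.append("S = " + ", ".join(fmt(v) for v in nutrients.S))
    lines.append("v = " + ", ".join(fmt(v) for v in nutrients.v))
    lines.append("")
    lines.append("[species]")
    lines.append("guild\tmass\tK1\tK2\therb_only")
    for i, m in enumerate(community.masses_plants):
        lines.append(
            f"plant\t{fmt(m)}\t{fmt(nutrients.K[i, 0])}\t{fmt(nutrients.K[i, 1])}\t")
    herb = community.herbivore_only_mask
    for i, m in enumerate(community.masses_animals):
        flag = "" if herb is None else str(int(herb[i]))
        lines.append(f"animal\t{fmt(m)}\t\t\t{flag}")
    path.write_text("\n".join(lines) + "\n")


def load_community(
    path: str | Path,
) -> tuple[Community, ParameterSet, NutrientParameters]:
    """Parse a community file and reassemble the pruned food web."""
    text = Path(path).read_text()
    sections: dict[str, list[str]] = {}
    current = None
    for raw in text.splitlines():
        line = raw.rstrip("\n")
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1]
            sections[current] = []
        elif current is not None and line.strip():
            sections[current].append(line)

    kv = {}
    for line in sections.get("parameters", []):
        key, _, val = line.partition("=")
        kv[key.strip()] = val.strip()
    eps = float(kv.pop("prune_epsilon", "0.01"))
    par_fields = {f.name for f in dataclasses.fields(ParameterSet)}
    params = ParameterSet(**{k: float(v) for k, v in kv.items() if k in par_fields})

    nut_kv = {}
    for line in sections.get("nutrients", []):
        key, _, val = line.partition("=")
        nut_kv[key.strip()] = val.strip()

    table = pd.read_csv(
        _io.StringIO("\n".join(sections["species"])), sep="\t", dtype=str
    )
    plants = table[table["guild"] == "plant"]
    animals = table[table["guild"] == "animal"]
    masses_p = plants["mass"].astype(float).to_numpy()
    masses_a = animals["mass"].astype(float).to_numpy()
    K = plants[["K1", "K2"]].astype(float).to_numpy()
    herb_col = animals["herb_only"]
    herb_mask = None
    if herb_col.notna().any():
        herb_mask = herb_col.fillna("0").astype(float).astype(bool).to_numpy()

    nutrients = NutrientParameters(
        S=np.array([float(v) for v in nut_kv["S"].split(",")]),
        K=K,
        D=float(nut_kv.get("D", "0.25")),
        v=np.array([float(v) for v in nut_kv["v"].split(",")]),
    )
    community = Community(masses_plants=masses_p, masses_animals=masses_a)
    community = build_food_web(
        community, eps=eps, R_opt=params.R_opt, gamma=params.gamma,
        herbivore_only_mask=herb_mask,
    )
    return community, params, nutrients


def trajectory_frame(trajectory, community) -> pd.DataFrame:
    """Long-format time series: one row per (time, species), nutrients wide."""
    rows = []
    for k, t in enumerate(trajectory.times):
        for i in range(community.S_A):
            rows.append((t, f"animal_{i}", trajectory.A[k, i]))
        for i in range(community.S_P):
            rows.append((t, f"plant_{i}", trajectory.P[k, i]))
        rows.append((t, "nutrient_1", trajectory.N[k, 0]))
        rows.append((t, "nutrient_2", trajectory.N[k, 1]))
    return pd.DataFrame(rows, columns=["time", "species", "biomass"])
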