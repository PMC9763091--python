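"""Plain-text serialization: patterns/colors as CSV, rules as CSV, params as
YAML, transforms as JSON.  Lattice JSON lives in :mod:`scalepat.lattice`."""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd
import yaml

from .colormap import AffineMap3
from .lattice import ColorState, PatternState
from .rd import RDParams
from .stochastic import SCARules

__all__ = [
    "patterns_to_csv", "patterns_from_csv",
    "colors_to_csv", "colors_from_csv",
    "rules_to_csv", "rules_from_csv",
    "params_to_yaml", "params_from_yaml",
    "transform_to_json", "transform_from_json",
]


def patterns_to_csv(patterns, path: str) -> None:
    rows = [
        {"scale_id": i, "time": p.time, "state": int(s)}
        for p in patterns
        for i, s in enumerate(p.states)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def patterns_from_csv(path: str) -> list[PatternState]:
    df = pd.read_csv(path)
    out = []
    for t, grp in df.groupby("time", sort=True):
        grp = grp.sort_values("scale_id")
        out.append(PatternState(grp["state"].to_numpy(np.int8), float(t)))
    return out


def colors_to_csv(colors, path: str) -> None:
    rows = [
        {"scale_id": i, "time": c.time, "L": v[0], "a": v[1], "b": v[2]}
        for c in colors
        for i, v in enumerate(c.colors)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def colors_from_csv(path: str) -> list[ColorState]:
    df = pd.read_csv(path)
    out = []
    for t, grp in df.groupby("time", sort=True):
        grp = grp.sort_values("scale_id")
        out.append(ColorState(grp[["L", "a", "b"]].to_numpy(float), float(t)))
    return out


def rules_to_csv(rules: SCARules, path: str) -> None:
    rows = []
    for s, name in ((0, "black"), (1, "green")):
        for i in range(8):
            rows.append(
                {"state": name, "i": i, "n": int(rules.n[s, i]), "k": int(rules.k[s, i]),
                 "E_p": rules.expected_p[s, i]}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def rules_from_csv(path: str) -> SCARules:
    df = pd.read_csv(path)
    n = np.zeros((2, 8), dtype=np.int64)
    k = np.zeros((2, 8), dtype=np.int64)
    smap = {"black": 0, "green": 1}
    for _, row in df.iterrows():
        n[smap[row["state"]], int(row["i"])] = int(row["n"])
        k[smap[row["state"]], int(row["i"])] = int(row["k"])
    return SCARules(n, k)


def params_to_yaml(params: RDParams, path: str) -> None:
    d = dataclasses.asdict(params)
    if d.get("growth") is not None:
        d["growth"] = list(d["growth"])
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh)


def params_from_yaml(path: str) -> RDParams:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if d.get("growth") is not None:
        d["growth"] = tuple(d["growth"])
    return RDParams(**d)


def transform_to_json(T: AffineMap3, path: str) -> None:
    with open(path, "w") as fh:
        json.dump({"matrix": T.matrix.tolist()}, fh)


def transform_from_json(path: str) -> AffineMap3:
    with open(path) as fh:
        return AffineMap3(np.asarray(json.load(fh)["matrix"]))
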