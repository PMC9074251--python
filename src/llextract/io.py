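"""Readers and writers for tie-line tables, parameter sets, streams, and
cost tables.

Formats
-------
* tie-lines: CSV with columns ``T_K, x1_org..xN_org, x1_aq..xN_aq`` in the
  component order of the associated :class:`ComponentSet`;
* NRTL parameters: JSON or YAML pair list
  ``{components, T_ref_K, pairs: [{i, j, tau_ij, tau_ji, alpha}]}``;
* streams: JSON with per-stream flow + composition (mole or mass basis);
* cost tables: YAML/JSON with investment and utility line items in million
  USD (utilities per annum).
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .components import ComponentSet
from .economics import CostTable
from .estimation import TieLineDataset
from .cascade import Stream
from .flash import TieLine
from .nrtl import NrtlParameterSet

__all__ = [
    "read_tielines_csv",
    "write_tielines_csv",
    "read_params",
    "write_params",
    "read_streams",
    "write_streams",
    "read_cost_table",
    "packaged_path",
]


class SchemaError(ValueError):
    """A file parsed but does not match the expected schema."""


def packaged_path(name: str) -> Path:
    """Path to a packaged data fixture (e.g. the printed stream table)."""
    return Path(str(resources.files("llextract.data").joinpath(name)))


# -- tie-line CSV -------------------------------------------------------


def write_tielines_csv(path, data: TieLineDataset) -> None:
    n = data.components.n
    rows = []
    for tl in data.tielines:
        row = {"T_K": tl.T}
        for i in range(n):
            row[f"x{i + 1}_org"] = tl.x_org[i]
        for i in range(n):
            row[f"x{i + 1}_aq"] = tl.x_aq[i]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_tielines_csv(
    path, components: ComponentSet, noise_sd: float = 0.0
) -> TieLineDataset:
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise SchemaError(f"{path}: no tie-line rows")
    n = components.n
    org_cols = [f"x{i + 1}_org" for i in range(n)]
    aq_cols = [f"x{i + 1}_aq" for i in range(n)]
    missing = [c for c in ["T_K", *org_cols, *aq_cols] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    T_vals = df["T_K"].unique()
    if len(T_vals) != 1:
        raise SchemaError(f"{path}: tie-lines must share one temperature, got {T_vals}")
    tls = []
    for idx, row in df.iterrows():
        try:
            tls.append(
                TieLine(
                    x_org=row[org_cols].to_numpy(float),
                    x_aq=row[aq_cols].to_numpy(float),
                    T=float(row["T_K"]),
                )
            )
        except ValueError as exc:
            raise SchemaError(f"{path} row {idx}: {exc}") from exc
    return TieLineDataset(components, tuple(tls), T=float(T_vals[0]), noise_sd=noise_sd)


# -- NRTL parameter sets -------------------------------------------------


def write_params(path, params: NrtlParameterSet) -> None:
    path = Path(path)
    d = params.to_dict()
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        path.write_text(json.dumps(d, indent=2))


def read_params(path) -> NrtlParameterSet:
    path = Path(path)
    text = path.read_text()
    d = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    try:
        return NrtlParameterSet.from_dict(d)
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError(f"{path}: {exc}") from exc


# -- streams --------------------------------------------------------------


def write_streams(path, streams: dict[str, Stream]) -> None:
    first = next(iter(streams.values()))
    comps = first.components
    d = {
        "components": list(comps.names),
        "molar_mass": list(comps.molar_mass),
        "basis": "mole",
        "flow_units": "kmol/h",
        "streams": [
            {
                "label": label,
                "flow": s.total,
                "composition": [float(v) for v in s.x],
            }
            for label, s in streams.items()
        ],
    }
    Path(path).write_text(json.dumps(d, indent=2))


def read_streams(path) -> dict[str, Stream]:
    """Streams from JSON; mass-basis files are converted to molar flows."""
    d = json.loads(Path(path).read_text())
    try:
        comps = ComponentSet(tuple(d["components"]), tuple(d.get("molar_mass", ())))
        basis = d.get("basis", "mole")
        out: dict[str, Stream] = {}
        for s in d["streams"]:
            x = np.asarray(s["composition"], float)
            if x.shape != (comps.n,):
                raise SchemaError(
                    f"stream {s.get('label')!r}: composition length mismatch"
                )
            flow = float(s["flow"])
            if basis == "mole":
                flows = flow * x / max(x.sum(), 1e-300)
            elif basis == "mass":
                moles = flow * x / comps.masses()  # kg/h -> kmol/h per comp.
                flows = moles
            else:
                raise SchemaError(f"unknown basis {basis!r}")
            out[s["label"]] = Stream(comps, flows, label=s["label"])
        return out
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"{path}: {exc}") from exc


# -- cost tables -----------------------------------------------------------


def read_cost_table(path) -> tuple[CostTable, Optional[float]]:
    """CostTable plus the product rate (kg/h) if the file states one."""
    path = Path(path)
    text = path.read_text()
    d = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    try:
        table = CostTable(
            investment_items=dict(d["investment"]),
            utility_items=dict(d["utility"]),
            payout_years=float(d.get("payout_years", 5.0)),
            hours_per_year=float(d.get("hours_per_year", 8000.0)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError(f"{path}: {exc}") from exc
    rate = d.get("product_rate_kg_h")
    return table, (float(rate) if rate is not None else None)
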