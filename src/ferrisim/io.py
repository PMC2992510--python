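"""Reading and writing parameters, states and experiment outputs.

Parameters travel as a flat YAML/JSON document keyed by the published
parameter names (``k_aso``, ``fe_pack``, ``fn_total``, ...).  Unknown keys
are rejected rather than ignored so a typo cannot silently fall back to a
default.  Floats are serialized at full round-trip precision (17 significant
digits).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import (
    ConfigurationError,
    ModelParameters,
    SystemState,
    make_parameters,
)

__all__ = [
    "parameters_to_dict",
    "parameters_from_dict",
    "load_parameters",
    "save_parameters",
    "state_to_csv",
    "state_from_csv",
    "read_calibration_points",
    "write_csv",
    "write_json",
]

FLOAT_FORMAT = "%.17g"

# flat document keys <-> dataclass fields
_PACKING_KEYS = {
    "fe_pack": "atoms_per_package",
    "fn_max": "max_capacity_atoms",
    "fn_max_eff": "effective_capacity_atoms",
}
_SCALAR_KEYS = (
    "k_aso",
    "k_dis",
    "k_cat",
    "k_d",
    "k_loss_base",
    "hill_n",
    "hill_theta",
    "hill_kappa",
    "fn_total",
    "fe_initial",
)


def parameters_to_dict(params: ModelParameters) -> dict:
    doc = {key: getattr(params, key) for key in _SCALAR_KEYS}
    for key, attr in _PACKING_KEYS.items():
        doc[key] = getattr(params.packing, attr)
    return doc


def parameters_from_dict(doc: dict) -> ModelParameters:
    overrides: dict = {}
    for key, value in doc.items():
        if key in _PACKING_KEYS:
            overrides[_PACKING_KEYS[key]] = int(value)
        elif key in _SCALAR_KEYS:
            overrides[key] = float(value)
        else:
            raise ConfigurationError(f"unknown parameter key {key!r}")
    return make_parameters(**overrides)


def load_parameters(path) -> ModelParameters:
    """Read a flat YAML (or JSON) parameter document."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        return make_parameters()
    if not isinstance(doc, dict):
        raise ConfigurationError("parameter file must hold a flat mapping")
    return parameters_from_dict(doc)


def save_parameters(params: ModelParameters, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(parameters_to_dict(params), fh, sort_keys=True)


def state_to_csv(state: SystemState, path) -> None:
    """CSV with one row per load class (i, fn_i, c_i) plus a leading row
    holding the scalar free-iron amount."""
    rows = [{"i": "fe", "fn": repr(float(state.fe)), "c": ""}]
    for i in range(state.n_packages + 1):
        rows.append(
            {"i": str(i), "fn": repr(float(state.fn[i])), "c": repr(float(state.c[i]))}
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def state_from_csv(path) -> SystemState:
    df = pd.read_csv(path, dtype=str)
    fe_rows = df[df["i"] == "fe"]
    if len(fe_rows) != 1:
        raise ValueError("state file must contain exactly one 'fe' row")
    fe = float(fe_rows["fn"].iloc[0])
    body = df[df["i"] != "fe"].copy()
    body["i"] = body["i"].astype(int)
    body = body.sort_values("i")
    if list(body["i"]) != list(range(len(body))):
        raise ValueError("load classes must cover 0..N without gaps")
    return SystemState(
        fe=fe,
        fn=body["fn"].astype(float).to_numpy(),
        c=body["c"].astype(float).to_numpy(),
    )


def read_calibration_points(path) -> list[tuple[int, float]]:
    """Two-column delimited text (fraction index, Fe/ferritin ratio);
    comma or whitespace separated, '#' comments and an optional header
    allowed."""
    pts: list[tuple[int, float]] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        if len(parts) < 2:
            raise ValueError(f"malformed calibration line: {raw!r}")
        try:
            pts.append((int(float(parts[0])), float(parts[1])))
        except ValueError:
            # tolerate a single header line
            if pts:
                raise
    if not pts:
        raise ValueError("no calibration points found")
    return pts


def write_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(doc: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, default=_jsonable, sort_keys=True)
        fh.write("\n")
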