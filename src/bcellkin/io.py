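"""Readers and writers for the package's plain-text formats (YAML/JSON
configs, CSV tables, JSON fit results)."""
from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .inference import MEASUREMENT_COLUMNS, FitResult, validate_measurements
from .parameters import KineticParameters


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML or JSON config file (dispatch on suffix)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def save_config(obj: dict[str, Any], path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(obj, sort_keys=False))


def load_parameters(path: str | Path) -> KineticParameters:
    """Read a flat key-value parameter config (all 14 constants)."""
    return KineticParameters.from_dict(load_config(path))


def save_parameters(params: KineticParameters, path: str | Path) -> None:
    save_config(params.as_dict(), path)


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read a per-mouse measurement CSV (mouse_id, group, day, subset,
    labeled_fraction) and validate it."""
    df = pd.read_csv(path)
    df["day"] = df["day"].astype(float)
    return validate_measurements(df)


def write_measurements(table: pd.DataFrame, path: str | Path) -> None:
    validate_measurements(table)
    table.to_csv(path, index=False, columns=list(MEASUREMENT_COLUMNS))


def read_totals_ranges(path: str | Path) -> dict[str, tuple[float, float]]:
    """Read a totals-range CSV (subset, lower, upper) into the mapping used
    by the steady-state filter."""
    df = pd.read_csv(path)
    missing = {"subset", "lower", "upper"} - set(df.columns)
    if missing:
        raise ValueError(f"totals-range table missing columns: {sorted(missing)}")
    bad = df[df["upper"] < df["lower"]]
    if len(bad):
        raise ValueError(f"totals ranges with upper < lower: {list(bad['subset'])}")
    return {r.subset: (float(r.lower), float(r.upper)) for r in df.itertuples(index=False)}


def write_totals_ranges(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, columns=["subset", "lower", "upper"])


def write_fit_result(fit: FitResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(fit.to_dict(), indent=2) + "\n")


def read_fit_result(path: str | Path) -> FitResult:
    d = json.loads(Path(path).read_text())
    return FitResult(
        params=KineticParameters.from_dict(d["parameters"]),
        log_likelihood=d["log_likelihood"],
        n_candidates=d["n_candidates"],
        n_passing=d["n_passing"],
        seed=d["seed"],
        sampled_names=tuple(d["sampled_names"]),
        ci={k: tuple(v) for k, v in d.get("ci", {}).items()},
    )
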