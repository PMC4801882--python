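"""Kinetic parameters of the five-compartment B-cell development model.

All rates are per 6-hour time unit (the simulation time unit); cell numbers
are absolute counts per mouse. Day-based quantities are converted at 4 units
per day (:data:`UNITS_PER_DAY`).
"""
from __future__ import annotations

from dataclasses import dataclass, fields, replace
from importlib import resources
from typing import Iterator, Mapping

import yaml

#: simulation time units per day (one unit = 6 h)
UNITS_PER_DAY = 4.0

#: the rate/capacity constants that appear in the model equations, in
#: canonical serialization order
PARAM_NAMES = (
    "S", "gamma", "K", "delta_oe", "delta_r", "mu_i", "delta_i_t",
    "delta_i_re", "mu_re", "phi_BM", "mu_t", "delta_t", "phi_s", "eps_spl",
)

#: the rate constants reported in published best-fit tables (everything
#: except the source inflow S and the carrying capacity K)
RATE_NAMES = tuple(n for n in PARAM_NAMES if n not in ("S", "K"))


@dataclass(frozen=True)
class KineticParameters:
    """Rate and capacity constants of the population model.

    Parameters
    ----------
    S : float
        Source inflow into the pro-/pre-B compartment (cells per 6 h).
    gamma : float
        Maximum pro-/pre-B proliferation rate (per 6 h).
    K : float
        Carrying capacity shared by the pro-/pre-B and BM mature
        recirculating compartments (cells).
    delta_oe : float
        Pro-/pre-B to immature differentiation rate.
    delta_r : float
        Immature to pro-/pre-B reflux rate.
    mu_i : float
        Immature B-cell death rate.
    delta_i_t : float
        Immature to transitional differentiation rate (BM exit to spleen).
    delta_i_re : float
        Immature to BM mature recirculating differentiation rate.
    mu_re : float
        BM mature recirculating death rate.
    phi_BM : float
        Flow rate from the BM mature recirculating pool to the splenic
        mature pool.
    mu_t : float
        Transitional B-cell death rate.
    delta_t : float
        Transitional to splenic mature maturation rate.
    phi_s : float
        Flow rate from the splenic mature pool to the BM mature
        recirculating pool.
    eps_spl : float
        Exit rate from the splenic mature pool (death or emigration to
        other organs).
    """

    S: float
    gamma: float
    K: float
    delta_oe: float
    delta_r: float
    mu_i: float
    delta_i_t: float
    delta_i_re: float
    mu_re: float
    phi_BM: float
    mu_t: float
    delta_t: float
    phi_s: float
    eps_spl: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (v >= 0):  # also rejects NaN
                raise ValueError(f"parameter {f.name} must be >= 0, got {v}")
        if not self.K > 0:
            raise ValueError(f"carrying capacity K must be > 0, got {self.K}")

    def as_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in PARAM_NAMES}

    def replace(self, **changes: float) -> "KineticParameters":
        return replace(self, **changes)

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "KineticParameters":
        unknown = set(d) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        missing = set(PARAM_NAMES) - set(d)
        if missing:
            raise ValueError(f"missing parameter keys: {sorted(missing)}")
        return cls(**{k: float(v) for k, v in d.items()})

    def __iter__(self) -> Iterator[float]:
        return (getattr(self, n) for n in PARAM_NAMES)


def _load_data_yaml(name: str) -> dict:
    with resources.files("bcellkin.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


def load_defaults() -> dict:
    """Package-level defaults (calibration anchor, depletion survival,
    experiment design, noise and sampling settings)."""
    return _load_data_yaml("defaults.yaml")


def table1_rates(group: str) -> dict[str, float]:
    """Published best-fit rate constants for one mouse group.

    Parameters
    ----------
    group : {"control", "depleted"}

    Returns
    -------
    dict
        The 12 rate constants (``S`` and ``K`` are not part of the published
        table; see :func:`bcellkin.model.calibrate_source_and_capacity`).
    """
    if group not in ("control", "depleted"):
        raise ValueError(f"group must be 'control' or 'depleted', got {group!r}")
    return {k: float(v) for k, v in _load_data_yaml(f"table1_{group}_bestfit.yaml").items()}


def table1_ci(group: str) -> dict[str, tuple[float, float]]:
    """Published 95% confidence intervals for the rate constants of one group."""
    if group not in ("control", "depleted"):
        raise ValueError(f"group must be 'control' or 'depleted', got {group!r}")
    raw = _load_data_yaml(f"table1_{group}_ci.yaml")
    return {k: (float(v[0]), float(v[1])) for k, v in raw.items()}


def table1_parameters(group: str) -> KineticParameters:
    """Full parameter set for one group: published best-fit rates with the
    source ``S`` and capacity ``K`` calibrated to the default steady-state
    anchor (see the calibration defaults in ``data/defaults.yaml``)."""
    from .model import calibrate_source_and_capacity  # circular at import time

    rates = table1_rates(group)
    cal = load_defaults()["calibration"]
    result = calibrate_source_and_capacity(
        rates,
        anchor_splenic_mature=cal["anchor_splenic_mature"],
        occupancy=cal["occupancy"],
    )
    return KineticParameters.from_dict({**rates, "S": result.S, "K": result.K})
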