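"""Synthetic measurement cohorts with the study's sampling structure.

The labeling study harvests mice terminally, so every (group, day) cell of
the design is a fresh, cross-sectional set of animals. The generator
simulates the true labeled-fraction trajectory per group and scatters
per-mouse observations around it with Gaussian noise clipped to [0, 1] —
the same observation model the likelihood assumes. It emulates the design
(two groups, measurement days within a week of continuous labeling, a fixed
number of mice per time point, four measured subsets) but none of the raw
cytometry structure (events, gating, spectral spillover), so agreement on
synthetic cohorts validates the estimation machinery, not the instrument
model.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .labeling import ExperimentDesign, predicted_fractions
from .model import DepletionSpec, SteadyStateOptions
from .parameters import KineticParameters, load_defaults

logger = logging.getLogger(__name__)


def default_designs() -> dict[str, ExperimentDesign]:
    """Study-design defaults: control and depleted protocols with a 34-day
    recovery and labeling sampled on days 2, 4 and 7."""
    cfg = load_defaults()
    dep = DepletionSpec(**cfg["depletion"])
    d = cfg["design"]
    common = dict(
        recovery_units=d["recovery_units"],
        labeling_units=d["labeling_units"],
        measurement_days=tuple(d["measurement_days"]),
    )
    return {
        "control": ExperimentDesign(group="control", **common),
        "depleted": ExperimentDesign(group="depleted", depletion=dep, **common),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Ground truth and design for one synthetic cohort."""

    params: Mapping[str, KineticParameters]
    designs: Mapping[str, ExperimentDesign] = field(default_factory=default_designs)
    mice_per_time_point: int = 8
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mice_per_time_point < 1:
            raise ValueError("need at least one mouse per time point")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if set(self.params) != set(self.designs):
            raise ValueError("params and designs must cover the same groups")


def generate_cohort(
    spec: CohortSpec, opts: SteadyStateOptions | None = None
) -> pd.DataFrame:
    """Draw a per-mouse measurement table from the true model.

    For each (group, day, subset) the true labeled fraction is simulated
    once; each mouse then contributes ``clip(truth + noise, 0, 1)``. Mouse
    identifiers are distinct across days (terminal harvests). Deterministic
    given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    n_clipped = 0
    for group in sorted(spec.params):
        design = spec.designs[group]
        pred = predicted_fractions(spec.params[group], design, opts)
        for day in design.measurement_days:
            for m in range(spec.mice_per_time_point):
                mouse_id = f"{group}_d{day:g}_m{m + 1}"
                for subset in design.subsets:
                    truth = pred[(float(day), subset)]
                    raw = truth + rng.normal(0.0, spec.noise_sd) if spec.noise_sd else truth
                    value = float(np.clip(raw, 0.0, 1.0))
                    n_clipped += value != raw
                    rows.append(
                        {
                            "mouse_id": mouse_id,
                            "group": group,
                            "day": float(day),
                            "subset": subset,
                            "labeled_fraction": value,
                        }
                    )
    table = pd.DataFrame(rows)
    if n_clipped > 0.01 * len(table):
        logger.warning(
            "clipped %d of %d synthetic observations to [0, 1]", n_clipped, len(table)
        )
    return table


def generate_totals_ranges(
    true_params: KineticParameters,
    relative_width: float | None = None,
) -> pd.DataFrame:
    """Plausibility ranges for steady-state subset totals.

    Stands in for the unpublished experimentally measured total-cell-number
    ranges: each measured subset's range is its steady-state total times
    ``(1 - width, 1 + width)``.
    """
    from .model import MEASURED_SUBSETS, steady_state_analytic

    if relative_width is None:
        relative_width = load_defaults()["sampling"]["totals_relative_width"]
    if not relative_width > 0:
        raise ValueError("relative width must be > 0")
    ss = steady_state_analytic(true_params)
    rows = [
        {
            "subset": s,
            "lower": getattr(ss, s) * (1.0 - relative_width),
            "upper": getattr(ss, s) * (1.0 + relative_width),
        }
        for s in MEASURED_SUBSETS
    ]
    return pd.DataFrame(rows)


def totals_ranges_dict(table: pd.DataFrame) -> dict[str, tuple[float, float]]:
    """Convert a totals-range table (subset, lower, upper) to the mapping
    consumed by the steady-state filter."""
    return {
        row.subset: (float(row.lower), float(row.upper))
        for row in table.itertuples(index=False)
    }
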