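"""Continuous-labeling (BrdU) extension of the population model.

Each compartment is split into an unlabeled (``U``) and a labeled (``L``)
pool. Only pro-/pre-B cells divide; an unlabeled cell that divides leaves the
unlabeled pool and contributes *two* labeled daughters, while a labeled
divider nets one additional labeled cell. Differentiation, recirculation and
death act identically on both pools (label is assumed non-toxic over the
short, 7-day experiment) and the upstream source is never labeled. With
``lam = 1 - (B_oe + B_Mrec)/K`` evaluated on the totals:

    dUB_oe/dt = S - gamma*lam*UB_oe - delta_oe*UB_oe + delta_r*UB_i
    dLB_oe/dt = gamma*lam*(2*UB_oe + LB_oe) - delta_oe*LB_oe + delta_r*LB_i

and the remaining eight equations replicate the totals-only flows on each
pool. Summing the U and L equations compartmentwise recovers the totals-only
model exactly (mass balance).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import (
    COMPARTMENTS,
    MEASURED_SUBSETS,
    DepletionSpec,
    PopulationState,
    SteadyStateOptions,
    _rhs,
    apply_depletion,
    find_steady_state,
)
from .parameters import UNITS_PER_DAY, KineticParameters


#: output grid spacing during the labeling phase, in 6-h units
_GRID_STEP = 0.25


@dataclass(frozen=True)
class LabeledPopulationState:
    """Unlabeled and labeled cell counts for the five compartments."""

    unlabeled: PopulationState
    labeled: PopulationState

    def totals(self) -> PopulationState:
        return PopulationState.from_array(
            self.unlabeled.as_array() + self.labeled.as_array()
        )

    def as_array(self) -> np.ndarray:
        """Ten-element vector: the five unlabeled pools then the five
        labeled pools."""
        return np.concatenate([self.unlabeled.as_array(), self.labeled.as_array()])

    @classmethod
    def from_array(cls, y: Sequence[float]) -> "LabeledPopulationState":
        y = np.asarray(y, dtype=float)
        if y.shape != (10,):
            raise ValueError(f"expected 10 pools, got shape {y.shape}")
        return cls(
            unlabeled=PopulationState.from_array(y[:5]),
            labeled=PopulationState.from_array(y[5:]),
        )


@dataclass(frozen=True)
class ExperimentDesign:
    """Simulation protocol for one mouse group.

    Control mice are labeled from the steady state; depleted mice are run to
    steady state, depleted instantaneously, left to recover for
    ``recovery_units`` (default 136 units = 34 days), and then labeled.
    ``measurement_days`` are counted from the start of labeling.
    """

    group: str = "control"
    depletion: DepletionSpec | None = None
    recovery_units: float = 136.0
    labeling_units: float = 28.0
    measurement_days: tuple[float, ...] = (2.0, 4.0, 7.0)
    subsets: tuple[str, ...] = MEASURED_SUBSETS

    def __post_init__(self) -> None:
        if self.group not in ("control", "depleted"):
            raise ValueError(f"group must be 'control' or 'depleted', got {self.group!r}")
        if self.labeling_units < 0:
            raise ValueError("labeling duration must be >= 0")
        if self.group == "depleted" and self.recovery_units < 0:
            raise ValueError("recovery interval must be >= 0")
        for d in self.measurement_days:
            if d * UNITS_PER_DAY > self.labeling_units + 1e-9:
                raise ValueError(
                    f"measurement day {d} falls outside the labeling window"
                )
        unknown = set(self.subsets) - set(COMPARTMENTS)
        if unknown:
            raise ValueError(f"unknown subsets: {sorted(unknown)}")


@dataclass(frozen=True)
class LabelingTrajectory:
    """Dense labeled/unlabeled time course over the labeling phase.

    ``times`` are 6-h units from the start of labeling; ``unlabeled`` and
    ``labeled`` are ``(len(times), 5)`` arrays in :data:`COMPARTMENTS`
    order.
    """

    times: np.ndarray
    unlabeled: np.ndarray
    labeled: np.ndarray
    design: ExperimentDesign
    params: KineticParameters = field(repr=False)

    def fractions(self) -> np.ndarray:
        """Labeled fraction L/(U+L) per time and compartment; NaN where a
        compartment is empty."""
        tot = self.unlabeled + self.labeled
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(tot > 0, self.labeled / np.where(tot > 0, tot, 1.0), np.nan)
        return f

    def index_of_day(self, day: float) -> int:
        t = day * UNITS_PER_DAY
        idx = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[idx] - t) > 1e-6:
            raise ValueError(f"day {day} is not on the trajectory grid")
        return idx

    def fraction_at(self, day: float, subset: str) -> float:
        """Labeled fraction of one compartment at one measurement day."""
        return float(self.fractions()[self.index_of_day(day), COMPARTMENTS.index(subset)])

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: one row per (time, compartment)."""
        f = self.fractions()
        rows = []
        for i, t in enumerate(self.times):
            for j, c in enumerate(COMPARTMENTS):
                rows.append(
                    {
                        "time_units": float(t),
                        "day": float(t) / UNITS_PER_DAY,
                        "compartment": c,
                        "unlabeled": self.unlabeled[i, j],
                        "labeled": self.labeled[i, j],
                        "total": self.unlabeled[i, j] + self.labeled[i, j],
                        "labeled_fraction": f[i, j],
                    }
                )
        return pd.DataFrame(rows)


def _rhs_labeled(t: float, y: np.ndarray, p: KineticParameters) -> np.ndarray:
    u_oe, u_i, u_rec, u_t, u_spl, l_oe, l_i, l_rec, l_t, l_spl = y
    lam = 1.0 - ((u_oe + l_oe) + (u_rec + l_rec)) / p.K
    g = p.gamma * lam
    d_i = p.mu_i + p.delta_i_t + p.delta_r + p.delta_i_re
    return np.array(
        [
            p.S - g * u_oe - p.delta_oe * u_oe + p.delta_r * u_i,
            p.delta_oe * u_oe - d_i * u_i,
            p.delta_i_re * u_i + p.phi_s * u_spl - (p.mu_re + p.phi_BM) * u_rec,
            p.delta_i_t * u_i - (p.mu_t + p.delta_t) * u_t,
            p.delta_t * u_t + p.phi_BM * u_rec - (p.phi_s + p.eps_spl) * u_spl,
            g * (2.0 * u_oe + l_oe) - p.delta_oe * l_oe + p.delta_r * l_i,
            p.delta_oe * l_oe - d_i * l_i,
            p.delta_i_re * l_i + p.phi_s * l_spl - (p.mu_re + p.phi_BM) * l_rec,
            p.delta_i_t * l_i - (p.mu_t + p.delta_t) * l_t,
            p.delta_t * l_t + p.phi_BM * l_rec - (p.phi_s + p.eps_spl) * l_spl,
        ]
    )


def labeling_derivatives(
    lstate: LabeledPopulationState, params: KineticParameters
) -> np.ndarray:
    """Rates of change of all ten pools (five unlabeled then five labeled),
    in cells per 6 h."""
    return _rhs_labeled(0.0, lstate.as_array(), params)


def _labeling_grid(duration: float, days: Sequence[float]) -> np.ndarray:
    grid = np.arange(0.0, duration + _GRID_STEP / 2, _GRID_STEP)
    extra = np.array([d * UNITS_PER_DAY for d in days], dtype=float)
    return np.unique(np.concatenate([grid, extra, [duration]]))


def simulate_experiment(
    params: KineticParameters,
    design: ExperimentDesign,
    opts: SteadyStateOptions | None = None,
    steady_state: PopulationState | None = None,
) -> LabelingTrajectory:
    """Run the full labeling protocol for one group.

    Control: integrate from the empty state to steady state, then start
    labeling with all cells unlabeled. Depleted: reach steady state with the
    (depleted) parameter set under evaluation, apply the depletion operator,
    integrate the recovery interval, then label. A precomputed
    ``steady_state`` may be supplied to skip the (deterministic) burn-in.
    """
    opts = opts or SteadyStateOptions()
    if design.group == "depleted" and design.depletion is None:
        raise ValueError("a depleted design requires a depletion spec")
    ss = steady_state if steady_state is not None else find_steady_state(params, opts)

    if design.group == "depleted":
        y0 = apply_depletion(ss, design.depletion).as_array()
        if design.recovery_units > 0:
            sol = solve_ivp(
                _rhs,
                (0.0, design.recovery_units),
                y0,
                args=(params,),
                method="LSODA",
                rtol=opts.rtol,
                atol=opts.atol,
            )
            if not sol.success:
                raise RuntimeError(f"recovery integration failed: {sol.message}")
            y0 = np.clip(sol.y[:, -1], 0.0, None)
        start = y0
    else:
        start = ss.as_array()

    times = _labeling_grid(design.labeling_units, design.measurement_days)
    n = len(times)
    if design.labeling_units == 0:
        unlabeled = np.tile(start, (n, 1))
        labeled = np.zeros((n, 5))
        return LabelingTrajectory(times, unlabeled, labeled, design, params)

    y0 = np.concatenate([start, np.zeros(5)])
    sol = solve_ivp(
        _rhs_labeled,
        (0.0, design.labeling_units),
        y0,
        args=(params,),
        method="LSODA",
        rtol=opts.rtol,
        atol=opts.atol,
        t_eval=times,
    )
    if not sol.success:
        raise RuntimeError(f"labeling integration failed: {sol.message}")
    y = np.clip(sol.y.T, 0.0, None)
    return LabelingTrajectory(times, y[:, :5], y[:, 5:], design, params)


def labeled_fraction_table(
    traj: LabelingTrajectory,
    days: Sequence[float] | None = None,
    subsets: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Labeled fractions at the requested measurement days.

    Returns a tidy frame with columns ``day``, ``subset`` and ``fraction``;
    an empty compartment yields a NaN fraction rather than 0/0.
    """
    days = tuple(days) if days is not None else traj.design.measurement_days
    subsets = tuple(subsets) if subsets is not None else traj.design.subsets
    f = traj.fractions()
    rows = []
    for d in days:
        i = traj.index_of_day(d)
        for s in subsets:
            rows.append(
                {"day": float(d), "subset": s, "fraction": f[i, COMPARTMENTS.index(s)]}
            )
    return pd.DataFrame(rows)


def predicted_fractions(
    params: KineticParameters,
    design: ExperimentDesign,
    opts: SteadyStateOptions | None = None,
    steady_state: PopulationState | None = None,
) -> dict[tuple[float, str], float]:
    """Model-predicted labeled fractions keyed by (day, subset); the
    quantity the likelihood compares against per-mouse measurements."""
    traj = simulate_experiment(params, design, opts, steady_state=steady_state)
    table = labeled_fraction_table(traj)
    return {
        (row.day, row.subset): row.fraction for row in table.itertuples(index=False)
    }
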