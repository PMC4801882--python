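"""Global sensitivity analysis of subset totals.

Inputs are the sampled kinetic rates plus a mouse-type indicator (0 =
control, 1 = depleted); outcomes are the subset totals at the measurement
epoch of each protocol (steady state for control rows; 34 days after
depletion for depleted rows, which have not yet re-equilibrated). Two
summaries are provided: forward stepwise linear regression (multiple R, R^2,
and the partial correlation of each included input) and partial rank
correlation coefficients (PRCC), the rank-based analogue that measures
monotone association after removing the linear effect of the other inputs on
the ranks.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.stats import rankdata

from .inference import ParameterRanges, lhs_matrix
from .model import (
    COMPARTMENTS,
    DepletionSpec,
    SteadyStateError,
    apply_depletion,
    steady_state_analytic,
    _rhs,
)

logger = logging.getLogger(__name__)


class DegenerateOutcomeError(ValueError):
    """Raised when an outcome column has no variance to explain."""


def default_sensitivity_ranges(widen: float = 0.0) -> dict[str, ParameterRanges]:
    """Per-group sampling boxes for sensitivity analysis.

    Rates are sampled over the published per-group CIs (optionally widened);
    the source ``S``, capacity ``K`` and reflux ``delta_r`` are held fixed at
    the default control calibration across all draws, so the outcomes respond
    to the rates alone. (Re-calibrating ``S``/``K`` per draw would pin the
    anchored totals by construction and cancel exactly the responses the
    analysis is meant to measure; holding one ``K`` for both groups also
    matches the finding that the carrying capacity does not differ between
    mouse types.)
    """
    from .parameters import table1_ci, table1_parameters

    ctrl = table1_parameters("control")
    fixed = {"S": ctrl.S, "K": ctrl.K, "delta_r": 0.0}
    out = {}
    for group in ("control", "depleted"):
        ci = table1_ci(group)
        sampled = {}
        for name, (lo, hi) in ci.items():
            w = (hi - lo) * widen
            sampled[name] = (max(0.0, lo - w), hi + w)
        out[group] = ParameterRanges(sampled=sampled, fixed=dict(fixed))
    return out


@dataclass
class SensitivitySample:
    """Paired input/outcome matrices for regression-based sensitivity.

    ``inputs`` has one column per sampled rate plus ``mouse_type``;
    ``outcomes`` has one column per compartment total. Rows with failed
    simulations are dropped and counted in ``n_failed``.
    """

    inputs: pd.DataFrame
    outcomes: pd.DataFrame
    n_failed: int

    def __post_init__(self) -> None:
        if len(self.inputs) != len(self.outcomes):
            raise ValueError("inputs and outcomes must have the same row count")


@dataclass
class SensitivityReport:
    """Stepwise-regression summary for one outcome: overall (multiple)
    Pearson R and R^2 of the final model, and the ordered included inputs
    with their partial correlations given the other included inputs."""

    outcome: str
    r: float
    r2: float
    included: list[tuple[str, float]]
    method: str = "stepwise-linear"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "outcome": self.outcome,
                    "R": self.r,
                    "R2": self.r2,
                    "parameter": name,
                    "partial_R": pr,
                }
                for name, pr in self.included
            ]
        )


def _day34_totals(
    params, depletion: DepletionSpec, recovery_units: float
) -> np.ndarray:
    ss = steady_state_analytic(params)
    y0 = apply_depletion(ss, depletion).as_array()
    sol = solve_ivp(
        _rhs,
        (0.0, recovery_units),
        y0,
        args=(params,),
        method="LSODA",
        rtol=1e-8,
        atol=1e-3,
    )
    if not sol.success:
        raise RuntimeError(f"recovery integration failed: {sol.message}")
    return np.clip(sol.y[:, -1], 0.0, None)


def build_sensitivity_sample(
    ranges: Mapping[str, ParameterRanges],
    n: int,
    seed: int,
    depletion: DepletionSpec | None = None,
    recovery_units: float = 136.0,
) -> SensitivitySample:
    """Monte Carlo sample for sensitivity analysis.

    ``ranges`` maps group name (``control``/``depleted``) to its sampling
    box; each group contributes ``n`` LHS draws, so the sample has up to
    ``2n`` rows. Control outcomes are steady-state totals; depleted
    outcomes are totals at the end of the post-depletion recovery interval.
    """
    if n < 10:
        raise ValueError("need at least 10 draws per group")
    depletion = depletion or DepletionSpec()
    rng = np.random.default_rng(seed)
    in_rows: list[dict] = []
    out_rows: list[dict] = []
    n_failed = 0
    names_ref: tuple[str, ...] | None = None
    for group, grp_ranges in ranges.items():
        mouse_type = 0.0 if group == "control" else 1.0
        names, mat = lhs_matrix(grp_ranges, n, rng)
        if names_ref is None:
            names_ref = names
        elif set(names) != set(names_ref):
            raise ValueError("all groups must sample the same parameters")
        for row in mat:
            values = dict(zip(names, row))
            try:
                params = grp_ranges.complete(values)
                if mouse_type == 0.0:
                    totals = steady_state_analytic(params).as_array()
                else:
                    totals = _day34_totals(params, depletion, recovery_units)
            except (SteadyStateError, RuntimeError, ValueError):
                n_failed += 1
                continue
            in_rows.append({**values, "mouse_type": mouse_type})
            out_rows.append(dict(zip(COMPARTMENTS, totals)))
    if n_failed:
        logger.warning("dropped %d failed simulations", n_failed)
    return SensitivitySample(
        inputs=pd.DataFrame(in_rows), outcomes=pd.DataFrame(out_rows), n_failed=n_failed
    )


def _residualize(y: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Residual of y after least-squares projection on [1, Z]."""
    X = np.column_stack([np.ones(len(y)), Z]) if Z.size else np.ones((len(y), 1))
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta

def partial_correlation(x: np.ndarray, y: np.ndarray, Z: np.ndarray) -> float:
    """Pearson correlation of x and y after removing the linear effect of
    the columns of Z from both."""
    rx = _residualize(np.asarray(x, float), Z)
    ry = _residualize(np.asarray(y, float), Z)
    denom = np.sqrt(np.sum(rx**2) * np.sum(ry**2))
    if denom == 0:
        return 0.0
    return float(np.clip(np.dot(rx, ry) / denom, -1.0, 1.0))


def _r2(y: np.ndarray, X: np.ndarray) -> float:
    resid = _residualize(y, X)
    tss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - float(np.sum(resid**2)) / tss


def stepwise_regression_sensitivity(
    sample: SensitivitySample,
    outcome: str,
    threshold: float = 0.01,
) -> SensitivityReport:
    """Forward stepwise linear regression of one outcome on the inputs.

    Inputs enter in order of the improvement in R^2 they produce; selection
    stops once the best remaining improvement drops below ``threshold``.
    The report carries the final model's multiple R and R^2 and, for every
    included input, its partial correlation given the other included ones.
    """
    if len(sample.inputs) < 10:
        raise ValueError("need at least 10 rows")
    y = sample.outcomes[outcome].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise DegenerateOutcomeError(f"outcome {outcome!r} is constant")
    X = sample.inputs.to_numpy(dtype=float)
    names = list(sample.inputs.columns)
    included: list[int] = []
    r2 = 0.0
    while len(included) < len(names):
        best_gain, best_j, best_r2 = 0.0, None, r2
        for j in range(len(names)):
            if j in included:
                continue
            cand_r2 = _r2(y, X[:, included + [j]])
            if cand_r2 - r2 > best_gain:
                best_gain, best_j, best_r2 = cand_r2 - r2, j, cand_r2
        if best_j is None or best_gain < threshold:
            break
        included.append(best_j)
        r2 = best_r2
    partials = []
    for j in included:
        others = [k for k in included if k != j]
        partials.append(
            (names[j], partial_correlation(X[:, j], y, X[:, others]))
        )
    return SensitivityReport(
        outcome=outcome, r=float(np.sqrt(max(r2, 0.0))), r2=float(r2), included=partials
    )


def prcc(sample: SensitivitySample, outcome: str) -> pd.Series:
    """Partial rank correlation coefficient of every input with one outcome.

    Inputs and outcome are rank-transformed (average ranks on ties); each
    input's coefficient is its partial correlation with the outcome
    controlling for all other inputs. Invariant under strictly monotone
    transformations of any column.
    """
    if len(sample.inputs) < 10:
        raise ValueError("need at least 10 rows")
    ranks_X = np.column_stack(
        [rankdata(sample.inputs[c].to_numpy()) for c in sample.inputs.columns]
    ).astype(float)
    ranks_y = rankdata(sample.outcomes[outcome].to_numpy()).astype(float)
    out = {}
    for j, name in enumerate(sample.inputs.columns):
        others = np.delete(ranks_X, j, axis=1)
        out[name] = partial_correlation(ranks_X[:, j], ranks_y, others)
    return pd.Series(out, name=outcome)
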