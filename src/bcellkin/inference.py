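"""Parameter estimation: Latin hypercube search, steady-state filtering,
Gaussian likelihood, and profile-likelihood confidence intervals.

The search follows the screening-style estimation used for this class of
labeling model: draw ``N`` candidate rate sets by Latin hypercube sampling,
keep those whose steady-state subset totals fall inside experimentally
plausible ranges, score each survivor by the likelihood of the per-mouse
labeled fractions, and take the argmax. Confidence intervals come from the
profile likelihood: a parameter is stepped over a grid, the others are
re-optimized at each step, and the interval collects the grid points where
the likelihood-ratio statistic ``G^2 = 2[lnL(best) - lnL(theta0)]`` stays
below the chi-square(1) quantile (3.84 at the 95% level).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, qmc

from .labeling import ExperimentDesign, predicted_fractions
from .model import (
    MEASURED_SUBSETS,
    InfeasibleTargetError,
    PopulationState,
    SteadyStateError,
    SteadyStateOptions,
    calibrate_source_and_capacity,
    steady_state_analytic,
)
from .parameters import RATE_NAMES, KineticParameters, load_defaults

logger = logging.getLogger(__name__)

MEASUREMENT_COLUMNS = ("mouse_id", "group", "day", "subset", "labeled_fraction")


class FitError(RuntimeError):
    """Raised when no candidate survives the steady-state filter."""


def validate_measurements(data: pd.DataFrame) -> pd.DataFrame:
    """Check a per-mouse measurement table against the expected dialect."""
    missing = set(MEASUREMENT_COLUMNS) - set(data.columns)
    if missing:
        raise ValueError(f"measurement table missing columns: {sorted(missing)}")
    bad_subset = set(data["subset"]) - set(MEASURED_SUBSETS)
    if bad_subset:
        raise ValueError(f"unknown subsets in measurement table: {sorted(bad_subset)}")
    frac = data["labeled_fraction"].to_numpy(dtype=float)
    if np.any(frac < 0) or np.any(frac > 1):
        raise ValueError("labeled_fraction values must lie in [0, 1]")
    return data


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian observation model for per-mouse labeled fractions.

    ``sd`` may be a single standard deviation, a per-subset mapping, or
    ``None`` to profile a per-subset standard deviation out of the
    likelihood in closed form (the maximizing sd is the per-subset RMS
    residual).
    """

    family: str = "gaussian"
    sd: float | Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.family != "gaussian":
            raise ValueError(f"unsupported noise family {self.family!r}")
        if isinstance(self.sd, (int, float)) and not self.sd > 0:
            raise ValueError("fixed sd must be > 0")
        if isinstance(self.sd, Mapping):
            for k, v in self.sd.items():
                if not v > 0:
                    raise ValueError(f"fixed sd for {k} must be > 0")

    def sd_for(self, subset: str) -> float | None:
        if self.sd is None:
            return None
        if isinstance(self.sd, Mapping):
            return float(self.sd[subset])
        return float(self.sd)


@dataclass(frozen=True)
class ParameterRanges:
    """Sampling ranges for the LHS search.

    ``sampled`` maps parameter names to (lower, upper) bounds; ``fixed``
    pins the remaining parameters. Parameters in neither mapping (normally
    ``S`` and ``K``) are completed per candidate by steady-state calibration
    with ``anchor_splenic_mature``/``occupancy``.
    """

    sampled: Mapping[str, tuple[float, float]]
    fixed: Mapping[str, float] = field(default_factory=dict)
    anchor_splenic_mature: float | None = None
    occupancy: float | None = None

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.sampled.items():
            if not (0 <= lo <= hi):
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        overlap = set(self.sampled) & set(self.fixed)
        if overlap:
            raise ValueError(f"parameters both sampled and fixed: {sorted(overlap)}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.sampled)

    def _calibration(self) -> tuple[float, float]:
        cal = load_defaults()["calibration"]
        return (
            self.anchor_splenic_mature or cal["anchor_splenic_mature"],
            self.occupancy or cal["occupancy"],
        )

    def complete(self, values: Mapping[str, float]) -> KineticParameters:
        """Build a full parameter set from sampled values, filling fixed
        entries and calibrating ``S``/``K`` when they are not specified."""
        d = dict(self.fixed)
        d.update({k: float(v) for k, v in values.items()})
        if "S" not in d or "K" not in d:
            anchor, occ = self._calibration()
            rates = {n: d[n] for n in RATE_NAMES}
            res = calibrate_source_and_capacity(
                rates, anchor_splenic_mature=anchor, occupancy=occ
            )
            d.setdefault("S", res.S)
            d.setdefault("K", res.K)
        return KineticParameters.from_dict(d)

    @classmethod
    def from_ci(
        cls,
        ci: Mapping[str, tuple[float, float]],
        widen: float | None = None,
        delta_r_range: tuple[float, float] | None = None,
        **kwargs,
    ) -> "ParameterRanges":
        """Default search box: published CIs widened by ``widen`` times
        their width on each side (floored at 0), plus a reflux-rate range."""
        cfg = load_defaults()["sampling"]
        widen = cfg["ci_widen"] if widen is None else widen
        delta_r_range = tuple(
            cfg["delta_r_range"] if delta_r_range is None else delta_r_range
        )
        sampled = {}
        for name, (lo, hi) in ci.items():
            w = (hi - lo) * widen
            sampled[name] = (max(0.0, lo - w), hi + w)
        sampled["delta_r"] = delta_r_range
        return cls(sampled=sampled, **kwargs)


def lhs_matrix(
    ranges: ParameterRanges, n: int, seed: int | np.random.Generator
) -> tuple[tuple[str, ...], np.ndarray]:
    """Latin hypercube draw: an ``(n, d)`` matrix with exactly one value in
    each of the ``n`` equal-width strata of every sampled range."""
    if n < 1:
        raise ValueError("need at least one sample")
    names = ranges.names
    rng = np.random.default_rng(seed)
    sampler = qmc.LatinHypercube(d=len(names), seed=rng)
    unit = sampler.random(n)
    lo = np.array([ranges.sampled[k][0] for k in names])
    hi = np.array([ranges.sampled[k][1] for k in names])
    return names, lo + unit * (hi - lo)


def lhs_sample(
    ranges: ParameterRanges,
    n: int,
    seed: int | np.random.Generator,
    on_infeasible: str = "raise",
) -> list[KineticParameters]:
    """``n`` complete candidate parameter sets from a Latin hypercube draw,
    deterministic given the seed.

    A draw whose calibration implies a negative source (proliferation alone
    would overshoot the steady-state balance) either raises or is dropped,
    per ``on_infeasible`` ("raise" or "drop").
    """
    if on_infeasible not in ("raise", "drop"):
        raise ValueError("on_infeasible must be 'raise' or 'drop'")
    names, mat = lhs_matrix(ranges, n, seed)
    out = []
    for row in mat:
        try:
            out.append(ranges.complete(dict(zip(names, row))))
        except InfeasibleTargetError:
            if on_infeasible == "raise":
                raise
    return out


@dataclass
class FilterResult:
    """Outcome of the steady-state plausibility screen."""

    passing: list[KineticParameters]
    states: list[PopulationState]
    indices: list[int]
    n_candidates: int
    n_failed: int

    @property
    def n_passing(self) -> int:
        return len(self.passing)


def steady_state_filter(
    candidates: Sequence[KineticParameters],
    total_ranges: Mapping[str, tuple[float, float]],
    opts: SteadyStateOptions | None = None,
) -> FilterResult:
    """Keep candidates whose steady-state subset totals fall inside all the
    supplied ranges.

    The ranges normally come from control-mouse measurements and are applied
    to both mouse types (a depleted set is expected to reconstitute to
    control-like totals). Candidates whose steady state cannot be computed
    count as failed, not passing.
    """
    for subset, (lo, hi) in total_ranges.items():
        if hi < lo:
            raise ValueError(f"range for {subset} has upper < lower")
    passing: list[KineticParameters] = []
    states: list[PopulationState] = []
    indices: list[int] = []
    n_failed = 0
    for i, cand in enumerate(candidates):
        try:
            ss = steady_state_analytic(cand)
        except (SteadyStateError, ValueError):
            n_failed += 1
            continue
        ok = all(
            lo <= getattr(ss, subset) <= hi for subset, (lo, hi) in total_ranges.items()
        )
        if ok:
            passing.append(cand)
            states.append(ss)
            indices.append(i)
    if not passing:
        logger.warning(
            "steady-state filter rejected all %d candidates (%d failed outright)",
            len(candidates),
            n_failed,
        )
    return FilterResult(passing, states, indices, len(candidates), n_failed)


def _gaussian_lnl(residuals: np.ndarray, sd: float | None) -> float:
    """Log-likelihood of one subset's residuals; profiles sd when None."""
    n = residuals.size
    if n == 0:
        return 0.0
    rss = float(np.sum(residuals**2))
    if sd is None:
        if rss == 0.0:
            return math.inf  # degenerate: data exactly on the model
        sd2 = rss / n
        return -0.5 * n * (math.log(2.0 * math.pi * sd2) + 1.0)
    return -n * math.log(sd * math.sqrt(2.0 * math.pi)) - rss / (2.0 * sd**2)


def log_likelihood(
    params: KineticParameters,
    data: pd.DataFrame,
    design: ExperimentDesign,
    noise: NoiseModel | None = None,
    opts: SteadyStateOptions | None = None,
    steady_state: PopulationState | None = None,
) -> float:
    """Gaussian log-likelihood of per-mouse labeled fractions under the
    simulated protocol; returns ``-inf`` when the simulation fails."""
    noise = noise or NoiseModel()
    validate_measurements(data)
    try:
        pred = predicted_fractions(params, design, opts, steady_state=steady_state)
    except (SteadyStateError, RuntimeError, ValueError) as exc:
        logger.debug("simulation failed during likelihood evaluation: %s", exc)
        return -math.inf
    lnl = 0.0
    for subset, sub in data.groupby("subset"):
        obs = sub["labeled_fraction"].to_numpy(dtype=float)
        try:
            mu = np.array([pred[(float(d), subset)] for d in sub["day"]])
        except KeyError as exc:
            raise ValueError(f"no prediction for (day, subset) = {exc}") from None
        if np.any(np.isnan(mu)):
            return -math.inf
        lnl += _gaussian_lnl(obs - mu, noise.sd_for(subset))
    return lnl


@dataclass
class FitResult:
    """Best-fit parameter set with search metadata and (optional) CIs."""

    params: KineticParameters
    log_likelihood: float
    n_candidates: int
    n_passing: int
    seed: int | None
    sampled_names: tuple[str, ...]
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "parameters": self.params.as_dict(),
            "log_likelihood": self.log_likelihood,
            "n_candidates": self.n_candidates,
            "n_passing": self.n_passing,
            "seed": self.seed,
            "sampled_names": list(self.sampled_names),
            "ci": {k: list(v) for k, v in self.ci.items()},
        }


def fit_mle(
    data: pd.DataFrame,
    ranges: ParameterRanges,
    n: int,
    seed: int,
    design: ExperimentDesign,
    noise: NoiseModel | None = None,
    total_ranges: Mapping[str, tuple[float, float]] | None = None,
    opts: SteadyStateOptions | None = None,
) -> FitResult:
    """Latin-hypercube maximum-likelihood fit for one mouse group.

    Evaluates the likelihood for every filter-passing candidate and returns
    the argmax; ties break toward the earliest candidate in sampling order,
    so the result is deterministic given ``(data, ranges, n, seed)``.
    """
    candidates = lhs_sample(ranges, n, seed, on_infeasible="drop")
    n_infeasible = n - len(candidates)
    if n_infeasible:
        logger.info("dropped %d infeasible-calibration candidates", n_infeasible)
    if total_ranges is not None:
        filt = steady_state_filter(candidates, total_ranges, opts)
    else:
        states = []
        kept = []
        idx = []
        n_failed = 0
        for i, c in enumerate(candidates):
            try:
                states.append(steady_state_analytic(c))
            except (SteadyStateError, ValueError):
                n_failed += 1
                continue
            kept.append(c)
            idx.append(i)
        filt = FilterResult(kept, states, idx, n, n_failed)
    if filt.n_passing == 0:
        raise FitError(
            f"no candidate passed the steady-state filter "
            f"({filt.n_candidates} tried, {filt.n_failed} failed outright)"
        )
    best_lnl = -math.inf
    best = None
    for cand, ss in zip(filt.passing, filt.states):
        lnl = log_likelihood(cand, data, design, noise, opts, steady_state=ss)
        if lnl > best_lnl:
            best_lnl = lnl
            best = cand
    logger.info(
        "fit: %d/%d candidates passed filter, best lnL = %.4f",
        filt.n_passing,
        filt.n_candidates,
        best_lnl,
    )
    return FitResult(
        params=best,
        log_likelihood=best_lnl,
        n_candidates=n,
        n_passing=filt.n_passing,
        seed=seed if isinstance(seed, int) else None,
        sampled_names=ranges.names,
    )


@dataclass(frozen=True)
class ProfileCI:
    """Profile-likelihood confidence interval for one parameter."""

    name: str
    lower: float
    upper: float
    censored_lower: bool
    censored_upper: bool
    grid: np.ndarray
    g2: np.ndarray
    alpha: float

    def __iter__(self):
        return iter((self.lower, self.upper))


def likelihood_ratio_cutoff(alpha: float = 0.05) -> float:
    """The ``G^2`` threshold bounding a (1 - alpha) profile-likelihood CI:
    the (1 - alpha) quantile of chi-square with one degree of freedom
    (3.84 at alpha = 0.05)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return float(chi2.ppf(1.0 - alpha, df=1))


def _profile_grid(lo: float, hi: float, size: int) -> np.ndarray:
    if lo > 0 and hi / lo > 10.0:
        return np.geomspace(lo, hi, size)
    return np.linspace(lo, hi, size)


def profile_ci_from_loglik(
    loglik: Callable[[Mapping[str, float]], float],
    ranges: ParameterRanges,
    best_values: Mapping[str, float],
    best_lnl: float,
    param_name: str,
    grid_size: int | None = None,
    alpha: float = 0.05,
    n_draws: int | None = None,
    n_rounds: int | None = None,
    seed: int | np.random.Generator = 0,
) -> ProfileCI:
    """Generic profile-likelihood interval over a sampled-parameter box.

    ``loglik`` maps a full dict of sampled values to a log-likelihood. At
    each grid value of ``param_name`` the remaining (nuisance) parameters
    are re-optimized by repeated Latin-hypercube refinement around the best
    point found so far, warm-starting each grid point at its neighbor's
    optimum.
    """
    cfg = load_defaults()["profile"]
    grid_size = grid_size or cfg["grid_size"]
    n_draws = n_draws or cfg["n_draws"]
    n_rounds = n_rounds or cfg["n_rounds"]
    rng = np.random.default_rng(seed)
    lo, hi = ranges.sampled[param_name]
    grid = np.unique(
        np.concatenate([_profile_grid(lo, hi, grid_size), [best_values[param_name]]])
    )
    nuisance = [k for k in ranges.names if k != param_name]

    def optimize_at(theta0: float, start: dict[str, float]) -> tuple[float, dict]:
        current = dict(start)
        current[param_name] = theta0
        best = loglik(current)
        center = dict(current)
        if not nuisance:
            return best, center
        for r in range(n_rounds):
            shrink = 0.5 * 0.4**r  # half-width as a fraction of the full range
            sub_ranges = {}
            for k in nuisance:
                klo, khi = ranges.sampled[k]
                half = (khi - klo) * shrink
                c = center[k]
                sub_ranges[k] = (max(klo, c - half), min(khi, c + half))
            sub = ParameterRanges(
                sampled=sub_ranges,
                fixed=dict(ranges.fixed),
                anchor_splenic_mature=ranges.anchor_splenic_mature,
                occupancy=ranges.occupancy,
            )
            _, mat = lhs_matrix(sub, n_draws, rng)
            for row in mat:
                trial = dict(zip(nuisance, row))
                trial[param_name] = theta0
                lnl = loglik(trial)
                if lnl > best:
                    best = lnl
                    center = dict(trial)
        return best, center

    # profile outward from the best-fit value in both directions, warm-starting
    order = np.argsort(np.abs(grid - best_values[param_name]), kind="stable")
    profile = np.full(len(grid), -np.inf)
    start_left = dict(best_values)
    start_right = dict(best_values)
    for i in order:
        theta0 = grid[i]
        start = start_left if theta0 <= best_values[param_name] else start_right
        lnl, argmax = optimize_at(float(theta0), start)
        lnl = min(lnl, best_lnl)  # G^2 is non-negative by definition
        profile[i] = lnl
        if theta0 <= best_values[param_name]:
            start_left = argmax
        if theta0 >= best_values[param_name]:
            start_right = argmax
    g2 = 2.0 * (best_lnl - profile)
    cutoff = likelihood_ratio_cutoff(alpha)
    inside = g2 <= cutoff
    accepted = grid[inside]
    lower, upper = float(accepted.min()), float(accepted.max())
    return ProfileCI(
        name=param_name,
        lower=lower,
        upper=upper,
        censored_lower=bool(np.isclose(lower, lo)),
        censored_upper=bool(np.isclose(upper, hi)),
        grid=grid,
        g2=g2,
        alpha=alpha,
    )


def profile_likelihood_ci(
    param_name: str,
    fit: FitResult,
    data: pd.DataFrame,
    ranges: ParameterRanges,
    design: ExperimentDesign,
    noise: NoiseModel | None = None,
    total_ranges: Mapping[str, tuple[float, float]] | None = None,
    grid_size: int | None = None,
    alpha: float = 0.05,
    n_draws: int | None = None,
    n_rounds: int | None = None,
    seed: int = 0,
    opts: SteadyStateOptions | None = None,
) -> ProfileCI:
    """Profile-likelihood CI for one rate of a fitted labeling model.

    Candidates violating the steady-state total ranges (when supplied) score
    ``-inf``, so the interval respects the same plausibility screen as the
    fit. An interval that touches its sampling bound is flagged censored
    rather than silently truncated.
    """
    def loglik(values: Mapping[str, float]) -> float:
        try:
            params = ranges.complete(values)
        except (ValueError, ArithmeticError):
            return -math.inf
        try:
            ss = steady_state_analytic(params)
        except (SteadyStateError, ValueError):
            return -math.inf
        if total_ranges is not None:
            if not all(
                lo <= getattr(ss, subset) <= hi
                for subset, (lo, hi) in total_ranges.items()
            ):
                return -math.inf
        return log_likelihood(params, data, design, noise, opts, steady_state=ss)

    best_values = {k: getattr(fit.params, k) for k in ranges.names}
    return profile_ci_from_loglik(
        loglik,
        ranges,
        best_values,
        fit.log_likelihood,
        param_name,
        grid_size=grid_size,
        alpha=alpha,
        n_draws=n_draws,
        n_rounds=n_rounds,
        seed=seed,
    )
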