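"""Deterministic five-compartment model of B-cell development.

The compartments are the bone-marrow pro-/pre-B (``pro_pre``), immature
(``immature``) and mature recirculating (``mature_recirculating``) pools, and
the splenic transitional (``transitional``) and mature (``splenic_mature``)
pools. Pro-/pre-B cells are the only proliferating population; their division
is throttled logistically by the joint occupancy of the pro-/pre-B and BM
mature recirculating niches relative to the carrying capacity ``K``:

    dB_oe/dt    = S + gamma*B_oe*(1 - (B_oe + B_Mrec)/K) - delta_oe*B_oe
                  + delta_r*B_i
    dB_i/dt     = delta_oe*B_oe - (mu_i + delta_i_t + delta_r + delta_i_re)*B_i
    dB_Mrec/dt  = delta_i_re*B_i + phi_s*B_Mspl - (mu_re + phi_BM)*B_Mrec
    dB_t/dt     = delta_i_t*B_i - (mu_t + delta_t)*B_t
    dB_Mspl/dt  = delta_t*B_t + phi_BM*B_Mrec - (phi_s + eps_spl)*B_Mspl

All rates are per 6-hour unit; populations are cell counts.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .parameters import KineticParameters

#: compartment order used by every array-valued interface in the package
COMPARTMENTS = (
    "pro_pre",
    "immature",
    "mature_recirculating",
    "transitional",
    "splenic_mature",
)

#: the four subsets measured by flow cytometry in the labeling experiment
MEASURED_SUBSETS = (
    "immature",
    "mature_recirculating",
    "transitional",
    "splenic_mature",
)


class SteadyStateError(RuntimeError):
    """Raised when integration does not reach the convergence criterion
    within the allowed horizon."""


class InfeasibleTargetError(ValueError):
    """Raised when calibration targets imply a negative source inflow."""


@dataclass(frozen=True)
class PopulationState:
    """Total cell counts in the five compartments."""

    pro_pre: float
    immature: float
    mature_recirculating: float
    transitional: float
    splenic_mature: float

    def __post_init__(self) -> None:
        for name in COMPARTMENTS:
            v = getattr(self, name)
            if not (v >= 0):
                raise ValueError(f"compartment {name} must be >= 0, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in COMPARTMENTS], dtype=float)

    @classmethod
    def from_array(cls, y: Sequence[float]) -> "PopulationState":
        y = np.asarray(y, dtype=float)
        if y.shape != (5,):
            raise ValueError(f"expected 5 compartments, got shape {y.shape}")
        return cls(*map(float, y))

    def as_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in COMPARTMENTS}

    @classmethod
    def zero(cls) -> "PopulationState":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class DepletionSpec:
    """Instantaneous depletion event: per-compartment survival fractions.

    The default mirrors the antibody-mediated depletion phenotype: pro-/pre-B
    cells are untouched (they do not express the target antigen), about half
    of the immature pool survives, and the mature recirculating, transitional
    and splenic mature pools are fully depleted.
    """

    pro_pre: float = 1.0
    immature: float = 0.5
    mature_recirculating: float = 0.0
    transitional: float = 0.0
    splenic_mature: float = 0.0

    def __post_init__(self) -> None:
        for name in COMPARTMENTS:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(
                    f"survival fraction {name} must be in [0, 1], got {v}"
                )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in COMPARTMENTS], dtype=float)


@dataclass(frozen=True)
class SteadyStateOptions:
    """Convergence control for :func:`find_steady_state`.

    ``tol`` bounds the relative derivative ``|dB/dt| / (B + 1)`` (per 6 h);
    ``max_time`` is the integration horizon in 6-h units (4000 units is about
    3 years of mouse life). ``rtol``/``atol`` are passed to the ODE solver;
    the absolute tolerance is in cells.
    """

    tol: float = 1e-8
    max_time: float = 4000.0
    rtol: float = 1e-8
    atol: float = 1e-3

    def __post_init__(self) -> None:
        if not self.tol > 0:
            raise ValueError("tolerance must be > 0")
        if not self.max_time > 0:
            raise ValueError("max_time must be > 0")


def _rhs(t: float, y: np.ndarray, p: KineticParameters) -> np.ndarray:
    """Right-hand side of the totals-only model (array in, array out)."""
    b_oe, b_i, b_rec, b_t, b_spl = y
    lam = 1.0 - (b_oe + b_rec) / p.K
    return np.array(
        [
            p.S + p.gamma * lam * b_oe - p.delta_oe * b_oe + p.delta_r * b_i,
            p.delta_oe * b_oe
            - (p.mu_i + p.delta_i_t + p.delta_r + p.delta_i_re) * b_i,
            p.delta_i_re * b_i + p.phi_s * b_spl - (p.mu_re + p.phi_BM) * b_rec,
            p.delta_i_t * b_i - (p.mu_t + p.delta_t) * b_t,
            p.delta_t * b_t + p.phi_BM * b_rec - (p.phi_s + p.eps_spl) * b_spl,
        ]
    )


def population_derivatives(
    state: PopulationState, params: KineticParameters
) -> PopulationState:
    """Instantaneous rates of change of the five compartments (cells per 6 h).

    Returns a :class:`PopulationState`-shaped object whose fields hold
    ``dB/dt``; use :func:`population_derivatives_array` when raw arrays are
    more convenient. Raises ``ValueError`` for negative states (enforced by
    the state type) or ``K <= 0`` (enforced by the parameter type).
    """
    dy = _rhs(0.0, state.as_array(), params)
    out = PopulationState.__new__(PopulationState)  # rates may be negative
    for name, v in zip(COMPARTMENTS, dy):
        object.__setattr__(out, name, float(v))
    return out


def population_derivatives_array(
    y: np.ndarray, params: KineticParameters
) -> np.ndarray:
    """Array version of :func:`population_derivatives`."""
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("population state must be non-negative")
    return _rhs(0.0, y, params)


def _converged(y: np.ndarray, params: KineticParameters, tol: float) -> bool:
    dy = _rhs(0.0, y, params)
    return bool(np.max(np.abs(dy) / (y + 1.0)) < tol)


def find_steady_state(
    params: KineticParameters, opts: SteadyStateOptions | None = None
) -> PopulationState:
    """Integrate from the all-zero state until the system settles.

    The convergence criterion is ``max_x |dB_x/dt| / (B_x + 1) < tol``.
    Integration proceeds in windows so the criterion can stop it early;
    failure to converge within ``opts.max_time`` raises
    :class:`SteadyStateError`.
    """
    opts = opts or SteadyStateOptions()
    y = np.zeros(5)
    if _converged(y, params, opts.tol):  # e.g. S == 0: empty system is stable
        return PopulationState.from_array(y)
    t = 0.0
    window = min(500.0, opts.max_time)
    while t < opts.max_time:
        t_end = min(t + window, opts.max_time)
        sol = solve_ivp(
            _rhs,
            (t, t_end),
            y,
            args=(params,),
            method="LSODA",
            rtol=opts.rtol,
            atol=opts.atol,
        )
        if not sol.success:
            raise SteadyStateError(f"integrator failed: {sol.message}")
        y = np.clip(sol.y[:, -1], 0.0, None)
        t = t_end
        if _converged(y, params, opts.tol):
            return PopulationState.from_array(y)
    raise SteadyStateError(
        f"no steady state within {opts.max_time} time units "
        f"(last relative derivative "
        f"{np.max(np.abs(_rhs(0.0, y, params)) / (y + 1.0)):.3g})"
    )


def steady_state_analytic(params: KineticParameters) -> PopulationState:
    """Closed-form fixed point of the model, reachable from the empty state.

    The four downstream balance equations are linear given ``B_oe``, so all
    compartments are proportional to ``B_oe``; substituting the proportions
    into the pro-/pre-B balance leaves one quadratic in ``B_oe``. This is the
    unique attracting fixed point that :func:`find_steady_state` converges
    to, and is used where many parameter sets must be screened quickly.
    """
    p = params
    if p.S == 0.0:
        # from the empty initial condition the system stays empty
        return PopulationState.zero()
    d_i = p.mu_i + p.delta_i_t + p.delta_r + p.delta_i_re
    if d_i <= 0 or (p.mu_t + p.delta_t) <= 0:
        raise ValueError("immature and transitional loss rates must be positive")
    b = p.delta_oe / d_i  # B_i per B_oe
    a = p.delta_i_t / (p.mu_t + p.delta_t)  # B_t per B_i
    # 2x2 linear solve for (B_Mrec, B_Mspl) per unit B_i
    a11 = p.mu_re + p.phi_BM
    a12 = -p.phi_s
    a21 = -p.phi_BM
    a22 = p.phi_s + p.eps_spl
    det = a11 * a22 - a12 * a21
    if det <= 0:
        raise ValueError("mature-pool exchange rates are degenerate")
    r1 = p.delta_i_re
    r2 = p.delta_t * a
    rec_per_i = (a22 * r1 - a12 * r2) / det
    spl_per_i = (a11 * r2 - a21 * r1) / det
    m = rec_per_i * b  # B_Mrec per B_oe
    # quadratic: -gamma*(1+m)/K * x^2 + (gamma - delta_oe + delta_r*b) * x + S = 0
    qa = -p.gamma * (1.0 + m) / p.K
    qb = p.gamma - p.delta_oe + p.delta_r * b
    qc = p.S
    if qa == 0.0:
        if qb >= 0:
            raise SteadyStateError("unbounded growth: no finite steady state")
        b_oe = -qc / qb
    else:
        disc = qb * qb - 4.0 * qa * qc
        b_oe = (-qb - np.sqrt(disc)) / (2.0 * qa)  # the positive root
    b_i = b * b_oe
    return PopulationState(
        pro_pre=float(b_oe),
        immature=float(b_i),
        mature_recirculating=float(rec_per_i * b_i),
        transitional=float(a * b_i),
        splenic_mature=float(spl_per_i * b_i),
    )


def apply_depletion(state: PopulationState, spec: DepletionSpec) -> PopulationState:
    """Instantaneous depletion: multiply each compartment by its survival
    fraction."""
    return PopulationState.from_array(state.as_array() * spec.as_array())


#: death + exit rates defining the mean residence time of each non-source
#: compartment
_RESIDENCE_RATES = {
    "immature": ("mu_i", "delta_i_t", "delta_i_re", "delta_r"),
    "transitional": ("mu_t", "delta_t"),
    "mature_recirculating": ("mu_re", "phi_BM"),
    "splenic_mature": ("phi_s", "eps_spl"),
}


def residence_time(params: KineticParameters, compartment: str) -> float:
    """Mean dwell time in a compartment, ``1 / (death rate + exit rates)``,
    in 6-h units."""
    try:
        rate_names = _RESIDENCE_RATES[compartment]
    except KeyError:
        raise ValueError(
            f"no residence time defined for {compartment!r}; "
            f"choose one of {sorted(_RESIDENCE_RATES)}"
        ) from None
    total = sum(getattr(params, n) for n in rate_names)
    if total <= 0:
        raise ZeroDivisionError(
            f"total loss rate of {compartment} is zero; residence time undefined"
        )
    return 1.0 / total


@dataclass(frozen=True)
class CalibrationResult:
    """Source/capacity constants implied by a steady-state target, together
    with the exactly balance-consistent totals used to derive them."""

    S: float
    K: float
    totals: PopulationState


def calibrate_source_and_capacity(
    rates: Mapping[str, float] | KineticParameters,
    anchor_splenic_mature: float | None = None,
    occupancy: float = 0.5,
    target_totals: PopulationState | None = None,
) -> CalibrationResult:
    """Solve for the unprinted source ``S`` and capacity ``K``.

    Published best-fit tables report the 11 kinetic rates (and ``delta_r``)
    but not ``S`` or ``K``. Given the rates, the steady-state balance
    equations fix every compartment ratio, so one anchor (the splenic mature
    total) plus the requested logistic occupancy ``lambda = 1 - (B_oe +
    B_Mrec)/K`` determine the whole steady state and hence

        K = (B_oe + B_Mrec) / (1 - lambda)
        S = delta_oe*B_oe - gamma*lambda*B_oe - delta_r*B_i.

    If ``target_totals`` is given, its splenic mature entry is used as the
    anchor and the remaining entries are replaced by the nearest
    balance-consistent point (the four downstream balances determine them
    exactly). A negative implied ``S`` raises
    :class:`InfeasibleTargetError`.
    """
    if isinstance(rates, KineticParameters):
        rates = rates.as_dict()
    if not 0.0 < occupancy < 1.0:
        raise ValueError(f"occupancy must be in (0, 1), got {occupancy}")
    if target_totals is not None:
        anchor_splenic_mature = target_totals.splenic_mature
    if anchor_splenic_mature is None or not anchor_splenic_mature > 0:
        raise ValueError("a positive splenic mature anchor is required")

    g = {k: float(rates[k]) for k in rates}
    d_i = g["mu_i"] + g["delta_i_t"] + g["delta_r"] + g["delta_i_re"]
    if d_i <= 0 or (g["mu_t"] + g["delta_t"]) <= 0:
        raise ValueError("immature and transitional loss rates must be positive")
    a = g["delta_i_t"] / (g["mu_t"] + g["delta_t"])
    den = g["mu_re"] + g["phi_BM"]
    if den <= 0:
        raise ValueError("mature recirculating loss rate must be positive")
    # splenic mature balance with B_Mrec eliminated via its own balance
    coef_out = (g["phi_s"] + g["eps_spl"]) - g["phi_BM"] * g["phi_s"] / den
    coef_in = g["delta_t"] * a + g["phi_BM"] * g["delta_i_re"] / den
    if coef_in <= 0 or coef_out <= 0:
        raise InfeasibleTargetError(
            "rates imply no positive steady state for the splenic mature pool"
        )
    b_spl = float(anchor_splenic_mature)
    b_i = b_spl * coef_out / coef_in
    b_t = a * b_i
    b_rec = (g["delta_i_re"] * b_i + g["phi_s"] * b_spl) / den
    b_oe = b_i * d_i / g["delta_oe"]
    K = (b_oe + b_rec) / (1.0 - occupancy)
    S = g["delta_oe"] * b_oe - g["gamma"] * occupancy * b_oe - g["delta_r"] * b_i
    if S < 0:
        raise InfeasibleTargetError(
            f"calibration implies negative source S={S:.3g}; "
            "lower the occupancy or the proliferation rate"
        )
    totals = PopulationState(
        pro_pre=b_oe,
        immature=b_i,
        mature_recirculating=b_rec,
        transitional=b_t,
        splenic_mature=b_spl,
    )
    return CalibrationResult(S=float(S), K=float(K), totals=totals)
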