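"""Well-mixed single-compartment aerosol mass balance.

The compartment concentration C(t) obeys the first-order balance

    V dC/dt = G + P*Q*C_out - (Q + lambda_dep*V + sum(extra sinks)) * C

with V the compartment volume (m3), Q the ventilation flow (m3/h), P the
penetration fraction of supply air, lambda_dep the first-order surface
deposition rate (1/h), G a constant source (quantity/h) and extra sinks
expressed as equivalent clean-air flows (m3/h), e.g. purifier filtration
eta*Q_p. The state unit (number 1/cm3 or mass ng/m3) is carried by the
caller; the model is unit-generic as long as G and C share a quantity unit.

Note on the loss term: the balance is implemented with outflow -Q*C and
deposition -lambda*V*C, i.e. ventilation removes chamber particles. A sign
variant in which ventilation adds particles has no physical reading and is
not supported.

For constant coefficients the closed-form exponential relaxation

    C(t) = C_ss + (C0 - C_ss) * exp(-k_total * t),   k_total = loss rate (1/h)

is the primary solution path. An adaptive numerical integrator is provided
as an independent oracle (and for time-varying supply concentration).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "Compartment",
    "SourceSinkSet",
    "SolutionProfile",
    "NoSteadyStateError",
    "total_loss_rate",
    "steady_state",
    "solve_profile",
    "solve_profile_numeric",
    "closed_chamber_profile",
]


class NoSteadyStateError(ValueError):
    """Raised when the total loss rate is zero so no steady state exists."""


@dataclass(frozen=True)
class Compartment:
    """A single well-mixed air volume.

    volume_m3: compartment volume V (m3), > 0.
    flow_m3_h: ventilation flow Q (m3/h), >= 0.
    penetration: fraction P of supply-air particles entering, in [0, 1].
    lambda_dep_h: first-order surface deposition rate (1/h), >= 0.
    outdoor_conc: supply/outdoor concentration in the state unit, >= 0.
    """

    volume_m3: float
    flow_m3_h: float = 0.0
    penetration: float = 1.0
    lambda_dep_h: float = 0.0
    outdoor_conc: float = 0.0

    def __post_init__(self) -> None:
        if self.volume_m3 <= 0:
            raise ValueError("volume_m3 must be > 0")
        if self.flow_m3_h < 0:
            raise ValueError("flow_m3_h must be >= 0")
        if not 0.0 <= self.penetration <= 1.0:
            raise ValueError("penetration must be in [0, 1]")
        if self.lambda_dep_h < 0:
            raise ValueError("lambda_dep_h must be >= 0")
        if self.outdoor_conc < 0:
            raise ValueError("outdoor_conc must be >= 0")


@dataclass(frozen=True)
class SourceSinkSet:
    """Constant source G (quantity/h) and first-order sink flows (m3/h)."""

    source_rate: float = 0.0
    extra_sink_flows_m3_h: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.source_rate < 0:
            raise ValueError("source_rate must be >= 0")
        if any(f < 0 for f in self.extra_sink_flows_m3_h):
            raise ValueError("sink flows must be >= 0")


@dataclass(frozen=True)
class SolutionProfile:
    """Concentration profile on a time grid, with its asymptote.

    steady_state is None when the loss rate is zero and the profile grows
    without bound.
    """

    times_h: np.ndarray
    concentrations: np.ndarray
    steady_state: float | None
    loss_rate_total_h: float
    state_unit: str = ""


def total_loss_rate(comp: Compartment, sinks: SourceSinkSet = SourceSinkSet()) -> float:
    """Total first-order loss rate k_total (1/h): (Q + lambda*V + sum sinks)/V."""
    q_total = comp.flow_m3_h + sum(sinks.extra_sink_flows_m3_h)
    return (q_total + comp.lambda_dep_h * comp.volume_m3) / comp.volume_m3


def _inflow_rate(comp: Compartment, sinks: SourceSinkSet) -> float:
    """Total constant input G + P*Q*C_out (quantity/h)."""
    return sinks.source_rate + comp.penetration * comp.flow_m3_h * comp.outdoor_conc


def steady_state(comp: Compartment, sinks: SourceSinkSet = SourceSinkSet()) -> float:
    """Steady-state concentration (G + P*Q*C_out) / (Q + lambda*V + sinks)."""
    k = total_loss_rate(comp, sinks)
    if k <= 0.0:
        raise NoSteadyStateError(
            "total loss rate is zero: a sealed compartment with a source has "
            "no steady state (use closed_chamber_profile for linear growth)"
        )
    return _inflow_rate(comp, sinks) / (k * comp.volume_m3)


def _validate_times(times_h: Sequence[float]) -> np.ndarray:
    t = np.asarray(times_h, dtype=float)
    if t.ndim != 1 or t.size < 1:
        raise ValueError("times must be a 1-D grid")
    if t[0] != 0.0:
        raise ValueError("time grid must start at 0")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("time grid must be strictly increasing")
    return t


def solve_profile(
    comp: Compartment,
    sinks: SourceSinkSet,
    c0: float,
    times_h: Sequence[float],
    state_unit: str = "",
) -> SolutionProfile:
    """Closed-form solution for constant coefficients.

    Exponential relaxation toward the steady state when the loss rate is
    positive; linear accumulation when it is zero (sealed compartment).
    """
    if c0 < 0:
        raise ValueError("initial concentration must be >= 0")
    t = _validate_times(times_h)
    k = total_loss_rate(comp, sinks)
    inflow = _inflow_rate(comp, sinks)
    if k > 0.0:
        c_ss = inflow / (k * comp.volume_m3)
        conc = c_ss + (c0 - c_ss) * np.exp(-k * t)
        return SolutionProfile(t, conc, c_ss, k, state_unit)
    conc = c0 + (inflow / comp.volume_m3) * t
    return SolutionProfile(t, conc, None, 0.0, state_unit)


def solve_profile_numeric(
    comp: Compartment,
    sinks: SourceSinkSet,
    c0: float,
    times_h: Sequence[float],
    outdoor_conc: Callable[[float], float] | None = None,
    rtol: float = 1e-12,
    state_unit: str = "",
) -> SolutionProfile:
    """Adaptive ODE integration of the same balance (independent oracle).

    outdoor_conc, if given, is a callable C_out(t_h) overriding the constant
    supply concentration (the one case the closed form cannot handle).
    """
    if c0 < 0:
        raise ValueError("initial concentration must be >= 0")
    t = _validate_times(times_h)
    k = total_loss_rate(comp, sinks)
    v = comp.volume_m3

    def c_out(th: float) -> float:
        return outdoor_conc(th) if outdoor_conc is not None else comp.outdoor_conc

    def rhs(th: float, y: np.ndarray) -> list[float]:
        inflow = sinks.source_rate + comp.penetration * comp.flow_m3_h * c_out(th)
        return [inflow / v - k * y[0]]

    try:
        c_ss: float | None = steady_state(comp, sinks) if outdoor_conc is None else None
    except NoSteadyStateError:
        c_ss = None
    scale = max(abs(c0), abs(c_ss) if c_ss is not None else 0.0, 1e-30)
    if t.size == 1:
        return SolutionProfile(t, np.array([c0]), c_ss, k, state_unit)
    sol = solve_ivp(
        rhs,
        (t[0], t[-1]),
        [c0],
        t_eval=t,
        method="DOP853",
        rtol=rtol,
        atol=1e-13 * scale,
        dense_output=False,
    )
    if not sol.success:  # pragma: no cover - defensive
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return SolutionProfile(t, sol.y[0], c_ss, k, state_unit)


def closed_chamber_profile(
    volume: float, source_rate_per_s: float, c0: float, t_s: float | np.ndarray
) -> float | np.ndarray:
    """Sealed-chamber special case: V dC/dt = G, so C(t) = C0 + G*t/V.

    With Q ~ 0 and negligible surface losses the balance reduces to linear
    accumulation. ``volume`` must be expressed in the volume unit of the
    concentration denominator (cm3 for 1/cm3 number concentrations, m3 for
    ng/m3 mass concentrations); ``t_s`` is in seconds.
    """
    if volume <= 0:
        raise ValueError("volume must be > 0")
    return c0 + source_rate_per_s * np.asarray(t_s, dtype=float) / volume
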