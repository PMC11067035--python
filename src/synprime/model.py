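"""Four-state release-site kinetics: continuous inter-spike evolution and
instantaneous per-spike maps.

Between action potentials the site population obeys a linear ODE whose
forward rates depend on the instantaneous effective calcium concentration:

    dES/dt  = -k1(Ca)*ES + b1*LS
    dLS/dt  =  k1(Ca)*ES - (b1 + k2(Ca))*LS + b2*TS + TSL/b3
    dTS/dt  =  k2(Ca)*LS - b2*TS
    dTSL/dt = -TSL/b3

with k1(Ca) = k1_max * Ca / (Ca + K_M) (Michaelis-Menten saturation) and
k2(Ca) = max(0, k2_0 + s2 * (Ca - Ca_rest)) (linear above rest).  At each
action potential two instantaneous maps act in order: fusion of a fraction
``p_fusion`` of TS and TSL vesicles (freed sites become empty), then
transfer of a fraction ``f_tsl`` of LS vesicles into the labile TSL state.
Total occupancy is conserved by both the flow and the maps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .params import CalciumParameters, PrimingParameters

__all__ = [
    "StateVector",
    "k1_of_ca",
    "k2_of_ca",
    "ca_trace",
    "state_derivative",
    "evolve",
    "apply_ap",
    "resting_steady_state",
    "ts_fraction",
    "StateError",
    "StepSizeError",
    "DegenerateEquilibriumError",
]

_SUM_TOL = 1e-9


class StateError(ValueError):
    """Raised for invalid state vectors or invalid kinetic inputs."""


class StepSizeError(RuntimeError):
    """Raised when an integration step drives occupancies out of range."""


class DegenerateEquilibriumError(ValueError):
    """Raised when the resting equilibrium is undefined (b1 or b2 = 0)."""


@dataclass(frozen=True)
class StateVector:
    """Fractional occupancies of the four site states.

    Components are dimensionless fractions of the total site population and
    must sum to one.
    """

    es: float
    ls: float
    ts: float
    tsl: float = 0.0

    def __post_init__(self) -> None:
        for name in ("es", "ls", "ts", "tsl"):
            value = getattr(self, name)
            if not -_SUM_TOL <= value <= 1.0 + _SUM_TOL:
                raise StateError(f"occupancy {name} = {value!r} outside [0, 1]")
        total = self.es + self.ls + self.ts + self.tsl
        if abs(total - 1.0) > _SUM_TOL:
            raise StateError(f"occupancies sum to {total!r}, expected 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.es, self.ls, self.ts, self.tsl])

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "StateVector":
        es, ls, ts, tsl = (float(x) for x in arr)
        return cls(es=es, ls=ls, ts=ts, tsl=tsl)


def k1_of_ca(ca: float, params: PrimingParameters) -> float:
    """Calcium-dependent docking rate ES -> LS, 1/s.

    Saturating (Michaelis-Menten) in the effective calcium concentration:
    ``k1_max * ca / (ca + K_M)``.
    """
    if ca < 0:
        raise StateError(f"negative calcium concentration: {ca!r}")
    return params.k1_max * ca / (ca + params.K_M)


def k2_of_ca(ca: float, params: PrimingParameters, ca_rest: float = 50.0) -> float:
    """Calcium-dependent priming rate LS -> TS, 1/s.

    Linear in the calcium elevation above rest with slope ``s2``, floored
    at zero: ``max(0, k2_0 + s2 * (ca - ca_rest))``.
    """
    if ca < 0:
        raise StateError(f"negative calcium concentration: {ca!r}")
    return max(0.0, params.k2_0 + params.s2 * (ca - ca_rest))


def ca_trace(
    t: float | np.ndarray,
    ap_times: Sequence[float],
    cap: CalciumParameters,
) -> float | np.ndarray:
    """Effective calcium concentration at time(s) ``t``, nM.

    Each action potential at ``t_j <= t`` contributes
    ``delta_ca * exp(-(t - t_j)/tau_ca)``; contributions superpose linearly
    on top of ``ca_rest``.  The increment is counted from the instant of
    the spike onward (a spike at exactly ``t`` contributes ``delta_ca``).
    """
    ap = np.asarray(ap_times, dtype=float)
    if ap.size > 1 and np.any(np.diff(ap) <= 0):
        raise StateError("ap_times must be strictly increasing")
    t_arr = np.asarray(t, dtype=float)
    dt = t_arr[..., None] - ap
    contrib = np.where(dt >= 0, np.exp(-np.maximum(dt, 0.0) / cap.tau_ca), 0.0)
    out = cap.ca_rest + cap.delta_ca * contrib.sum(axis=-1)
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(out)
    return out


def state_derivative(
    state: StateVector,
    ca: float,
    params: PrimingParameters,
    cap: CalciumParameters,
) -> tuple[float, float, float, float]:
    """Time derivative of (es, ls, ts, tsl), 1/s.  Components sum to zero."""
    k1 = k1_of_ca(ca, params)
    k2 = k2_of_ca(ca, params, cap.ca_rest)
    dock = k1 * state.es
    undock = params.b1 * state.ls
    prime = k2 * state.ls
    deprime = params.b2 * state.ts
    relax = state.tsl / params.b3
    d_es = -dock + undock
    d_ls = dock - undock - prime + deprime + relax
    d_ts = prime - deprime
    d_tsl = -relax
    return (d_es, d_ls, d_ts, d_tsl)


def _derivative_raw(
    es: float,
    ls: float,
    ts: float,
    tsl: float,
    k1: float,
    k2: float,
    params: PrimingParameters,
) -> tuple[float, float, float, float]:
    dock = k1 * es
    undock = params.b1 * ls
    prime = k2 * ls
    deprime = params.b2 * ts
    relax = tsl / params.b3
    return (
        -dock + undock,
        dock - undock - prime + deprime + relax,
        prime - deprime,
        -relax,
    )


def evolve(
    state: StateVector,
    ca_fn: Callable[[float], float],
    duration: float,
    dt: float = 1e-4,
    method: str = "euler",
    params: PrimingParameters | None = None,
    cap: CalciumParameters | None = None,
    t0: float = 0.0,
) -> StateVector:
    """Integrate the inter-spike kinetics for ``duration`` seconds.

    ``ca_fn`` maps absolute time (starting at ``t0``) to effective calcium.
    ``method`` is ``"euler"`` (fixed-step forward Euler, the reference
    integrator) or ``"rk4"`` (classical Runge-Kutta, used as a
    cross-check).  The step count is rounded so that steps tile the
    interval exactly.
    """
    if params is None or cap is None:
        raise TypeError("params and cap are required")
    if duration < 0:
        raise StateError("duration must be non-negative")
    if not dt > 0:
        raise StateError("dt must be strictly positive")
    if duration == 0:
        return state

    n_steps = max(1, round(duration / dt))
    h = duration / n_steps
    es, ls, ts, tsl = state.es, state.ls, state.ts, state.tsl
    ca_rest = cap.ca_rest

    def rates(t: float) -> tuple[float, float]:
        ca = ca_fn(t)
        return (
            k1_of_ca(ca, params),
            k2_of_ca(ca, params, ca_rest),
        )

    if method == "euler":
        for i in range(n_steps):
            k1, k2 = rates(t0 + i * h)
            d = _derivative_raw(es, ls, ts, tsl, k1, k2, params)
            es += h * d[0]
            ls += h * d[1]
            ts += h * d[2]
            tsl += h * d[3]
    elif method == "rk4":
        for i in range(n_steps):
            t = t0 + i * h
            r0 = rates(t)
            rh = rates(t + 0.5 * h)
            r1 = rates(t + h)
            a = _derivative_raw(es, ls, ts, tsl, *r0, params)
            b = _derivative_raw(
                es + 0.5 * h * a[0],
                ls + 0.5 * h * a[1],
                ts + 0.5 * h * a[2],
                tsl + 0.5 * h * a[3],
                *rh,
                params,
            )
            c = _derivative_raw(
                es + 0.5 * h * b[0],
                ls + 0.5 * h * b[1],
                ts + 0.5 * h * b[2],
                tsl + 0.5 * h * b[3],
                *rh,
                params,
            )
            d = _derivative_raw(
                es + h * c[0],
                ls + h * c[1],
                ts + h * c[2],
                tsl + h * c[3],
                *r1,
                params,
            )
            es += h / 6.0 * (a[0] + 2 * b[0] + 2 * c[0] + d[0])
            ls += h / 6.0 * (a[1] + 2 * b[1] + 2 * c[1] + d[1])
            ts += h / 6.0 * (a[2] + 2 * b[2] + 2 * c[2] + d[2])
            tsl += h / 6.0 * (a[3] + 2 * b[3] + 2 * c[3] + d[3])
    else:
        raise ValueError(f"unknown integration method {method!r}")

    return _check_and_pack(es, ls, ts, tsl, dt)


def _check_and_pack(es: float, ls: float, ts: float, tsl: float, dt: float) -> StateVector:
    components = (es, ls, ts, tsl)
    out_of_range_tol = 1e-6
    if any(c < -out_of_range_tol or c > 1.0 + out_of_range_tol for c in components):
        raise StepSizeError(
            f"occupancies {components} left [0, 1]; reduce the integration "
            f"step (dt = {dt})"
        )
    # Flows conserve the sum analytically; clip sub-tolerance float drift.
    es, ls, ts, tsl = (min(max(c, 0.0), 1.0) for c in components)
    total = es + ls + ts + tsl
    if abs(total - 1.0) > _SUM_TOL:
        raise StepSizeError(
            f"total occupancy drifted to {total}; reduce the integration step"
        )
    scale = 1.0 / total
    return StateVector(es=es * scale, ls=ls * scale, ts=ts * scale, tsl=tsl * scale)


def apply_ap(
    state: StateVector, params: PrimingParameters
) -> tuple[StateVector, float]:
    """Instantaneous per-spike map: fusion, then loose-to-labile transfer.

    Returns the post-spike state and the released fraction of sites.
    Release acts on the tight pools present at the moment of the spike;
    vesicles moved into the labile state by the same spike are only
    available from the next spike onward.
    """
    released = params.p_fusion * (state.ts + state.tsl)
    ts = state.ts * (1.0 - params.p_fusion)
    tsl = state.tsl * (1.0 - params.p_fusion)
    es = state.es + released
    moved = params.f_tsl * state.ls
    ls = state.ls - moved
    tsl += moved
    return StateVector(es=es, ls=ls, ts=ts, tsl=tsl), released


def resting_steady_state(
    params: PrimingParameters, cap: CalciumParameters
) -> StateVector:
    """Closed-form fixed point of the kinetics at resting calcium.

    At rest the labile pool is empty and detailed balance gives
    ``TS/LS = k2_0/b2`` and ``LS/ES = k1(ca_rest)/b1``.
    """
    if params.b1 == 0 or params.b2 == 0:
        raise DegenerateEquilibriumError("b1 and b2 must be non-zero")
    k1_rest = k1_of_ca(cap.ca_rest, params)
    ls_over_es = k1_rest / params.b1
    ts_over_ls = params.k2_0 / params.b2
    es = 1.0
    ls = ls_over_es
    ts = ls * ts_over_ls
    total = es + ls + ts
    return StateVector(es=es / total, ls=ls / total, ts=ts / total, tsl=0.0)


def ts_fraction(state: StateVector) -> float:
    """Fraction of docked vesicles that are (stably) tightly docked,
    ``TS/(TS+LS)``."""
    denom = state.ts + state.ls
    if denom <= 0:
        raise StateError("ts_fraction undefined: no docked vesicles (TS+LS = 0)")
    return state.ts / denom


def tsl_decay(tsl0: float, t: float, params: PrimingParameters) -> float:
    """Closed-form relaxation of an isolated labile pool,
    ``tsl0 * exp(-t/b3)``."""
    return tsl0 * math.exp(-t / params.b3)
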