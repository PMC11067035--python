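"""Deterministic protocol simulation: per-AP release fractions, quantal
content and EPSC peak amplitudes."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import (
    StateVector,
    apply_ap,
    resting_steady_state,
)
from .params import CalciumParameters, PrimingParameters
from .protocols import ProtocolSpec

__all__ = ["SimulationResult", "simulate", "normalized_amplitudes"]


@dataclass(frozen=True)
class SimulationResult:
    """Per-AP output of a protocol simulation.

    ``released_fraction`` is the fraction of all sites releasing at each
    AP; ``quanta`` scales it by the site count and ``epsc_pa`` by the
    quantal size.  ``states_pre``/``states_post`` hold the state vector
    immediately before and after each AP's instantaneous maps.
    """

    protocol: ProtocolSpec
    released_fraction: np.ndarray
    quanta: np.ndarray
    epsc_pa: np.ndarray
    states_pre: tuple[StateVector, ...]
    states_post: tuple[StateVector, ...]

    def __post_init__(self) -> None:
        n = self.protocol.n_ap
        if not (
            len(self.released_fraction) == len(self.quanta) == len(self.epsc_pa) == n
        ):
            raise ValueError("per-AP arrays must match the protocol's AP count")


def _integrate_interval(
    es: float,
    ls: float,
    ts: float,
    tsl: float,
    elev: float,
    duration: float,
    dt: float,
    method: str,
    params: PrimingParameters,
    cap: CalciumParameters,
) -> tuple[float, float, float, float, float]:
    """Advance the state over one inter-AP interval.

    ``elev`` is the calcium elevation above rest at the start of the
    interval; it decays exponentially and is updated exactly per step, so
    arbitrary spike histories reduce to a single scalar.
    """
    if duration <= 0:
        return es, ls, ts, tsl, elev
    n_steps = max(1, round(duration / dt))
    h = duration / n_steps
    decay = math.exp(-h / cap.tau_ca)
    b1 = params.b1
    b2 = params.b2
    inv_b3 = 1.0 / params.b3
    k1_max = params.k1_max
    km = params.K_M
    k2_0 = params.k2_0
    s2 = params.s2
    ca_rest = cap.ca_rest

    if method == "euler":
        for _ in range(n_steps):
            ca = ca_rest + elev
            k1 = k1_max * ca / (ca + km)
            k2 = k2_0 + s2 * elev
            dock = k1 * es
            undock = b1 * ls
            prime = k2 * ls
            deprime = b2 * ts
            relax = tsl * inv_b3
            es += h * (undock - dock)
            ls += h * (dock - undock - prime + deprime + relax)
            ts += h * (prime - deprime)
            tsl -= h * relax
            elev *= decay
    elif method == "rk4":
        half_decay = math.exp(-0.5 * h / cap.tau_ca)

        def deriv(
            es_: float, ls_: float, ts_: float, tsl_: float, elev_: float
        ) -> tuple[float, float, float, float]:
            ca = ca_rest + elev_
            k1 = k1_max * ca / (ca + km)
            k2 = k2_0 + s2 * elev_
            dock = k1 * es_
            undock = b1 * ls_
            prime = k2 * ls_
            deprime = b2 * ts_
            relax = tsl_ * inv_b3
            return (
                undock - dock,
                dock - undock - prime + deprime + relax,
                prime - deprime,
                -relax,
            )

        for _ in range(n_steps):
            e_mid = elev * half_decay
            e_end = elev * decay
            a = deriv(es, ls, ts, tsl, elev)
            b = deriv(
                es + 0.5 * h * a[0],
                ls + 0.5 * h * a[1],
                ts + 0.5 * h * a[2],
                tsl + 0.5 * h * a[3],
                e_mid,
            )
            c = deriv(
                es + 0.5 * h * b[0],
                ls + 0.5 * h * b[1],
                ts + 0.5 * h * b[2],
                tsl + 0.5 * h * b[3],
                e_mid,
            )
            d = deriv(
                es + h * c[0],
                ls + h * c[1],
                ts + h * c[2],
                tsl + h * c[3],
                e_end,
            )
            es += h / 6.0 * (a[0] + 2 * b[0] + 2 * c[0] + d[0])
            ls += h / 6.0 * (a[1] + 2 * b[1] + 2 * c[1] + d[1])
            ts += h / 6.0 * (a[2] + 2 * b[2] + 2 * c[2] + d[2])
            tsl += h / 6.0 * (a[3] + 2 * b[3] + 2 * c[3] + d[3])
            elev = e_end
    else:
        raise ValueError(f"unknown integration method {method!r}")
    return es, ls, ts, tsl, elev


def simulate(
    protocol: ProtocolSpec,
    params: PrimingParameters,
    cap: CalciumParameters,
    dt: float = 1e-4,
    method: str = "euler",
    initial_state: StateVector | None = None,
) -> SimulationResult:
    """Run a stimulation protocol through the model.

    The state starts at the resting steady state (sweeps in the underlying
    experiments are separated by 30-60 s, ample for full recovery), evolves
    continuously between spikes under the decaying calcium transient, and
    undergoes the instantaneous fusion/transfer maps at each spike.  The
    result is deterministic given parameters and integrator settings.
    """
    state = initial_state or resting_steady_state(params, cap)
    es, ls, ts, tsl = state.es, state.ls, state.ts, state.tsl
    elev = 0.0
    t = protocol.ap_times[0]
    released = np.empty(protocol.n_ap)
    pre: list[StateVector] = []
    post: list[StateVector] = []
    for i, t_ap in enumerate(protocol.ap_times):
        es, ls, ts, tsl, elev = _integrate_interval(
            es, ls, ts, tsl, elev, t_ap - t, dt, method, params, cap
        )
        t = t_ap
        state = StateVector(es=es, ls=ls, ts=ts, tsl=tsl)
        pre.append(state)
        state, rel = apply_ap(state, params)
        post.append(state)
        es, ls, ts, tsl = state.es, state.ls, state.ts, state.tsl
        released[i] = rel
        elev += cap.delta_ca
    quanta = params.n_sites * released
    return SimulationResult(
        protocol=protocol,
        released_fraction=released,
        quanta=quanta,
        epsc_pa=quanta * params.q,
        states_pre=tuple(pre),
        states_post=tuple(post),
    )


def normalized_amplitudes(
    result: SimulationResult | np.ndarray,
    reference: str = "first_ap",
    protocol: ProtocolSpec | None = None,
) -> np.ndarray:
    """Amplitudes normalized to a reference response.

    ``reference="first_ap"`` divides by the first amplitude of the whole
    protocol; ``"first_of_segment"`` divides every AP by the first
    amplitude of its own segment.
    """
    if isinstance(result, SimulationResult):
        amps = result.epsc_pa
        proto = result.protocol
    else:
        amps = np.asarray(result, dtype=float)
        proto = protocol
    if reference == "first_ap":
        ref = amps[0]
        if ref == 0:
            raise ZeroDivisionError("reference amplitude is zero")
        return amps / ref
    if reference == "first_of_segment":
        if proto is None:
            raise ValueError("a protocol is required for per-segment normalization")
        out = np.empty_like(amps, dtype=float)
        labels = proto.segment_labels
        seg_start = 0
        for i in range(len(amps)):
            if i > 0 and labels[i] != labels[i - 1]:
                seg_start = i
            ref = amps[seg_start]
            if ref == 0:
                raise ZeroDivisionError("reference amplitude is zero")
            out[i] = amps[i] / ref
        return out
    raise ValueError(f"unknown reference {reference!r}")
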