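"""Summary statistics of EPSC amplitude trains and derived model quantities.

These are the quantities on which the biological conclusions rest: the
paired-pulse ratio, the steady-state depression level, recovery ratios
after conditioning trains, the per-site release probability
``Pv = P_fusion * TS fraction``, quantal conversion, and fold changes
between pharmacological conditions.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .protocols import PRECONDITIONING, RECOVERY, TRAIN, ProtocolSpec
from .simulate import SimulationResult

__all__ = [
    "paired_pulse_ratio",
    "steady_state_ratio",
    "recovery_ratio",
    "pv",
    "quantal_content",
    "fold_change",
    "round_sig",
]


class MetricError(ValueError):
    pass


def _amps(train: Sequence[float] | SimulationResult) -> np.ndarray:
    if isinstance(train, SimulationResult):
        return train.epsc_pa
    return np.asarray(train, dtype=float)


def paired_pulse_ratio(
    train: Sequence[float] | SimulationResult, i: int = 2, j: int = 1
) -> float:
    """Ratio of the ``i``-th to the ``j``-th amplitude (1-based), PPR_i/j."""
    a = _amps(train)
    denom = a[j - 1]
    if denom == 0:
        raise MetricError(f"paired-pulse ratio undefined: amplitude {j} is zero")
    return float(a[i - 1] / denom)


def steady_state_ratio(
    train: Sequence[float] | SimulationResult, k_last: int = 3
) -> float:
    """Mean of the last ``k_last`` amplitudes over the first amplitude.

    Quantifies the depression (or facilitation) level reached at the end
    of a constant-frequency train.
    """
    a = _amps(train)
    if len(a) <= k_last:
        raise MetricError(f"train of length {len(a)} too short for k_last={k_last}")
    if a[0] == 0:
        raise MetricError("steady-state ratio undefined: first amplitude is zero")
    return float(a[-k_last:].mean() / a[0])


def recovery_ratio(
    result: SimulationResult | Sequence[float],
    reference: str = "first_of_first_train",
    protocol: ProtocolSpec | None = None,
) -> float:
    """First recovery-segment amplitude relative to a reference response.

    ``reference`` selects the denominator: ``"first_of_first_train"`` uses
    the very first amplitude of the protocol; ``"first_of_preconditioning"``
    uses the first amplitude of the preconditioning segment (the convention
    used for the complex protocols at the facilitating connection; identical
    when the preconditioning train opens the protocol).
    """
    if isinstance(result, SimulationResult):
        amps = result.epsc_pa
        proto = result.protocol
    else:
        amps = np.asarray(result, dtype=float)
        proto = protocol
    if proto is None:
        raise MetricError("a protocol with segment labels is required")
    rec = proto.segment_indices(RECOVERY)
    if not rec:
        raise MetricError("protocol has no recovery segment")
    if reference == "first_of_first_train":
        ref_idx = 0
    elif reference == "first_of_preconditioning":
        pre = proto.segment_indices(PRECONDITIONING)
        if not pre:
            raise MetricError("protocol has no preconditioning segment")
        ref_idx = pre[0]
    else:
        raise MetricError(f"unknown reference {reference!r}")
    denom = amps[ref_idx]
    if denom == 0:
        raise MetricError("recovery ratio undefined: reference amplitude is zero")
    return float(amps[rec[0]] / denom)


def pv(p_fusion: float, ts_fraction: float) -> float:
    """Per-site vesicular release probability, ``P_fusion * P_TS``.

    The probability that a docked vesicle is released by a single action
    potential: it must be in the fusion-competent tight state (probability
    ``ts_fraction``) and then fuse (probability ``p_fusion``).
    """
    for name, value in (("p_fusion", p_fusion), ("ts_fraction", ts_fraction)):
        if not 0.0 <= value <= 1.0:
            raise MetricError(f"{name} must lie in [0, 1], got {value!r}")
    return p_fusion * ts_fraction

def quantal_content(amplitude_pa: float | np.ndarray, q: float) -> float | np.ndarray:
    """Convert EPSC peak amplitude(s) to quantal content (released vesicles)."""
    if not q > 0:
        raise MetricError("quantal size must be positive")
    return amplitude_pa / q


def fold_change(a: float, b: float) -> float:
    """Ratio ``a / b``, e.g. a parameter under drug over its control value."""
    if b == 0:
        raise MetricError("fold change undefined: reference value is zero")
    return a / b


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (reported ratios use two)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))
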