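"""Parameter containers for the sequential two-step priming/fusion model.

The model describes a population of presynaptic release sites that cycle
through four states: empty (ES), loosely docked (LS), tightly docked (TS)
and a labile tightly docked state (TSL).  Vesicles dock into empty sites
(ES -> LS, rate ``k1``), mature into the fusion-competent tight state
(LS -> TS, rate ``k2``) and can un-dock or de-prime (``b1``, ``b2``).  Both
forward rates are sensitive to the effective intracellular calcium
concentration; the fusion probability is not.  On each action potential a
fraction ``f_tsl`` of loosely docked vesicles is transferred to the labile
tight state, from which they relax back to LS with time constant ``b3``.
Tight-state vesicles (TS and TSL) fuse with probability ``p_fusion`` per
action potential.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields, replace

__all__ = [
    "PrimingParameters",
    "CalciumParameters",
    "RATE_PARAM_NAMES",
    "FSIN_PARAMS",
    "OLM_PARAMS",
    "DEFAULT_CALCIUM",
    "CALCIUM_4AP",
]

#: Kinetic parameters that are legal targets of the fitting machinery
#: (everything except the scaling constants n_sites and q).
RATE_PARAM_NAMES = (
    "b1",
    "k1_max",
    "K_M",
    "k2_0",
    "s2",
    "b2",
    "b3",
    "f_tsl",
    "p_fusion",
)


class ParameterError(ValueError):
    """Raised when a parameter set violates its invariants."""


@dataclass(frozen=True)
class PrimingParameters:
    """Kinetic and scaling constants of the four-state priming scheme.

    Parameters
    ----------
    b1 : float
        Un-docking rate LS -> ES, 1/s.
    k1_max : float
        Saturating maximum of the calcium-dependent docking rate ES -> LS, 1/s.
    K_M : float
        Half-saturation calcium concentration of the docking rate, nM.
    k2_0 : float
        Forward priming rate LS -> TS at resting calcium, 1/s.
    s2 : float
        Slope of the calcium dependence of the priming rate, 1/(s*nM).
    b2 : float
        Backward rate TS -> LS, 1/s.
    b3 : float
        Decay time constant with which TSL relaxes back to LS, s.
    f_tsl : float
        Fraction of LS vesicles transferred to the labile tight state after
        each action potential, dimensionless in [0, 1].
    p_fusion : float
        Per-action-potential fusion probability of TS and TSL vesicles.
    n_sites : float
        Total number of docking sites; scales fractional release to quanta.
    q : float
        Quantal size, pA of EPSC peak amplitude per released vesicle.
    """

    b1: float
    k1_max: float
    K_M: float
    k2_0: float
    s2: float
    b2: float
    b3: float
    f_tsl: float
    p_fusion: float
    n_sites: float = 25.0
    q: float = 32.0

    def __post_init__(self) -> None:
        for name in ("b1", "k1_max", "K_M", "b2", "b3", "n_sites", "q"):
            value = getattr(self, name)
            if not value > 0:
                raise ParameterError(f"{name} must be strictly positive, got {value!r}")
        for name in ("k2_0", "s2"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        for name in ("f_tsl", "p_fusion"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {value!r}")
        # Physiological parameter sets have a labile tight state that is much
        # shorter-lived than the stable one (b3 << 1/b2); warn, don't fail.
        if self.b3 >= 1.0 / self.b2:
            warnings.warn(
                f"b3 = {self.b3} s is not smaller than 1/b2 = {1.0 / self.b2} s; "
                "the labile tight state outlives the stable one",
                stacklevel=2,
            )

    def replace(self, **changes: float) -> "PrimingParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, data: dict[str, float]) -> "PrimingParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**data)


@dataclass(frozen=True)
class CalciumParameters:
    """Effective presynaptic calcium dynamics.

    ``ca_rest`` is the resting effective concentration, ``delta_ca`` the
    jump added by each action potential, and ``tau_ca`` the exponential
    decay time constant of each jump.  Increments superpose linearly.
    """

    ca_rest: float = 50.0  # nM
    delta_ca: float = 110.0  # nM per AP
    tau_ca: float = 0.14  # s

    def __post_init__(self) -> None:
        if self.ca_rest < 0:
            raise ParameterError("ca_rest must be non-negative")
        if self.delta_ca < 0:
            raise ParameterError("delta_ca must be non-negative")
        if not self.tau_ca > 0:
            raise ParameterError("tau_ca must be strictly positive")

    def replace(self, **changes: float) -> "CalciumParameters":
        return replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, data: dict[str, float]) -> "CalciumParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown calcium parameter keys: {sorted(unknown)}")
        return cls(**data)


DEFAULT_CALCIUM = CalciumParameters()

#: Calcium parameters under 4-aminopyridine: the potassium-channel block
#: broadens the action potential, raising the per-AP calcium increment from
#: 110 nM to 168 nM while resting calcium stays at 50 nM.
CALCIUM_4AP = CalciumParameters(ca_rest=50.0, delta_ca=168.0, tau_ca=0.14)

# ---------------------------------------------------------------------------
# Reference parameter sets.
#
# The constants that characterise the two connection types are the fitted
# fusion probability and the resting tight-state fraction: a depressing
# pyramidal-cell -> fast-spiking-interneuron (FSIN) connection with
# p_fusion = 0.6 and TS/(TS+LS) = 0.44 at rest, and a facilitating
# pyramidal-cell -> O-LM interneuron connection with p_fusion = 0.36 and a
# resting tight-state fraction of 0.07.  At rest TS/LS = k2_0/b2, so k2_0
# encodes the tight-state fraction once b2 is fixed.  b3 ~ 40 ms and
# 1/b2 ~ 50*b3 place the labile state's lifetime far below the stable
# one's.  Per-AP transfer of ~20% of loose vesicles into the labile state
# drives high-frequency facilitation.  The two connection types differ only
# in k2_0, s2 and p_fusion (and in the amplitude scaling n_sites); every
# other kinetic constant is shared.  The remaining constants (k1_max, K_M,
# b1, s2 and the calcium decay tau_ca) are calibrated once, by weighted
# least squares, so that the depressing set reproduces the measured
# grand-average phenotype: frequency-dependent steady-state depression
# (~0.48 / 0.37 / 0.14 of the first response at 5 / 20 / 100 Hz), a
# paired-pulse ratio near 0.7, and ~56% recovery 110 ms after a 100 Hz
# train; see docs/methods.md for the calibration procedure and residuals.
# ---------------------------------------------------------------------------

_B2 = 0.5  # 1/s
_B3 = 0.04  # s

FSIN_PARAMS = PrimingParameters(
    b1=0.1,
    k1_max=4.4,
    K_M=410.0,
    k2_0=_B2 * 0.44 / 0.56,  # resting TS fraction 0.44
    s2=0.024,
    b2=_B2,
    b3=_B3,
    f_tsl=0.2,
    p_fusion=0.6,
    n_sites=21.0,
    q=32.0,
)

OLM_PARAMS = FSIN_PARAMS.replace(
    k2_0=_B2 * 0.07 / 0.93,  # resting TS fraction 0.07
    s2=0.0024,
    p_fusion=0.36,
    n_sites=24.0,
    q=32.0,
)
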