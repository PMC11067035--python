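"""Pharmacology scenarios as constraint transformations on fit problems.

Two manipulations dissociate fusion from priming:

* 4-aminopyridine (4-AP) broadens the presynaptic action potential and
  raises the AP-evoked calcium influx; in the model this is purely a
  larger per-AP calcium increment (110 -> 168 nM) with resting calcium
  unchanged.  A fit under this constraint should attribute the enhanced
  release to fusion (``p_fusion``), not to the resting tight-state pool.
* Phorbol dibutyrate (PDBU) activates Munc13 and enhances priming without
  changing calcium influx; the fit therefore clamps all calcium
  parameters to their control values and frees the priming/fusion
  constants, so any enhancement must surface in the priming rates (and
  hence the tight-state fraction).

Both transformations are pure functions: inputs are never mutated.
"""

from __future__ import annotations

from .fitting import FitProblem
from .params import CalciumParameters, RATE_PARAM_NAMES

__all__ = ["SCENARIOS", "apply_4ap", "apply_pdbu_constraints", "apply_scenario"]

#: Per-AP calcium increment under 4-AP, nM (a ~50% rise over the 110 nM
#: control value, matching the measured increase in AP-evoked influx).
DELTA_CA_4AP = 168.0


def apply_4ap(cap: CalciumParameters) -> CalciumParameters:
    """Calcium parameters under 4-AP: increment raised to 168 nM, resting
    calcium fixed at 50 nM.  Idempotent."""
    return cap.replace(ca_rest=50.0, delta_ca=DELTA_CA_4AP)


def apply_pdbu_constraints(
    problem: FitProblem, control_cap: CalciumParameters | None = None
) -> FitProblem:
    """Constrain a fit problem for PDBU data.

    Calcium parameters are fixed to the control condition's values; all
    priming/fusion parameters are freed.
    """
    cap = control_cap if control_cap is not None else problem.cap
    return problem.replace(cap=cap, free=tuple(RATE_PARAM_NAMES))


def apply_4ap_constraints(
    problem: FitProblem, free: tuple[str, ...] = tuple(RATE_PARAM_NAMES)
) -> FitProblem:
    """Constrain a fit problem for 4-AP data: calcium increment raised,
    priming/fusion parameters free."""
    return problem.replace(cap=apply_4ap(problem.cap), free=free)


SCENARIOS = {
    "control": lambda problem: problem,
    "4ap": apply_4ap_constraints,
    "pdbu": apply_pdbu_constraints,
}


def apply_scenario(name: str, problem: FitProblem) -> FitProblem:
    try:
        transform = SCENARIOS[name]
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}"
        ) from None
    return transform(problem)
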