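"""Joint multi-protocol fitting of model parameters to per-AP release data.

The objective is the root-mean-square deviation (rmsd) between modelled
and observed per-site release fractions (quantal content divided by the
site count), pooled over every action potential of every protocol in the
problem with equal weight.  Optimization is bounded local least squares
in log10 parameter space, restarted from log-uniform draws within the
bounds (plus one warm start at the base parameter values), so results are
reproducible given the seed.

Two constrained variants mirror the analysis workflow: an exhaustive
parameter-subset ladder (which single/double/triple parameter changes
convert one connection type's model into the other's) and a shared
scaling-factor fit in which ``k2_0`` and ``s2`` move together by one
common factor while only that factor and ``p_fusion`` are free.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .model import resting_steady_state, ts_fraction, k1_of_ca
from .metrics import pv
from .params import (
    CalciumParameters,
    PrimingParameters,
    RATE_PARAM_NAMES,
)
from .protocols import ProtocolSpec
from .simulate import simulate

__all__ = [
    "FitProblem",
    "FitResult",
    "DEFAULT_BOUNDS",
    "rmsd_objective",
    "fit",
    "subset_ladder",
    "scaled_fit",
    "OptimizationFailure",
]


class FitError(ValueError):
    pass


class OptimizationFailure(RuntimeError):
    """No optimization start converged; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics: list[str]):
        super().__init__(message + "\n" + "\n".join(diagnostics))
        self.diagnostics = diagnostics


#: Default box bounds for the kinetic parameters.  Rates span 1e-3..1e3 1/s,
#: the labile-state lifetime 1..1000 ms, the half-saturation concentration
#: 1..1e4 nM, the priming-rate slope up to 1 (1/(s*nM)), and fractions and
#: probabilities live in (0, 1] with a tiny positive floor so that
#: log-space optimization stays defined.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "b1": (1e-3, 1e3),
    "k1_max": (1e-3, 1e3),
    "K_M": (1.0, 1e4),
    "k2_0": (1e-4, 1e3),
    "s2": (1e-7, 1.0),
    "b2": (1e-3, 1e3),
    "b3": (1e-3, 1.0),
    "f_tsl": (1e-4, 1.0),
    "p_fusion": (1e-4, 1.0),
}


@dataclass(frozen=True)
class FitProblem:
    """Datasets, protocols and constraints defining one fitting task.

    ``datasets`` maps protocol names to observed per-AP quantal contents
    (grand-average amplitudes already divided by the quantal size).  The
    calcium parameters are fixed during fitting; the free kinetic
    parameters are named in ``free``.
    """

    datasets: Mapping[str, np.ndarray]
    protocols: Mapping[str, ProtocolSpec]
    base_params: PrimingParameters
    cap: CalciumParameters
    free: tuple[str, ...] = ()
    bounds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    dt: float = 1e-4

    def __post_init__(self) -> None:
        for name in self.free:
            if name not in RATE_PARAM_NAMES:
                raise FitError(
                    f"{name!r} is not a fittable parameter "
                    f"(choose from {RATE_PARAM_NAMES})"
                )
        for name, data in self.datasets.items():
            if name not in self.protocols:
                raise FitError(f"dataset {name!r} has no protocol definition")
            if len(data) != self.protocols[name].n_ap:
                raise FitError(
                    f"dataset {name!r} has {len(data)} values but protocol "
                    f"defines {self.protocols[name].n_ap} APs"
                )
        object.__setattr__(
            self,
            "datasets",
            {k: np.asarray(v, dtype=float) for k, v in self.datasets.items()},
        )

    def replace(self, **changes) -> "FitProblem":
        from dataclasses import replace as _replace

        return _replace(self, **changes)


@dataclass(frozen=True)
class FitResult:
    """Best parameter set found, with its objective value and derived
    resting quantities."""

    params: PrimingParameters
    rmsd: float
    per_protocol_rmsd: dict[str, float]
    free: tuple[str, ...]
    ts_fraction_rest: float
    pv_rest: float
    k1_0: float
    seed: int | None = None
    n_starts: int = 0
    n_converged: int = 0
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "rmsd": self.rmsd,
            "per_protocol_rmsd": dict(self.per_protocol_rmsd),
            "free": list(self.free),
            "ts_fraction_rest": self.ts_fraction_rest,
            "pv_rest": self.pv_rest,
            "k1_0": self.k1_0,
            "seed": self.seed,
            "n_starts": self.n_starts,
            "n_converged": self.n_converged,
            "extra": dict(self.extra),
        }


def _residuals(
    params: PrimingParameters, problem: FitProblem
) -> tuple[np.ndarray, dict[str, float]]:
    """Per-AP residual vector (model minus data, per-site fractions) and
    per-protocol rmsd."""
    pieces = []
    per_protocol: dict[str, float] = {}
    n_sites = problem.base_params.n_sites
    for name in sorted(problem.datasets):
        data_rf = problem.datasets[name] / n_sites
        result = simulate(
            problem.protocols[name], params, problem.cap, dt=problem.dt
        )
        res = result.released_fraction - data_rf
        per_protocol[name] = float(np.sqrt(np.mean(res**2)))
        pieces.append(res)
    return np.concatenate(pieces), per_protocol


def rmsd_objective(params: PrimingParameters, problem: FitProblem) -> float:
    """Pooled rmsd between modelled and observed per-site release fractions."""
    res, _ = _residuals(params, problem)
    return float(np.sqrt(np.mean(res**2)))


def _make_result(
    params: PrimingParameters,
    problem: FitProblem,
    free: tuple[str, ...],
    seed: int | None,
    n_starts: int,
    n_converged: int,
    extra: dict | None = None,
) -> FitResult:
    res, per_protocol = _residuals(params, problem)
    rmsd = float(np.sqrt(np.mean(res**2)))
    rest = resting_steady_state(params, problem.cap)
    tsf = ts_fraction(rest)
    return FitResult(
        params=params,
        rmsd=rmsd,
        per_protocol_rmsd=per_protocol,
        free=free,
        ts_fraction_rest=tsf,
        pv_rest=pv(params.p_fusion, tsf),
        k1_0=k1_of_ca(problem.cap.ca_rest, params),
        seed=seed,
        n_starts=n_starts,
        n_converged=n_converged,
        extra=extra or {},
    )


def _multistart_least_squares(
    vector_to_params: Callable[[np.ndarray], PrimingParameters],
    x_warm: np.ndarray,
    log_bounds: tuple[np.ndarray, np.ndarray],
    problem: FitProblem,
    n_starts: int,
    seed: int,
) -> tuple[np.ndarray, int, list[str]]:
    """Run bounded least squares from a warm start plus log-uniform draws.

    Parameter vectors are log10-transformed.  Returns the best solution,
    the number of converged starts, and per-start diagnostics.
    """
    lo, hi = log_bounds
    rng = np.random.default_rng(seed)
    starts = [np.clip(x_warm, lo, hi)]
    starts += [rng.uniform(lo, hi) for _ in range(max(0, n_starts - 1))]

    def fun(z: np.ndarray) -> np.ndarray:
        # candidate parameter sets explored by the optimizer may violate
        # soft physiological expectations; only the returned set matters
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            res, _ = _residuals(vector_to_params(10.0**z), problem)
        return res

    best_x = None
    best_cost = np.inf
    n_converged = 0
    diagnostics: list[str] = []
    for i, x0 in enumerate(starts):
        try:
            sol = least_squares(
                fun, x0, bounds=(lo, hi), method="trf", xtol=1e-10, ftol=1e-10
            )
        except Exception as err:  # noqa: BLE001 — record and move on
            diagnostics.append(f"start {i}: raised {err!r}")
            continue
        diagnostics.append(
            f"start {i}: status={sol.status} cost={sol.cost:.3e} nfev={sol.nfev}"
        )
        if sol.status > 0:
            n_converged += 1
            if sol.cost < best_cost:
                best_cost = sol.cost
                best_x = sol.x
    if best_x is None:
        raise OptimizationFailure("no optimization start converged", diagnostics)
    return best_x, n_converged, diagnostics


def fit(
    problem: FitProblem,
    n_starts: int = 10,
    seed: int = 0,
) -> FitResult:
    """Multi-start bounded fit of the problem's free parameters.

    With no free parameters the base parameters are returned together
    with their rmsd (useful for evaluating a fixed model on data).
    """
    free = problem.free
    if not free:
        return _make_result(problem.base_params, problem, free, seed, 0, 0)

    lo = np.array([math.log10(problem.bounds[n][0]) for n in free])
    hi = np.array([math.log10(problem.bounds[n][1]) for n in free])
    base = problem.base_params

    def vector_to_params(values: np.ndarray) -> PrimingParameters:
        changes = {
            n: min(v, 1.0) if n in ("f_tsl", "p_fusion") else v
            for n, v in zip(free, values)
        }
        return base.replace(**changes)

    x_warm = np.array(
        [
            math.log10(
                min(max(getattr(base, n), problem.bounds[n][0]), problem.bounds[n][1])
            )
            for n in free
        ]
    )
    best_x, n_conv, diagnostics = _multistart_least_squares(
        vector_to_params, x_warm, (lo, hi), problem, n_starts, seed
    )
    return _make_result(
        vector_to_params(10.0**best_x),
        problem,
        free,
        seed,
        n_starts,
        n_conv,
        extra={"diagnostics": diagnostics},
    )


def subset_ladder(
    problem: FitProblem,
    base_params: PrimingParameters | None = None,
    subset_sizes: Sequence[int] = (1, 2, 3),
    candidates: Sequence[str] = RATE_PARAM_NAMES,
    n_starts: int = 4,
    seed: int = 0,
) -> dict[int, list[FitResult]]:
    """Exhaustive fits of every parameter subset of each requested size.

    Starting from ``base_params`` (e.g. the depressing connection's best
    fit), every combination of ``size`` candidate parameters is freed and
    fitted; results per size are ranked by rmsd.  This identifies the
    smallest parameter change that converts one release phenotype into
    another.
    """
    base = base_params or problem.base_params
    out: dict[int, list[FitResult]] = {}
    for size in subset_sizes:
        results = []
        for combo in itertools.combinations(candidates, size):
            sub = problem.replace(free=tuple(combo), base_params=base)
            results.append(fit(sub, n_starts=n_starts, seed=seed))
        results.sort(key=lambda r: r.rmsd)
        out[size] = results
    return out


def scaled_fit(
    problem: FitProblem,
    base_params: PrimingParameters | None = None,
    n_starts: int = 10,
    seed: int = 0,
    scale_bounds: tuple[float, float] = (1e-4, 1e2),
) -> FitResult:
    """Fit a common scaling factor for ``k2_0`` and ``s2`` plus ``p_fusion``.

    The second priming step's resting rate and calcium sensitivity move
    together: ``k2_0 = g * k2_0_base`` and ``s2 = g * s2_base``.  Only the
    factor ``g`` and the fusion probability are free; everything else stays
    at the base values.  The fitted factor is reported in
    ``result.extra["scale_factor"]``.
    """
    base = base_params or problem.base_params
    if base.k2_0 <= 0 or base.s2 <= 0:
        raise FitError("scaled_fit requires strictly positive base k2_0 and s2")

    pf_lo, pf_hi = problem.bounds["p_fusion"]
    lo = np.array([math.log10(scale_bounds[0]), math.log10(pf_lo)])
    hi = np.array([math.log10(scale_bounds[1]), math.log10(pf_hi)])

    def vector_to_params(values: np.ndarray) -> PrimingParameters:
        g, pf = values
        return base.replace(k2_0=g * base.k2_0, s2=g * base.s2, p_fusion=min(pf, 1.0))

    x_warm = np.array([0.0, math.log10(max(base.p_fusion, pf_lo))])
    best_x, n_conv, diagnostics = _multistart_least_squares(
        vector_to_params, x_warm, (lo, hi), problem, n_starts, seed
    )
    g, pf = 10.0**best_x
    return _make_result(
        vector_to_params(10.0**best_x),
        problem,
        ("k2_0", "s2", "p_fusion"),
        seed,
        n_starts,
        n_conv,
        extra={"scale_factor": float(g), "diagnostics": diagnostics},
    )
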