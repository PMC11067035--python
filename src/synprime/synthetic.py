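"""Synthetic paired-recording datasets generated from known model parameters.

Emulates the structure of paired whole-cell recordings: a number of
connected cell pairs, each with its own connection strength (a single
multiplicative lognormal scale standing in for synapse count and size,
with the across-pair coefficient of variation matched to the recorded
populations, CV ~ 0.76-0.87), repeated stimulation trials per protocol,
optional binomial quantal release (which produces transmission failures
at weak connections), and additive Gaussian trial noise.  Per-pair mean
trains are averaged into a grand-total average (GTA) train per protocol,
the quantity the model is fitted to.

The seed hierarchy is deterministic: a master seed plus the pair index
fixes the pair strength; master seed, pair index and protocol name fix
the trial stream.  Identical configurations therefore yield identical
datasets.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .params import CalciumParameters, PrimingParameters
from .protocols import ProtocolSpec
from .simulate import SimulationResult, simulate

__all__ = [
    "GeneratorConfig",
    "generate_pair",
    "generate_dataset",
    "grand_total_average",
    "gta_tables",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the synthetic-data generator.

    ``pair_cv`` is the across-pair coefficient of variation of connection
    strength; the strength distribution is lognormal with mean 1, so the
    expected GTA equals the deterministic simulation.  ``noise_sd_pa`` is
    additive Gaussian noise per trial and AP.  With ``binomial=True`` the
    released quantal content is drawn per trial as Binomial(n_sites,
    released fraction) instead of its deterministic mean, producing
    realistic failures at low release probability.
    """

    params: PrimingParameters
    cap: CalciumParameters
    n_pairs: int = 25
    pair_cv: float = 0.76
    noise_sd_pa: float = 2.0
    trials_per_pair: int = 10
    binomial: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.pair_cv < 0:
            raise ValueError("pair_cv must be non-negative")
        if self.noise_sd_pa < 0:
            raise ValueError("noise_sd_pa must be non-negative")
        if self.trials_per_pair < 1:
            raise ValueError("trials_per_pair must be >= 1")


def _pair_scale(config: GeneratorConfig, pair_index: int) -> float:
    """Lognormal connection strength with mean 1 and CV ``pair_cv``."""
    if config.pair_cv == 0:
        return 1.0
    sigma2 = np.log1p(config.pair_cv**2)
    rng = np.random.default_rng([config.seed, 1000003, pair_index])
    return float(rng.lognormal(mean=-0.5 * sigma2, sigma=np.sqrt(sigma2)))


def _trial_rng(
    config: GeneratorConfig, pair_index: int, protocol: ProtocolSpec
) -> np.random.Generator:
    proto_key = zlib.crc32(protocol.name.encode())
    return np.random.default_rng([config.seed, 2000029, pair_index, proto_key])


def generate_pair(
    config: GeneratorConfig,
    protocol: ProtocolSpec,
    pair_index: int,
    deterministic: SimulationResult | None = None,
) -> np.ndarray:
    """Per-trial EPSC amplitude matrix for one pair, shape
    (trials_per_pair, n_ap), pA.

    ``deterministic`` may pass in a pre-computed simulation of the
    generating parameters to avoid re-integration across pairs.
    """
    sim = deterministic or simulate(protocol, config.params, config.cap)
    scale = _pair_scale(config, pair_index)
    rng = _trial_rng(config, pair_index, protocol)
    n_trials = config.trials_per_pair
    p = config.params
    if config.binomial:
        n_sites = int(round(p.n_sites))
        quanta = rng.binomial(
            n_sites, sim.released_fraction, size=(n_trials, protocol.n_ap)
        )
    else:
        quanta = np.broadcast_to(sim.quanta, (n_trials, protocol.n_ap))
    amps = scale * quanta * p.q
    if config.noise_sd_pa > 0:
        amps = amps + rng.normal(0.0, config.noise_sd_pa, size=amps.shape)
    return np.maximum(amps, 0.0)


def generate_dataset(
    config: GeneratorConfig, protocols: Mapping[str, ProtocolSpec]
) -> pd.DataFrame:
    """Long-format synthetic dataset over all pairs and protocols.

    Columns: pair_id, protocol, trial, ap_index, amplitude_pA.
    """
    frames = []
    for name in sorted(protocols):
        proto = protocols[name]
        sim = simulate(proto, config.params, config.cap)
        for pair in range(config.n_pairs):
            amps = generate_pair(config, proto, pair, deterministic=sim)
            n_trials, n_ap = amps.shape
            frames.append(
                pd.DataFrame(
                    {
                        "pair_id": pair,
                        "protocol": name,
                        "trial": np.repeat(np.arange(n_trials), n_ap),
                        "ap_index": np.tile(np.arange(n_ap), n_trials),
                        "amplitude_pA": amps.ravel(),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def grand_total_average(per_pair_means: Sequence[Sequence[float]] | np.ndarray) -> np.ndarray:
    """Unweighted across-pair mean of per-pair mean amplitude trains."""
    arr = np.asarray(per_pair_means, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 1:
        raise ValueError("expected a (n_pairs, n_ap) array with at least one pair")
    return arr.mean(axis=0)


def study_gta(
    params: PrimingParameters,
    cap: CalciumParameters,
    protocols: Mapping[str, ProtocolSpec],
    seed: int = 0,
    n_pairs: int = 25,
    pair_cv: float = 0.76,
    noise_sd_pa: float = 2.0,
    trials_per_pair: int = 10,
) -> dict[str, np.ndarray]:
    """GTA amplitude train per protocol, each from its own pair cohort.

    Emulates the recorded studies, in which each stimulation protocol's
    grand average comes from a different set of recorded pairs (e.g. 12,
    20 and 21 pairs for the three simple trains; 30 vs 20 pairs for the
    two complex protocols).  Independent cohorts decorrelate the
    across-protocol connection-strength sampling error, which a joint
    multi-protocol fit then averages down.  Cohort seeds are spawned
    deterministically from ``seed``.
    """
    out: dict[str, np.ndarray] = {}
    children = np.random.SeedSequence(seed).spawn(len(protocols))
    for child, name in zip(children, sorted(protocols)):
        config = GeneratorConfig(
            params=params,
            cap=cap,
            n_pairs=n_pairs,
            pair_cv=pair_cv,
            noise_sd_pa=noise_sd_pa,
            trials_per_pair=trials_per_pair,
            binomial=True,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        dataset = generate_dataset(config, {name: protocols[name]})
        out[name] = gta_tables(dataset)[name]
    return out


def gta_tables(dataset: pd.DataFrame) -> dict[str, np.ndarray]:
    """Grand-total-average amplitude train per protocol from a long-format
    dataset (mean over trials within pair, then over pairs)."""
    out: dict[str, np.ndarray] = {}
    for name, sub in dataset.groupby("protocol"):
        per_pair = sub.groupby(["pair_id", "ap_index"])["amplitude_pA"].mean().unstack()
        out[str(name)] = grand_total_average(per_pair.to_numpy())
    return out
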