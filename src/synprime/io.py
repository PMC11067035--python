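"""Readers and writers for parameter files, protocol definitions and
simulation/data tables.

File conventions: JSON for parameters, protocols and fit results; CSV
(comma-separated, '.' decimal, UTF-8, mandatory header) for amplitude
tables.  Times are seconds, concentrations nM, amplitudes pA.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .fitting import FitResult
from .params import CalciumParameters, PrimingParameters
from .protocols import ProtocolSpec, TRAIN, build_train, concat_with_gap
from .simulate import SimulationResult

__all__ = [
    "save_params",
    "load_params",
    "save_protocol",
    "load_protocol",
    "simulation_to_frame",
    "save_simulation",
    "save_dataset",
    "load_dataset",
    "save_fit_result",
]

PRIMING_UNITS = {
    "b1": "1/s",
    "k1_max": "1/s",
    "K_M": "nM",
    "k2_0": "1/s",
    "s2": "1/(s*nM)",
    "b2": "1/s",
    "b3": "s",
    "f_tsl": "fraction",
    "p_fusion": "probability",
    "n_sites": "count",
    "q": "pA",
}

CALCIUM_UNITS = {"ca_rest": "nM", "delta_ca": "nM", "tau_ca": "s"}


def save_params(
    path: str | Path,
    params: PrimingParameters,
    cap: CalciumParameters | None = None,
) -> None:
    doc: dict = {"priming": params.to_dict(), "units": dict(PRIMING_UNITS)}
    if cap is not None:
        doc["calcium"] = cap.to_dict()
        doc["units"].update(CALCIUM_UNITS)
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def load_params(
    path: str | Path,
) -> tuple[PrimingParameters, CalciumParameters | None]:
    doc = json.loads(Path(path).read_text())
    allowed = {"priming", "calcium", "units"}
    unknown = set(doc) - allowed
    if unknown:
        raise ValueError(f"unknown keys in parameter file {path}: {sorted(unknown)}")
    params = PrimingParameters.from_dict(doc["priming"])
    cap = CalciumParameters.from_dict(doc["calcium"]) if "calcium" in doc else None
    return params, cap


def save_protocol(path: str | Path, protocol: ProtocolSpec) -> None:
    """Write a protocol as a segment list (regular trains with gaps)."""
    segments = []
    labels = protocol.segment_labels
    times = protocol.ap_times
    start = 0
    for i in range(1, len(times) + 1):
        boundary = i == len(times) or labels[i] != labels[i - 1]
        if boundary:
            seg_times = times[start:i]
            n = len(seg_times)
            freq = 1.0 / (seg_times[1] - seg_times[0]) if n > 1 else None
            gap = (
                seg_times[0] - times[start - 1]
                if start > 0
                else seg_times[0]
            )
            segments.append(
                {
                    "n_ap": n,
                    "freq_hz": freq,
                    "gap_before_s": gap,
                    "label": labels[start],
                }
            )
            start = i
    Path(path).write_text(
        json.dumps({"name": protocol.name, "segments": segments}, indent=2) + "\n"
    )


def load_protocol(path: str | Path) -> ProtocolSpec:
    doc = json.loads(Path(path).read_text())
    proto: ProtocolSpec | None = None
    for seg in doc["segments"]:
        freq = seg["freq_hz"] if seg["freq_hz"] else 1.0
        piece = build_train(
            seg["n_ap"], freq, t0=0.0, label=seg.get("label", TRAIN)
        )
        if proto is None:
            shift = seg.get("gap_before_s", 0.0)
            piece = ProtocolSpec(
                name=doc["name"],
                ap_times=tuple(t + shift for t in piece.ap_times),
                segment_labels=piece.segment_labels,
            )
            proto = piece
        else:
            proto = concat_with_gap(
                proto, seg["gap_before_s"], piece, name=doc["name"]
            )
    if proto is None:
        raise ValueError(f"protocol file {path} defines no segments")
    return proto


def simulation_to_frame(result: SimulationResult) -> pd.DataFrame:
    proto = result.protocol
    return pd.DataFrame(
        {
            "protocol": proto.name,
            "ap_index": np.arange(proto.n_ap),
            "t_s": np.asarray(proto.ap_times),
            "segment": list(proto.segment_labels),
            "released_fraction": result.released_fraction,
            "quanta": result.quanta,
            "epsc_pA": result.epsc_pa,
        }
    )


def save_simulation(path: str | Path, result: SimulationResult) -> None:
    simulation_to_frame(result).to_csv(path, index=False)


def save_dataset(path: str | Path, dataset: pd.DataFrame) -> None:
    dataset.to_csv(path, index=False)


def load_dataset(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_fit_result(path: str | Path, result: FitResult) -> None:
    doc = result.to_dict()
    doc["extra"].pop("diagnostics", None)
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")
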