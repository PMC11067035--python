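"""Stimulation protocols: ordered action-potential times with segment labels.

The experimental battery consists of seven protocols built from regular
trains: three simple trains (15 APs at 5 Hz, 6 APs at 20 Hz, 15 APs at
100 Hz — the last followed by a recovery test train), two depletion/
recovery pairs (6 + 6 APs at 100 Hz with 110 ms or 1.5 s between them),
and two "complex" protocols in which a 6-AP 20 Hz preconditioning train
is immediately followed by 15 APs at 100 Hz and a 6-AP 100 Hz recovery
test train after 110 ms or 1.5 s.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "ProtocolSpec",
    "build_train",
    "concat_with_gap",
    "standard_protocols",
    "PRECONDITIONING",
    "TRAIN",
    "RECOVERY",
]

PRECONDITIONING = "preconditioning"
TRAIN = "train"
RECOVERY = "recovery"

#: Interval between the last preconditioning spike and the first
#: high-frequency spike in the complex protocols.  The preconditioning
#: train runs at 20 Hz and is immediately followed by the 100 Hz train,
#: so the transition keeps the 20 Hz inter-spike interval.
COMPLEX_TRANSITION_GAP = 0.05


class ProtocolError(ValueError):
    pass


@dataclass(frozen=True)
class ProtocolSpec:
    """An ordered list of action-potential times with per-AP segment tags."""

    name: str
    ap_times: tuple[float, ...]
    segment_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.ap_times) == 0:
            raise ProtocolError("a protocol needs at least one AP")
        if any(b <= a for a, b in zip(self.ap_times, self.ap_times[1:])):
            raise ProtocolError("ap_times must be strictly increasing")
        labels = self.segment_labels or tuple([TRAIN] * len(self.ap_times))
        if len(labels) != len(self.ap_times):
            raise ProtocolError("one segment label per AP required")
        # each label must form one contiguous block
        seen: set[str] = set()
        for prev, cur in zip(labels, labels[1:]):
            if cur != prev:
                if cur in seen:
                    raise ProtocolError(f"segment {cur!r} is not contiguous")
                seen.add(prev)
        object.__setattr__(self, "segment_labels", labels)

    @property
    def n_ap(self) -> int:
        return len(self.ap_times)

    @property
    def span(self) -> float:
        """Time from the first to the last AP, s."""
        return self.ap_times[-1] - self.ap_times[0]

    def segment_indices(self, label: str) -> list[int]:
        return [i for i, lab in enumerate(self.segment_labels) if lab == label]

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "ap_times": list(self.ap_times),
                "segment_labels": list(self.segment_labels),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ProtocolSpec":
        data = json.loads(text)
        return cls(
            name=data["name"],
            ap_times=tuple(data["ap_times"]),
            segment_labels=tuple(data["segment_labels"]),
        )


def build_train(
    n_ap: int, freq: float, t0: float = 0.0, label: str = TRAIN, name: str | None = None
) -> ProtocolSpec:
    """Regular train of ``n_ap`` action potentials at ``freq`` Hz starting
    at ``t0``."""
    if n_ap < 1:
        raise ProtocolError("n_ap must be >= 1")
    if not freq > 0:
        raise ProtocolError("freq must be positive")
    times = tuple(t0 + i / freq for i in range(n_ap))
    return ProtocolSpec(
        name=name or f"{freq:g}hz{n_ap}",
        ap_times=times,
        segment_labels=tuple([label] * n_ap),
    )


def concat_with_gap(
    a: ProtocolSpec, gap: float, b: ProtocolSpec, name: str | None = None
) -> ProtocolSpec:
    """Concatenate two protocols so that the interval from ``a``'s last AP
    to ``b``'s first AP equals ``gap`` (last-spike-to-first-spike
    convention).  Segment labels are preserved."""
    if not gap > 0:
        raise ProtocolError("gap must be positive")
    shift = a.ap_times[-1] + gap - b.ap_times[0]
    times = a.ap_times + tuple(t + shift for t in b.ap_times)
    labels = a.segment_labels + b.segment_labels
    return ProtocolSpec(
        name=name or f"{a.name}+{b.name}", ap_times=times, segment_labels=labels
    )


def standard_protocols() -> dict[str, ProtocolSpec]:
    """The seven-protocol experimental battery, keyed by name."""
    rec6 = build_train(6, 100.0, label=RECOVERY)

    p5 = build_train(15, 5.0, name="5hz15")
    p20 = build_train(6, 20.0, name="20hz6")
    p100_15_rec = concat_with_gap(
        build_train(15, 100.0), 0.110, rec6, name="100hz15_rec110"
    )
    p100_6_rec110 = concat_with_gap(
        build_train(6, 100.0), 0.110, rec6, name="100hz6_rec110"
    )
    p100_6_rec1500 = concat_with_gap(
        build_train(6, 100.0), 1.5, rec6, name="100hz6_rec1500"
    )
    precond = build_train(6, 20.0, label=PRECONDITIONING)
    core = concat_with_gap(precond, COMPLEX_TRANSITION_GAP, build_train(15, 100.0))
    complex110 = concat_with_gap(core, 0.110, rec6, name="complex_rec110")
    complex1500 = concat_with_gap(core, 1.5, rec6, name="complex_rec1500")

    out = [
        p5,
        p20,
        p100_15_rec,
        p100_6_rec110,
        p100_6_rec1500,
        complex110,
        complex1500,
    ]
    return {p.name: p for p in out}


#: Protocols the depressing-connection battery uses for its five-protocol
#: joint fit: the three simple trains and the two short-train recovery
#: protocols (the 100 Hz simple train is the pre-recovery part of
#: ``100hz15_rec110``).
SIMPLE_FIT_PROTOCOLS = (
    "5hz15",
    "20hz6",
    "100hz15_rec110",
    "100hz6_rec110",
    "100hz6_rec1500",
)

#: The two complex protocols (the only ones recorded at the facilitating
#: connection).
COMPLEX_PROTOCOLS = ("complex_rec110", "complex_rec1500")
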