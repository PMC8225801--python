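"""The seven-state disease space for Barrett esophagus progression.

States run from no Barrett esophagus (NoBE) through non-dysplastic BE
(NDBE), low- and high-grade dysplasia (LGD, HGD) and early/late esophageal
adenocarcinoma (EAC) to the absorbing Dead state.
"""
from __future__ import annotations

from enum import IntEnum


class HealthState(IntEnum):
    NO_BE = 0
    NDBE = 1
    LGD = 2
    HGD = 3
    EARLY_EAC = 4
    LATE_EAC = 5
    DEAD = 6

    @property
    def is_alive(self) -> bool:
        return self is not HealthState.DEAD

    @property
    def label(self) -> str:
        return _LABELS[self]


_LABELS = {
    HealthState.NO_BE: "NoBE",
    HealthState.NDBE: "NDBE",
    HealthState.LGD: "LGD",
    HealthState.HGD: "HGD",
    HealthState.EARLY_EAC: "EarlyEAC",
    HealthState.LATE_EAC: "LateEAC",
    HealthState.DEAD: "Dead",
}
_FROM_LABEL = {v: k for k, v in _LABELS.items()}

N_STATES = len(HealthState)
ALIVE_STATES = tuple(s for s in HealthState if s.is_alive)
#: States that can carry prevalent, screen-detectable disease at entry.
DISEASE_STATES = (
    HealthState.NDBE,
    HealthState.LGD,
    HealthState.HGD,
    HealthState.EARLY_EAC,
)


def state_from_label(label: str) -> HealthState:
    try:
        return _FROM_LABEL[label]
    except KeyError:
        raise ValueError(f"unknown health state label: {label!r}") from None
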