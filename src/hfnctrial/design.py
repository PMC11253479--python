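"""Interim and final decision rules of the adaptive design.

At each of the three interim analyses the trial stops for superiority if
P(HR > 1) exceeds 0.99, or for futility if P(HR < 1.15) exceeds 0.8
(an HR below 1.15 corresponds to less than about a 4-hour reduction in
median weaning time).  At the final analysis the intervention is declared
superior if P(HR > 1) exceeds 0.9, "statistically promising" if it exceeds
0.8, futile if P(HR < 1.15) exceeds 0.8, and inconclusive otherwise.  All
thresholds are strict inequalities ("exceeds"), and superiority is checked
before futility.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, asdict


class Action(str, enum.Enum):
    STOP_SUPERIOR = "stop_superior"
    STOP_FUTILE = "stop_futile"
    CONTINUE = "continue"
    FINAL_SUPERIOR = "final_superior"
    FINAL_PROMISING = "final_promising"
    FINAL_FUTILE = "final_futile"
    FINAL_INCONCLUSIVE = "final_inconclusive"


#: Actions that count as "declaring superiority" in the design's power
#: statements (interim stop or final declaration).
SUPERIOR_ACTIONS = frozenset({Action.STOP_SUPERIOR, Action.FINAL_SUPERIOR})
FUTILE_ACTIONS = frozenset({Action.STOP_FUTILE, Action.FINAL_FUTILE})


@dataclass(frozen=True)
class DesignConfig:
    """The trial's decision rules and operational constants."""

    max_n: int = 350
    interim_calendar_months: tuple[float, ...] = (12.0, 18.0, 24.0)
    interim_superiority_threshold: float = 0.99
    futility_hr_margin: float = 1.15
    futility_prob_threshold: float = 0.8
    final_superiority_threshold: float = 0.9
    promising_threshold: float = 0.8
    follow_up_cap_hours: float = 720.0

    def __post_init__(self):
        if not (0 < self.promising_threshold
                <= self.final_superiority_threshold
                <= self.interim_superiority_threshold < 1):
            raise ValueError(
                "need 0 < promising <= final superiority <= interim superiority < 1"
            )
        if self.futility_hr_margin < 1:
            raise ValueError("futility HR margin must be >= 1")
        if not 0 < self.futility_prob_threshold < 1:
            raise ValueError("futility probability threshold must be in (0, 1)")
        if self.max_n <= 0:
            raise ValueError("max_n must be positive")
        if self.follow_up_cap_hours <= 0:
            raise ValueError("follow-up cap must be positive")
        if any(m <= 0 for m in self.interim_calendar_months) or list(
            self.interim_calendar_months
        ) != sorted(self.interim_calendar_months):
            raise ValueError("interim months must be positive and increasing")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["interim_calendar_months"] = list(self.interim_calendar_months)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DesignConfig":
        d = dict(d)
        if "interim_calendar_months" in d:
            d["interim_calendar_months"] = tuple(d["interim_calendar_months"])
        return cls(**d)


@dataclass(frozen=True)
class Decision:
    """Outcome of one analysis: the stage it was taken at and the action.

    ``stage`` is the 1-based interim index, or ``"final"``.
    """

    stage: int | str
    action: Action
    p_superiority: float
    p_futility: float

    @property
    def stops_trial(self) -> bool:
        return self.action is not Action.CONTINUE


def _check_probs(p_sup: float, p_fut: float) -> None:
    for name, p in (("p_sup", p_sup), ("p_fut", p_fut)):
        if not 0 <= p <= 1:
            raise ValueError(f"{name}={p} outside [0, 1]")


def evaluate_interim(p_sup: float, p_fut: float, config: DesignConfig,
                     stage: int = 1) -> Decision:
    """Apply the interim stopping rules; superiority is checked first."""
    _check_probs(p_sup, p_fut)
    if p_sup > config.interim_superiority_threshold:
        action = Action.STOP_SUPERIOR
    elif p_fut > config.futility_prob_threshold:
        action = Action.STOP_FUTILE
    else:
        action = Action.CONTINUE
    return Decision(stage, action, p_sup, p_fut)


def evaluate_final(p_sup: float, p_fut: float, config: DesignConfig) -> Decision:
    """Apply the final-analysis four-way classification."""
    _check_probs(p_sup, p_fut)
    if p_sup > config.final_superiority_threshold:
        action = Action.FINAL_SUPERIOR
    elif p_sup > config.promising_threshold:
        action = Action.FINAL_PROMISING
    elif p_fut > config.futility_prob_threshold:
        action = Action.FINAL_FUTILE
    else:
        action = Action.FINAL_INCONCLUSIVE
    return Decision("final", action, p_sup, p_fut)
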