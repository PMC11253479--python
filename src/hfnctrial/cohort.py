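"""Synthetic study-site cohort: calibrated baseline weaning distribution,
duration sampling, Kaplan-Meier summaries, and flowsheet-style event logs.

The baseline time-to-wean distribution is a Weibull calibrated so that its
median equals the site's observed 35 h and so that multiplying the hazard by
the design effect size HR = 1.27 shortens the median by exactly 6.08 h.  The
Weibull is the standard two-parameter family closed under proportional
hazards, so those two printed summaries pin it down uniquely:

    median = scale * (ln 2)^(1/shape)
    median under hazard multiplier h = median * h^(-1/shape)

hence shape = ln(hr) / ln(m0 / (m0 - reduction)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter


@dataclass(frozen=True)
class BaselineDistribution:
    """Weibull time-to-wean distribution: hazard k/λ (t/λ)^(k-1)."""

    shape: float
    scale: float
    family: str = "weibull"

    def __post_init__(self):
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("Weibull shape and scale must be positive")
        if self.family != "weibull":
            raise ValueError("only the Weibull family is implemented")

    def median(self, hr: float = 1.0) -> float:
        """Analytic median under a proportional-hazards multiplier ``hr``."""
        if hr <= 0:
            raise ValueError("hazard ratio must be positive")
        return self.scale * math.log(2) ** (1 / self.shape) * hr ** (-1 / self.shape)

    def scale_under_hr(self, hr: float) -> float:
        if hr <= 0:
            raise ValueError("hazard ratio must be positive")
        return self.scale * hr ** (-1 / self.shape)


@dataclass(frozen=True)
class CohortSpec:
    """Size and censoring of a synthetic encounter cohort."""

    n_encounters: int = 549
    ppv_episode_probability: float = 0.0
    censor_hours: float = 720.0

    def __post_init__(self):
        if self.n_encounters <= 0:
            raise ValueError("n_encounters must be positive")
        if not 0 <= self.ppv_episode_probability <= 1:
            raise ValueError("ppv_episode_probability must be in [0, 1]")
        if self.censor_hours <= 0:
            raise ValueError("censor_hours must be positive")


def calibrate_baseline(median0: float = 35.0, hr_ref: float = 1.27,
                       median_reduction: float = 6.08) -> BaselineDistribution:
    """The unique Weibull with the stated median and effect-size correspondence."""
    if not 0 < median_reduction < median0:
        raise ValueError("median reduction must lie strictly between 0 and the median")
    if hr_ref <= 1:
        raise ValueError("reference hazard ratio must exceed 1")
    shape = math.log(hr_ref) / math.log(median0 / (median0 - median_reduction))
    scale = median0 / math.log(2) ** (1 / shape)
    return BaselineDistribution(shape=shape, scale=scale)


def sample_durations(dist: BaselineDistribution, hr: float, n: int,
                     seed: int | np.random.Generator | None = None) -> np.ndarray:
    """i.i.d. weaning times (hours) with the hazard multiplied by ``hr``."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return dist.scale_under_hr(hr) * rng.weibull(dist.shape, size=n)


@dataclass(frozen=True)
class KMEstimate:
    """Product-limit survival curve with its median-defined summary."""

    table: pd.DataFrame  # columns: time, survival, at_risk
    median: float | None  # earliest time the curve is <= 0.5; None if never

    @property
    def median_defined(self) -> bool:
        return self.median is not None


def km_estimate(times, events) -> KMEstimate:
    """Kaplan-Meier estimate; the median is the earliest time at which the
    survival curve drops to 0.5 or below, flagged undefined if it never does.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.shape != e.shape or t.ndim != 1 or t.size == 0:
        raise ValueError("times and events must be equal-length 1-D arrays")
    if e.sum() == 0:
        return KMEstimate(
            table=pd.DataFrame({"time": np.unique(t),
                                "survival": 1.0,
                                "at_risk": np.nan}),
            median=None,
        )
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    surv = kmf.survival_function_["KM_estimate"]
    at_risk = kmf.event_table["at_risk"].reindex(surv.index)
    table = pd.DataFrame({"time": surv.index.to_numpy(),
                          "survival": surv.to_numpy(),
                          "at_risk": at_risk.to_numpy()})
    reached = table["survival"] <= 0.5
    median = float(table.loc[reached, "time"].iloc[0]) if reached.any() else None
    return KMEstimate(table=table, median=median)


# -- event-log generation ----------------------------------------------

LOG_COLUMNS = ("encounter_id", "timestamp_hours", "channel", "value")
FLOW_CADENCE_HOURS = 1.0  # documentation cadence in synthetic flowsheets
BASELINE_FLOW_LPM = 8.0
WEANED_FLOW_LPM = 3.0


def generate_event_log(spec: CohortSpec, dist: BaselineDistribution,
                       hr_by_arm=(1.0, 1.0),
                       seed: int | None = None) -> pd.DataFrame:
    """Synthetic flowsheet logs for a cohort of HFNC encounters.

    Each encounter gets one ``powerplan_order`` row at time 0, hourly
    ``hfnc_flow_lpm`` rows at or above 4 L/min while on support, and a
    final sub-4 L/min row at the drawn weaning time (omitted when the drawn
    time exceeds the follow-up cap, emulating censoring).  With probability
    ``spec.ppv_episode_probability`` a positive-pressure interlude
    (``resp_mode`` rows, here "BiPAP") is inserted before weaning, after
    which HFNC resumes.  Arms alternate by encounter-identifier parity
    (identifiers are sequential integers), and each arm's weaning times are
    drawn with that arm's hazard multiplier.
    """
    rng = np.random.default_rng(seed)
    rows: list[tuple] = []
    for enc in range(1, spec.n_encounters + 1):
        arm = enc % 2  # parity of the sequential encounter identifier
        hr = hr_by_arm[arm]
        wean = float(sample_durations(dist, hr, 1, rng)[0])
        rows.append((enc, 0.0, "powerplan_order", 1.0))
        ppv_time = None
        if (spec.ppv_episode_probability > 0 and wean > 4.0
                and rng.uniform() < spec.ppv_episode_probability):
            ppv_time = float(rng.uniform(1.0, wean / 2))
            rows.append((enc, ppv_time, "resp_mode", "BiPAP"))
            rows.append((enc, ppv_time + 1.0, "resp_mode", "BiPAP"))
        horizon = min(wean, spec.censor_hours)
        t = FLOW_CADENCE_HOURS
        while t < horizon:
            rows.append((enc, float(t), "hfnc_flow_lpm", BASELINE_FLOW_LPM))
            t += FLOW_CADENCE_HOURS
        if wean <= spec.censor_hours:
            rows.append((enc, wean, "hfnc_flow_lpm", WEANED_FLOW_LPM))
        else:
            rows.append((enc, float(spec.censor_hours), "hfnc_flow_lpm",
                         BASELINE_FLOW_LPM))
    df = pd.DataFrame(rows, columns=list(LOG_COLUMNS))
    return df.sort_values(["encounter_id", "timestamp_hours"],
                          kind="stable").reset_index(drop=True)


def write_event_log(df: pd.DataFrame, path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep, index=False)


def read_event_log(path, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event log missing columns: {missing}")
    return df
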