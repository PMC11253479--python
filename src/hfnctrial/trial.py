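"""Virtual adaptive trials: accrual, randomization, outcomes, interim
snapshots, decisions, and operating characteristics.

Each replicate draws enrollment times from a homogeneous Poisson process,
assigns arms 1:1 (independent Bernoulli(0.5), emulating randomization by
parity of sequentially assigned encounter identifiers), draws weaning times
from the calibrated Weibull baseline with the arm's hazard multiplier, and
administratively censors at the 30-day cap.  At each interim calendar time
the model is refit (knots recomputed) on a snapshot in which in-progress
subjects are right-censored at the snapshot, and the decision rules are
consulted; the final analysis runs once all enrolled subjects complete
follow-up.  Running many replicates yields the design's operating
characteristics: the probability of each conclusion, and the distributions
of total enrollment and trial duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import BaselineDistribution, calibrate_baseline, sample_durations
from .data import SurvivalDataset
from .design import (Action, Decision, DesignConfig, SUPERIOR_ACTIONS,
                     evaluate_final, evaluate_interim)
from .model import MSplinePHModel, PriorSpec
from .splines import DegenerateDurationsError

HOURS_PER_MONTH = 365.25 / 12 * 24.0
HOURS_PER_YEAR = 365.25 * 24.0


@dataclass(frozen=True)
class ScenarioConfig:
    """The simulated truth and accrual pattern for one trial scenario."""

    true_hr: float = 1.27
    accrual_per_year: float = 125.0
    baseline: BaselineDistribution = field(default_factory=calibrate_baseline)
    n_replicates: int = 5000
    seed: int = 0
    max_calendar_months: float | None = None
    seasonal_amplitude: float = 0.0  # optional sinusoidal accrual modulation

    def __post_init__(self):
        if self.true_hr <= 0:
            raise ValueError("true_hr must be positive")
        if self.accrual_per_year <= 0:
            raise ValueError("accrual_per_year must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0 <= self.seasonal_amplitude < 1:
            raise ValueError("seasonal_amplitude must be in [0, 1)")


@dataclass(frozen=True)
class TrialResult:
    """Outcome of one simulated trial replicate."""

    decision: Decision
    stage_stopped: int | str
    n_enrolled: int
    calendar_duration_months: float


@dataclass(frozen=True)
class InferenceSettings:
    """How posterior fits are performed inside the simulator."""

    method: str = "laplace"
    draws: int = 4000
    chains: int = 4
    warmup: int = 750


def _enrollment_times(rng, n: int, rate_per_hour: float,
                      seasonal_amplitude: float) -> np.ndarray:
    """Arrival times (hours) of a Poisson process, optionally modulated by a
    12-month sinusoid via thinning."""
    if seasonal_amplitude == 0.0:
        gaps = rng.exponential(1.0 / rate_per_hour, size=n)
        return np.cumsum(gaps)
    times = []
    t = 0.0
    peak_rate = rate_per_hour * (1 + seasonal_amplitude)
    while len(times) < n:
        t += rng.exponential(1.0 / peak_rate)
        intensity = 1 + seasonal_amplitude * np.cos(2 * np.pi * t / (12 * HOURS_PER_MONTH))
        if rng.uniform() < intensity * rate_per_hour / peak_rate:
            times.append(t)
    return np.asarray(times)


def _snapshot(enroll_h, durations, events_cap, arm, snapshot_h, cap_hours):
    """Dataset of subjects enrolled before the snapshot, right-censoring
    those whose follow-up is still in progress."""
    enrolled = enroll_h < snapshot_h
    if not enrolled.any():
        return None
    elapsed = snapshot_h - enroll_h[enrolled]
    horizon = np.minimum(elapsed, cap_hours)
    t = np.minimum(durations[enrolled], horizon)
    e = (durations[enrolled] <= horizon) & events_cap[enrolled]
    keep = t > 0
    if not keep.any():
        return None
    return SurvivalDataset(t[keep], e[keep].astype(int), arm[enrolled][keep])


def _fit_probs(dataset: SurvivalDataset, prior: PriorSpec,
               settings: InferenceSettings, margin: float, seed: int):
    """(P(HR>1), P(HR<margin)) from a refit on the snapshot, or None when the
    snapshot cannot support a fit (no events, or knots undefined)."""
    if dataset is None or dataset.n_events < 1:
        return None
    try:
        model = MSplinePHModel(dataset, prior=prior)
    except DegenerateDurationsError:
        return None
    res = model.fit(method=settings.method, draws=settings.draws,
                    chains=settings.chains, warmup=settings.warmup, seed=seed)
    return res.prob_hr_greater(1.0), res.prob_hr_less(margin)


def simulate_trial(scenario: ScenarioConfig, design: DesignConfig,
                   seed: int, prior: PriorSpec | None = None,
                   settings: InferenceSettings | None = None) -> TrialResult:
    """Run one virtual trial under the configured truth and decision rules.

    A snapshot that cannot support a model fit defers the decision to the
    next analysis.  One integer ``seed`` fully determines the replicate.
    """
    prior = prior or PriorSpec()
    settings = settings or InferenceSettings()
    rng = np.random.default_rng(seed)
    cap = design.follow_up_cap_hours

    enroll_h = _enrollment_times(rng, design.max_n,
                                 scenario.accrual_per_year / HOURS_PER_YEAR,
                                 scenario.seasonal_amplitude)
    arm = rng.integers(0, 2, size=design.max_n)
    hr = np.where(arm == 1, scenario.true_hr, 1.0)
    base = sample_durations(scenario.baseline, 1.0, design.max_n, rng)
    # PH thinning: multiplying the hazard by h divides Weibull scale by h^(1/k)
    durations = base * hr ** (-1.0 / scenario.baseline.shape)
    events_cap = durations <= cap
    durations_obs = np.minimum(durations, cap)

    final_h = float(enroll_h[-1] + cap)
    if scenario.max_calendar_months is not None:
        final_h = min(final_h, scenario.max_calendar_months * HOURS_PER_MONTH)

    fit_seeds = rng.integers(0, 2**31 - 1, size=len(design.interim_calendar_months) + 1)

    for k, months in enumerate(design.interim_calendar_months, start=1):
        snap_h = months * HOURS_PER_MONTH
        if snap_h >= final_h:
            break
        ds = _snapshot(enroll_h, durations_obs, events_cap, arm, snap_h, cap)
        probs = _fit_probs(ds, prior, settings, design.futility_hr_margin,
                           int(fit_seeds[k - 1]))
        if probs is None:
            continue  # decision deferred to the next analysis
        decision = evaluate_interim(*probs, design, stage=k)
        if decision.stops_trial:
            n_enrolled = int((enroll_h < snap_h).sum())
            return TrialResult(decision, k, n_enrolled, snap_h / HOURS_PER_MONTH)

    ds = _snapshot(enroll_h, durations_obs, events_cap, arm, final_h, cap)
    probs = _fit_probs(ds, prior, settings, design.futility_hr_margin,
                       int(fit_seeds[-1]))
    if probs is None:  # no analyzable data at all: inconclusive by definition
        probs = (0.0, 0.0)
    decision = evaluate_final(*probs, design)
    n_enrolled = int((enroll_h < final_h).sum())
    return TrialResult(decision, "final", n_enrolled, final_h / HOURS_PER_MONTH)


class OperatingCharacteristics:
    """Aggregated results of many simulated replicates of one scenario."""

    def __init__(self, results: list[TrialResult], scenario: ScenarioConfig,
                 design: DesignConfig):
        if not results:
            raise ValueError("no replicates")
        self.results = results
        self.scenario = scenario
        self.design = design
        self.raw = pd.DataFrame(
            {
                "action": [r.decision.action.value for r in results],
                "stage": [str(r.stage_stopped) for r in results],
                "n_enrolled": [r.n_enrolled for r in results],
                "calendar_duration_months": [r.calendar_duration_months
                                             for r in results],
                "p_superiority": [r.decision.p_superiority for r in results],
                "p_futility": [r.decision.p_futility for r in results],
            }
        )

    @property
    def n_replicates(self) -> int:
        return len(self.results)

    def _frac(self, mask) -> tuple[float, float]:
        p = float(np.mean(mask))
        return p, float(np.sqrt(p * (1 - p) / self.n_replicates))

    def prob_superiority(self) -> tuple[float, float]:
        """Fraction declaring superiority (interim stop or final), with MC s.e."""
        acts = {a.value for a in SUPERIOR_ACTIONS}
        return self._frac(self.raw["action"].isin(acts))

    def prob_superior_or_promising(self) -> tuple[float, float]:
        acts = {a.value for a in SUPERIOR_ACTIONS} | {Action.FINAL_PROMISING.value}
        return self._frac(self.raw["action"].isin(acts))

    def table(self) -> pd.DataFrame:
        """Per-stage and overall decision-class fractions with MC s.e."""
        rows = []
        n = self.n_replicates
        for (stage, action), count in (
            self.raw.groupby(["stage", "action"]).size().items()
        ):
            p = count / n
            rows.append({"stage": stage, "action": action, "fraction": p,
                         "mc_se": np.sqrt(p * (1 - p) / n)})
        for action, count in self.raw.groupby("action").size().items():
            p = count / n
            rows.append({"stage": "overall", "action": action, "fraction": p,
                         "mc_se": np.sqrt(p * (1 - p) / n)})
        return pd.DataFrame(rows)

    def summary(self) -> pd.DataFrame:
        p_sup, se_sup = self.prob_superiority()
        p_sp, se_sp = self.prob_superior_or_promising()
        return pd.DataFrame(
            [
                {"quantity": "P(declare superiority)", "value": p_sup, "mc_se": se_sup},
                {"quantity": "P(superior or promising)", "value": p_sp, "mc_se": se_sp},
                {"quantity": "mean enrollment",
                 "value": self.raw["n_enrolled"].mean(),
                 "mc_se": self.raw["n_enrolled"].sem()},
                {"quantity": "mean duration (months)",
                 "value": self.raw["calendar_duration_months"].mean(),
                 "mc_se": self.raw["calendar_duration_months"].sem()},
            ]
        )

    # -- plots ----------------------------------------------------------

    def plot_outcomes(self, ax=None):
        """Stacked bar of decision classes by stage (futile / inconclusive /
        promising / superior)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        order = ["stop_futile", "final_futile", "final_inconclusive",
                 "final_promising", "stop_superior", "final_superior"]
        colors = {"stop_futile": "#c0392b", "final_futile": "#c0392b",
                  "final_inconclusive": "#95a5a6", "final_promising": "#85c1e9",
                  "stop_superior": "#1a5276", "final_superior": "#1a5276"}
        stages = [str(s) for s in
                  list(range(1, len(self.design.interim_calendar_months) + 1))
                  + ["final"]]
        bottom = np.zeros(len(stages))
        for action in order:
            fr = [np.mean((self.raw["stage"] == s)
                          & (self.raw["action"] == action)) for s in stages]
            ax.bar(stages, fr, bottom=bottom, color=colors[action], label=action)
            bottom += np.asarray(fr)
        ax.set_xlabel("analysis stage")
        ax.set_ylabel("fraction of replicates")
        ax.legend(fontsize=7)
        return ax

    def plot_enrollment(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.raw["n_enrolled"], bins=30, color="#1a5276")
        ax.set_xlabel("total enrollment")
        ax.set_ylabel("replicates")
        return ax

    def plot_duration(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.raw["calendar_duration_months"], bins=30, color="#1a5276")
        ax.set_xlabel("trial duration (months)")
        ax.set_ylabel("replicates")
        return ax


def replicate_seeds(master_seed: int, n: int) -> np.ndarray:
    """Per-replicate seeds derived from one master seed.

    Deterministic in the master seed and independent of the scenario's truth,
    so scenarios can be compared with common random numbers.
    """
    return np.random.default_rng(master_seed).integers(0, 2**31 - 1, size=n)


def run_operating_characteristics(
    scenario: ScenarioConfig, design: DesignConfig,
    prior: PriorSpec | None = None,
    settings: InferenceSettings | None = None,
    progress: bool = False,
) -> OperatingCharacteristics:
    """Simulate ``scenario.n_replicates`` virtual trials and aggregate."""
    seeds = replicate_seeds(scenario.seed, scenario.n_replicates)
    results = []
    iterator = enumerate(seeds)
    if progress:
        from tqdm import tqdm  # pragma: no cover - cosmetic only

        iterator = enumerate(tqdm(seeds))
    for _, s in iterator:
        results.append(simulate_trial(scenario, design, int(s), prior, settings))
    return OperatingCharacteristics(results, scenario, design)
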