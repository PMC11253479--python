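"""Primary-endpoint derivation: duration of HFNC from a flowsheet event log.

The duration runs from initiation of the HFNC order to *final* weaning,
evidenced by a documented nasal-cannula flow below 4 L/min that is never
followed by a flow at or above 4 L/min within follow-up.  If positive-
pressure ventilation (noninvasive or invasive) is documented after the
order, the clock restarts at the last such documentation preceding the
final HFNC period.  Follow-up is capped at 30 days (720 h), measured from
the (possibly restarted) clock start; a log with no qualifying weaning
before the cap is censored at the cap.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .data import SurvivalDataset

#: resp_mode labels recognized as positive-pressure ventilation.
DEFAULT_PPV_MODES = frozenset({"invasive ventilation", "BiPAP", "CPAP", "NIV"})

FLOW_THRESHOLD_LPM = 4.0


@dataclass(frozen=True)
class EndpointResult:
    """Derived duration of HFNC for one encounter."""

    encounter_id: int
    duration_hours: float
    censored: bool
    clock_start_hours: float
    ppv_rule_applied: bool

    @property
    def event(self) -> int:
        return 0 if self.censored else 1


def _validate_log(log: pd.DataFrame) -> pd.DataFrame:
    required = {"timestamp_hours", "channel", "value"}
    missing = required - set(log.columns)
    if missing:
        raise ValueError(f"event log missing columns: {sorted(missing)}")
    log = log.sort_values("timestamp_hours", kind="stable")
    orders = log[log["channel"] == "powerplan_order"]
    if len(orders) != 1:
        raise ValueError(
            f"expected exactly one powerplan_order row, found {len(orders)}"
        )
    if (log["channel"] == "hfnc_flow_lpm").sum() == 0:
        raise ValueError("event log contains no flow rows")
    return log


def derive_hfnc_duration(log: pd.DataFrame, cap_hours: float = 720.0,
                         ppv_modes=DEFAULT_PPV_MODES) -> EndpointResult:
    """Apply the primary-endpoint rule to one encounter's event log.

    ``log`` holds rows (timestamp_hours, channel, value) for a single
    encounter; ``channel`` is one of ``powerplan_order``, ``hfnc_flow_lpm``
    (value = flow in L/min) or ``resp_mode`` (value = ventilation-mode
    label).  Timestamps are hours on the encounter's own clock.
    """
    log = _validate_log(log)
    enc = int(log["encounter_id"].iloc[0]) if "encounter_id" in log.columns else -1
    order_time = float(
        log.loc[log["channel"] == "powerplan_order", "timestamp_hours"].iloc[0]
    )

    flows = log[(log["channel"] == "hfnc_flow_lpm")
                & (log["timestamp_hours"] >= order_time)]
    flow_t = flows["timestamp_hours"].to_numpy(dtype=float)
    flow_v = flows["value"].to_numpy(dtype=float)

    ppv = log[(log["channel"] == "resp_mode")
              & (log["timestamp_hours"] > order_time)
              & (log["value"].isin(ppv_modes))]
    ppv_t = ppv["timestamp_hours"].to_numpy(dtype=float)

    def final_weaning(clock: float):
        """Earliest sub-threshold flow in (clock, clock + cap) that is never
        followed by a >= threshold flow before the cap."""
        window = (flow_t > clock) & (flow_t < clock + cap_hours)
        t, v = flow_t[window], flow_v[window]
        high = v >= FLOW_THRESHOLD_LPM
        candidates = (~high) & (t > t[high].max() if high.any() else True)
        return float(t[candidates].min()) if candidates.any() else None

    # The clock restart (last PPV documentation preceding the final HFNC
    # period) shifts the follow-up window, which can in turn expose a later
    # final-weaning row; iterate to the fixed point (the clock only moves
    # forward, so this terminates).
    clock_start, ppv_applied = order_time, False
    for _ in range(len(ppv_t) + 1):
        endpoint = final_weaning(clock_start)
        horizon = endpoint if endpoint is not None else clock_start + cap_hours
        prior_ppv = ppv_t[ppv_t < horizon]
        new_clock = float(prior_ppv.max()) if prior_ppv.size else order_time
        if new_clock <= clock_start:
            break
        clock_start, ppv_applied = new_clock, True

    if endpoint is not None:
        return EndpointResult(enc, endpoint - clock_start, False,
                              clock_start, ppv_applied)
    return EndpointResult(enc, cap_hours, True, clock_start, ppv_applied)


def derive_cohort_endpoints(logs: pd.DataFrame, cap_hours: float = 720.0,
                            arms: pd.Series | None = None,
                            ppv_modes=DEFAULT_PPV_MODES) -> pd.DataFrame:
    """Derive the endpoint for every encounter in a multi-encounter log.

    Returns one row per encounter (encounter_id, duration_hours, censored,
    clock_start_hours, ppv_rule_applied, arm); ``arm`` defaults to the
    encounter-identifier parity used by the randomization scheme.
    """
    if "encounter_id" not in logs.columns:
        raise ValueError("multi-encounter log requires an encounter_id column")
    out = []
    for enc, grp in logs.groupby("encounter_id", sort=True):
        r = derive_hfnc_duration(grp, cap_hours=cap_hours, ppv_modes=ppv_modes)
        arm = (int(arms.loc[enc]) if arms is not None else int(enc) % 2)
        out.append({"encounter_id": int(enc),
                    "duration_hours": r.duration_hours,
                    "censored": r.censored,
                    "clock_start_hours": r.clock_start_hours,
                    "ppv_rule_applied": r.ppv_rule_applied,
                    "arm": arm})
    return pd.DataFrame(out)


def endpoints_to_survival(endpoints: pd.DataFrame) -> SurvivalDataset:
    """Package per-encounter endpoint rows as a survival dataset."""
    return SurvivalDataset(
        endpoints["duration_hours"].to_numpy(),
        (~endpoints["censored"].astype(bool)).astype(int).to_numpy(),
        endpoints["arm"].to_numpy(),
    )
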