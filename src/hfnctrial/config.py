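"""One-file configuration: scenario / design / prior / inference sections.

All defaults equal the trial's published design, so an empty override file
reproduces it exactly.
"""

from __future__ import annotations

from dataclasses import asdict

import yaml

from .cohort import BaselineDistribution, calibrate_baseline
from .design import DesignConfig
from .model import PriorSpec
from .trial import InferenceSettings, ScenarioConfig


def load_config(path=None) -> dict:
    """Resolve a full configuration from an optional YAML override file."""
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("configuration file must contain a mapping")

    scen_raw = dict(raw.get("scenario", {}))
    baseline_raw = scen_raw.pop("baseline", None)
    if baseline_raw is None:
        cal = raw.get("calibration", {})
        baseline = calibrate_baseline(
            median0=cal.get("median_hours", 35.0),
            hr_ref=cal.get("hr_ref", 1.27),
            median_reduction=cal.get("median_reduction_hours", 6.08),
        )
    else:
        baseline = BaselineDistribution(**baseline_raw)

    return {
        "scenario": ScenarioConfig(baseline=baseline, **scen_raw),
        "design": DesignConfig.from_dict(raw.get("design", {})),
        "prior": PriorSpec(**raw.get("prior", {})),
        "inference": InferenceSettings(**raw.get("inference", {})),
        "calibration": {
            "median_hours": raw.get("calibration", {}).get("median_hours", 35.0),
            "hr_ref": raw.get("calibration", {}).get("hr_ref", 1.27),
            "median_reduction_hours": raw.get("calibration", {}).get(
                "median_reduction_hours", 6.08
            ),
        },
    }


def config_as_dict(cfg: dict) -> dict:
    out = {}
    for key, val in cfg.items():
        if hasattr(val, "to_dict"):
            out[key] = val.to_dict()
        elif hasattr(val, "__dataclass_fields__"):
            out[key] = asdict(val)
        else:
            out[key] = val
    return out
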