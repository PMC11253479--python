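"""Run manifests and small reporting helpers."""

from __future__ import annotations

import datetime as dt
import hashlib
import json
from dataclasses import dataclass, field, asdict


def enrollment_rate(n_orders: int, start: dt.date, end: dt.date,
                    decimals: int = 1) -> float:
    """Average orders per day over [start, end], rounded for reporting.

    Example: 51 order placements between 2023-12-12 and 2024-01-09
    (28 days) is 1.8/day.
    """
    days = (end - start).days
    if days <= 0:
        raise ValueError("end must be after start")
    if n_orders < 0:
        raise ValueError("n_orders must be nonnegative")
    return round(n_orders / days, decimals)


@dataclass
class RunManifest:
    """Traceability record written next to every CLI output."""

    command: str
    config: dict
    seeds: dict
    outputs: list[str] = field(default_factory=list)
    timestamp: str = field(
        default_factory=lambda: dt.datetime.now(dt.timezone.utc).isoformat()
    )
    version: str = "0.1.0"

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.config, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def write(self, path) -> None:
        d = asdict(self)
        d["config_hash"] = self.config_hash
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, default=str)
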