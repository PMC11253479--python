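"""Per-subject survival records: (time in hours, weaning event flag, arm)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

COLUMNS = ("time_hours", "event", "arm")


@dataclass(frozen=True)
class SurvivalDataset:
    """Right-censored time-to-wean records for the two trial arms.

    ``time_hours`` are positive durations since the subject's clock start,
    ``event`` is 1 if weaning was observed (0 if administratively censored),
    and ``arm`` is 1 for the CDS intervention, 0 for usual care.
    """

    time_hours: np.ndarray
    event: np.ndarray
    arm: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.time_hours, dtype=float)
        e = np.asarray(self.event, dtype=int)
        a = np.asarray(self.arm, dtype=int)
        if not (t.shape == e.shape == a.shape) or t.ndim != 1:
            raise ValueError("time_hours, event and arm must be 1-D and equal length")
        if t.size == 0:
            raise ValueError("dataset is empty")
        if not np.isfinite(t).all() or (t <= 0).any():
            raise ValueError("all times must be positive and finite")
        if not np.isin(e, (0, 1)).all():
            raise ValueError("event must be 0/1")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("arm must be 0/1")
        object.__setattr__(self, "time_hours", t)
        object.__setattr__(self, "event", e)
        object.__setattr__(self, "arm", a)

    def __len__(self) -> int:
        return self.time_hours.size

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @property
    def uncensored_durations(self) -> np.ndarray:
        return self.time_hours[self.event == 1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SurvivalDataset":
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        return cls(df["time_hours"].to_numpy(), df["event"].to_numpy(),
                   df["arm"].to_numpy())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_hours": self.time_hours, "event": self.event, "arm": self.arm}
        )

    @classmethod
    def read_table(cls, path, sep: str = "\t") -> "SurvivalDataset":
        return cls.from_dataframe(pd.read_csv(path, sep=sep))

    def write_table(self, path, sep: str = "\t") -> None:
        self.to_dataframe().to_csv(path, sep=sep, index=False)
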