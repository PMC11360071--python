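"""Observed concentration–time profiles and their CSV representation.

Profiles are two-column tables: time in hours, concentration in mg/L.  They
come from three places — the simulator (via scheme-based sampling), the
seeded noise generator, or user-supplied files such as digitized literature
curves — and all three meet here in one container.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = ["ObservedProfile", "read_profile_csv", "write_profile_csv"]

CSV_COLUMNS = ("time_h", "conc_mg_per_L")


@dataclass(frozen=True)
class ObservedProfile:
    """A sampled concentration–time profile.

    Times must be strictly increasing with the first >= 0; concentrations
    are non-negative.
    """

    times: np.ndarray
    concentrations: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.ndim != 1 or c.ndim != 1 or t.size != c.size:
            raise ValidationError("times and concentrations must be equal-length 1-D arrays")
        if t.size and t[0] < 0:
            raise ValidationError("first sampling time must be >= 0")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("sampling times must be strictly increasing")
        if np.any(c < 0):
            raise ValidationError("concentrations must be >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)

    def __len__(self) -> int:
        return int(self.times.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({CSV_COLUMNS[0]: self.times, CSV_COLUMNS[1]: self.concentrations})


def read_profile_csv(path: str | Path, label: str | None = None) -> ObservedProfile:
    """Read a profile from CSV (columns ``time_h``, ``conc_mg_per_L``)."""
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"profile CSV {path} is missing columns {missing}")
    return ObservedProfile(
        times=df[CSV_COLUMNS[0]].to_numpy(float),
        concentrations=df[CSV_COLUMNS[1]].to_numpy(float),
        label=label if label is not None else str(path),
    )


def write_profile_csv(profile: ObservedProfile, path: str | Path) -> None:
    profile.to_frame().to_csv(path, index=False)
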