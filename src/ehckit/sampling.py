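"""Sampling schemes, trapezoidal AUC and the seeded noise generator.

Three families of blood-sampling schedules are encoded: a 17-point
meal-based scheme that brackets every meal, a 17-point conventional scheme
that front-loads samples to characterize tmax/Cmax, and five nested
limited-sampling schemes (TDM1–TDM5) restricted to clinically practical
times within the first 18 hours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

from .exceptions import ExtrapolationError, ValidationError
from .profiles import ObservedProfile
from .simulator import SimulationResult

__all__ = [
    "SamplingScheme",
    "NoiseModel",
    "SCHEME_NAMES",
    "scheme",
    "extract_samples",
    "extract_from_table",
    "trapezoid_auc",
    "add_noise",
]


@dataclass(frozen=True)
class SamplingScheme:
    """A named, strictly increasing list of sampling times (h)."""

    name: str
    times: tuple[float, ...]

    def __post_init__(self) -> None:
        t = tuple(float(x) for x in self.times)
        if not t or t[0] != 0.0:
            raise ValidationError("sampling schemes start at t = 0")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValidationError("sampling times must be strictly increasing")
        object.__setattr__(self, "times", t)

    def __len__(self) -> int:
        return len(self.times)


_SCHEMES = {
    "meal_based": (0, 0.5, 1, 2, 3, 4, 5, 6, 10, 11, 12, 16, 17, 18, 29, 53, 77),
    "conventional": (0, 0.25, 0.5, 0.75, 1, 1.5, 2, 2.5, 3, 4, 5, 7, 9, 12, 24, 48, 72),
    "TDM1": (0, 1, 3, 4, 6),
    "TDM2": (0, 1, 3, 4, 6, 10),
    "TDM3": (0, 1, 3, 4, 6, 10, 12),
    "TDM4": (0, 1, 3, 4, 6, 10, 12, 16),
    "TDM5": (0, 1, 3, 4, 6, 10, 12, 16, 18),
}

_ALIASES = {"meal": "meal_based", "meal_based": "meal_based",
            "conventional": "conventional",
            **{f"tdm{i}": f"TDM{i}" for i in range(1, 6)},
            **{f"TDM{i}": f"TDM{i}" for i in range(1, 6)}}

SCHEME_NAMES = tuple(_SCHEMES)


def scheme(name: str) -> SamplingScheme:
    """Look up a sampling scheme by name (``meal_based``, ``conventional``,
    ``TDM1``..``TDM5``; lowercase aliases accepted)."""
    key = _ALIASES.get(name) or _ALIASES.get(name.lower())
    if key is None:
        raise KeyError(f"unknown sampling scheme {name!r}; known: {SCHEME_NAMES}")
    return SamplingScheme(name=key, times=_SCHEMES[key])


def extract_from_table(times, dc, s: SamplingScheme, label: str | None = None) -> ObservedProfile:
    """Sample a dense (time, plasma concentration) table at the scheme times.

    Monotone cubic (PCHIP) interpolation; times beyond the table's end raise
    a range error.
    """
    times = np.asarray(times, dtype=float)
    dc = np.asarray(dc, dtype=float)
    t_req = np.asarray(s.times, dtype=float)
    if t_req[-1] > times[-1] + 1e-9:
        raise ValidationError(
            f"scheme {s.name} samples to {t_req[-1]} h but the trajectory "
            f"ends at {times[-1]} h"
        )
    interp = PchipInterpolator(times, dc, extrapolate=False)
    conc = np.clip(interp(np.minimum(t_req, times[-1])), 0.0, None)
    return ObservedProfile(times=t_req, concentrations=conc,
                           label=label if label is not None else s.name)


def extract_samples(sim: SimulationResult, s: SamplingScheme) -> ObservedProfile:
    """Plasma concentrations at the scheme's times, from the dense trajectory.

    The solver grid is far finer than any scheme, so interpolation (rather
    than re-integration per scheme) is exact to solver accuracy.
    """
    return extract_from_table(sim.times, sim.states[:, 0], s)


def trapezoid_auc(profile: ObservedProfile, extrapolate: bool = False) -> float:
    """Linear trapezoidal AUC over the observed span (mg·h/L).

    With ``extrapolate=True`` a terminal tail ``C_last / lambda_z`` is added,
    with lambda_z from a log-linear fit of the last three positive
    concentrations; a non-decaying tail raises
    :class:`~ehckit.exceptions.ExtrapolationError`.
    """
    if len(profile) < 2:
        raise ValidationError("trapezoid_auc needs at least 2 points")
    auc = float(np.trapezoid(profile.concentrations, profile.times))
    if not extrapolate:
        return auc
    pos = np.flatnonzero(profile.concentrations > 0)
    if pos.size < 3:
        raise ExtrapolationError("need 3 positive concentrations for a terminal fit")
    idx = pos[-3:]
    slope = np.polyfit(profile.times[idx], np.log(profile.concentrations[idx]), 1)[0]
    lam = -float(slope)
    if lam <= 0:
        raise ExtrapolationError("terminal concentrations do not decay")
    return auc + float(profile.concentrations[idx[-1]]) / lam


@dataclass(frozen=True)
class NoiseModel:
    """Seeded measurement noise: proportional CV plus additive SD (mg/L)."""

    proportional_cv: float = 0.1
    additive_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.proportional_cv < 0 or self.additive_sd < 0:
            raise ValidationError("noise magnitudes must be >= 0")


def add_noise(profile: ObservedProfile, noise: NoiseModel) -> ObservedProfile:
    """Perturb a profile: ``c' = max(0, c (1 + eps) + eta)``.

    ``eps ~ N(0, cv^2)`` and ``eta ~ N(0, sd^2)``, reproducible from the
    noise model's seed.
    """
    rng = np.random.default_rng(noise.seed)
    c = profile.concentrations
    eps = rng.normal(0.0, noise.proportional_cv, size=c.size) if noise.proportional_cv else 0.0
    eta = rng.normal(0.0, noise.additive_sd, size=c.size) if noise.additive_sd else 0.0
    noisy = np.maximum(0.0, c * (1.0 + eps) + eta)
    return ObservedProfile(times=profile.times, concentrations=noisy,
                           label=f"{profile.label}+noise" if profile.label else "noisy")
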