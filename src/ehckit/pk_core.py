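"""Mechanistic building blocks of the enterohepatic-circulation (EHC) model.

The compartmental model describes an orally dosed drug that dissolves from its
solid form, is absorbed from the intestine, distributes to a peripheral
compartment, and leaves the central compartment by renal elimination, by
saturable biotransformation, and by transfer into the gallbladder.  Bile is
discharged back into the intestine in short meal-triggered pulses, producing
the secondary plasma peaks characteristic of EHC.

This module holds the parameter containers and the three time/state-dependent
coefficient functions of that model:

* :func:`fdis` — Weibull dissolution of the solid dosage form,
* :func:`kgem` — periodic meal-triggered gallbladder-emptying rate,
* :func:`vbio` — Michaelis–Menten biotransformation rate,

together with the instantaneous and limiting fractions of central-compartment
drug undergoing EHC (:func:`ehc_percent`, :func:`ehc_max`, :func:`ehc_min`).

All compartment variables use a unit-volume convention: amounts live in an
apparent 1 L volume, so amount (mg) and concentration (mg/L) coincide
numerically and the biotransformation rate (mg/h) can be combined directly
with first-order rate constants (1/h).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

from .exceptions import ValidationError

__all__ = [
    "WeibullDissolution",
    "GallbladderSchedule",
    "MMElimination",
    "PKParameters",
    "fdis",
    "kgem",
    "vbio",
    "ehc_percent",
    "ehc_max",
    "ehc_min",
]


@dataclass(frozen=True)
class WeibullDissolution:
    """Weibull dissolution profile of the solid dosage form.

    Parameters
    ----------
    kd : float
        Scale rate (1/h) controlling how fast the dose dissolves.
    tlag : float
        Delay (h) before dissolution starts.
    a : float
        Shape parameter: ``a == 1`` exponential, ``a > 1`` sigmoid,
        ``a < 1`` parabolic.
    scaled_time : bool
        If True (default) the exponent is ``(kd * (t - tlag)) ** a`` so it
        stays dimensionless for every shape; if False the alternative
        ``kd * (t - tlag) ** a`` convention is used.  The two coincide at
        ``a == 1``.
    """

    kd: float = 0.5
    tlag: float = 0.0
    a: float = 1.0
    scaled_time: bool = True

    def __post_init__(self) -> None:
        if not self.kd > 0:
            raise ValidationError(f"kd must be > 0, got {self.kd}")
        if self.tlag < 0:
            raise ValidationError(f"tlag must be >= 0, got {self.tlag}")
        if not self.a > 0:
            raise ValidationError(f"a must be > 0, got {self.a}")


@dataclass(frozen=True)
class GallbladderSchedule:
    """Meal-triggered gallbladder-emptying schedule.

    The emptying rate is a sum of sharp 24 h-periodic pulses centred on the
    meal times.  ``b`` sets the pulse sharpness: with the standard value of
    300 the rate between pulses is numerically zero (< 1e-100 of ``kmax``),
    which realises the assumption that the gallbladder only empties at meals.
    """

    kmax: float = 3.0
    b: float = 300.0
    meal_times: tuple[float, ...] = (5.0, 11.0, 17.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "meal_times", tuple(float(c) for c in self.meal_times))
        if self.kmax < 0:
            raise ValidationError(f"kmax must be >= 0, got {self.kmax}")
        if not self.b > 0:
            raise ValidationError(f"b must be > 0, got {self.b}")
        if not self.meal_times:
            raise ValidationError("meal_times must be non-empty")
        if any(not (0 <= c < 24) for c in self.meal_times):
            raise ValidationError(f"meal_times must lie in [0, 24), got {self.meal_times}")
        if any(b <= a for a, b in zip(self.meal_times, self.meal_times[1:])):
            raise ValidationError(f"meal_times must be strictly increasing, got {self.meal_times}")

    @property
    def n_meals(self) -> int:
        return len(self.meal_times)


@dataclass(frozen=True)
class MMElimination:
    """Michaelis–Menten biotransformation: ``v = vmax * DC / (km + DC)``.

    ``vmax`` is in mg/h under the unit-volume convention; ``km`` in mg/L.
    Small ``km`` means high enzyme affinity, hence strong competition between
    biotransformation and biliary transfer at low concentrations.
    """

    vmax: float = 0.1
    km: float = 10.0

    def __post_init__(self) -> None:
        if self.vmax < 0:
            raise ValidationError(f"vmax must be >= 0, got {self.vmax}")
        if not self.km > 0:
            raise ValidationError(f"km must be > 0, got {self.km}")


#: Flat serialization keys, in canonical order.
_FLAT_KEYS = (
    "ka", "krel", "kgel", "k12", "k21", "kehc",
    "kd", "tlag", "a", "kmax", "b", "ci", "vmax", "km",
    "dose", "horizon",
)


@dataclass(frozen=True)
class PKParameters:
    """Full parameter set of the compartmental EHC model.

    Rates are first-order constants in 1/h; ``dose`` is the administered
    amount in mg (placed in the solid compartment at t = 0) and ``horizon``
    the simulation end in hours.
    """

    ka: float = 0.9
    krel: float = 0.1
    kgel: float = 0.1
    k12: float = 0.0
    k21: float = 0.0
    kehc: float = 0.15
    dissolution: WeibullDissolution = field(default_factory=WeibullDissolution)
    gallbladder: GallbladderSchedule = field(default_factory=GallbladderSchedule)
    biotransformation: MMElimination = field(default_factory=MMElimination)
    dose: float = 10.0
    horizon: float = 96.0

    def __post_init__(self) -> None:
        for name in ("ka", "krel", "kgel", "k12", "k21", "kehc"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not self.dose > 0:
            raise ValidationError(f"dose must be > 0, got {self.dose}")
        if not self.horizon > 0:
            raise ValidationError(f"horizon must be > 0, got {self.horizon}")

    # -- flat serialization ------------------------------------------------
    def to_dict(self) -> dict:
        """Serialize to the flat key set used by config files."""
        return {
            "ka": self.ka, "krel": self.krel, "kgel": self.kgel,
            "k12": self.k12, "k21": self.k21, "kehc": self.kehc,
            "kd": self.dissolution.kd, "tlag": self.dissolution.tlag,
            "a": self.dissolution.a,
            "kmax": self.gallbladder.kmax, "b": self.gallbladder.b,
            "ci": list(self.gallbladder.meal_times),
            "vmax": self.biotransformation.vmax, "km": self.biotransformation.km,
            "dose": self.dose, "horizon": self.horizon,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PKParameters":
        """Build from a flat mapping; missing keys fall back to defaults."""
        unknown = set(d) - set(_FLAT_KEYS)
        if unknown:
            raise ValidationError(f"unknown parameter keys: {sorted(unknown)}")
        base = cls()
        diss = replace(
            base.dissolution,
            kd=float(d.get("kd", base.dissolution.kd)),
            tlag=float(d.get("tlag", base.dissolution.tlag)),
            a=float(d.get("a", base.dissolution.a)),
        )
        gb = replace(
            base.gallbladder,
            kmax=float(d.get("kmax", base.gallbladder.kmax)),
            b=float(d.get("b", base.gallbladder.b)),
            meal_times=tuple(d.get("ci", base.gallbladder.meal_times)),
        )
        mm = replace(
            base.biotransformation,
            vmax=float(d.get("vmax", base.biotransformation.vmax)),
            km=float(d.get("km", base.biotransformation.km)),
        )
        return cls(
            ka=float(d.get("ka", base.ka)), krel=float(d.get("krel", base.krel)),
            kgel=float(d.get("kgel", base.kgel)), k12=float(d.get("k12", base.k12)),
            k21=float(d.get("k21", base.k21)), kehc=float(d.get("kehc", base.kehc)),
            dissolution=diss, gallbladder=gb, biotransformation=mm,
            dose=float(d.get("dose", base.dose)),
            horizon=float(d.get("horizon", base.horizon)),
        )

    def with_overrides(self, overrides: Mapping) -> "PKParameters":
        """Return a copy with flat-key overrides applied."""
        d = self.to_dict()
        unknown = set(overrides) - set(_FLAT_KEYS)
        if unknown:
            raise ValidationError(f"unknown parameter keys: {sorted(unknown)}")
        d.update(overrides)
        return PKParameters.from_dict(d)


# ---------------------------------------------------------------------------
# Coefficient functions
# ---------------------------------------------------------------------------

def fdis(t, w: WeibullDissolution):
    """Dissolved-fraction coefficient at time ``t`` (h).

    Returns 0 for ``t <= tlag`` and ``1 - exp(-(kd*(t-tlag))**a)`` beyond the
    lag (or the unscaled-time variant if ``w.scaled_time`` is False).
    Accepts scalars or arrays; non-decreasing in ``t`` and bounded in [0, 1).
    """
    t = np.asarray(t, dtype=float)
    u = np.maximum(t - w.tlag, 0.0)
    if w.scaled_time:
        expo = (w.kd * u) ** w.a
    else:
        expo = w.kd * u ** w.a
    out = -np.expm1(-expo)
    return float(out) if out.ndim == 0 else out


def kgem(t, g: GallbladderSchedule):
    """Gallbladder-emptying rate (1/h) at time ``t``.

    ``kmax * sum_i exp(-b * sin^2(pi*(t - ci)/24))`` — strictly positive and
    24 h-periodic, so meal pulses repeat automatically on every day.
    """
    t = np.asarray(t, dtype=float)
    acc = np.zeros_like(t)
    for c in g.meal_times:
        acc = acc + np.exp(-g.b * np.sin(np.pi * (t - c) / 24.0) ** 2)
    out = g.kmax * acc
    return float(out) if out.ndim == 0 else out


def vbio(dc, m: MMElimination):
    """Michaelis–Menten biotransformation rate (mg/h) at central level ``dc``.

    Monotone increasing in ``dc`` and bounded above by ``vmax``.
    """
    dc = np.asarray(dc, dtype=float)
    out = m.vmax * dc / (m.km + dc)
    return float(out) if out.ndim == 0 else out


def ehc_percent(dc, p: PKParameters):
    """Instantaneous percentage of central-compartment drug undergoing EHC.

    ``100 * kehc / (kehc + krel + k12 + vbio(dc))`` — the biliary route's
    share of all routes out of the central compartment.  Because ``vbio``
    rises from 0 to ``vmax`` with concentration, the value always lies
    between :func:`ehc_min` and :func:`ehc_max`.
    """
    v = np.asarray(vbio(dc, p.biotransformation), dtype=float)
    denom = p.kehc + p.krel + p.k12 + v
    out = 100.0 * p.kehc / denom
    return float(out) if out.ndim == 0 else out


def ehc_max(kehc: float, krel: float, k12: float) -> float:
    """Theoretical maximum EHC fraction (%), reached as DC -> 0.

    ``100 * kehc / (kehc + krel + k12)``.
    """
    denom = kehc + krel + k12
    if denom <= 0:
        raise ValidationError("kehc + krel + k12 must be > 0")
    return 100.0 * kehc / denom


def ehc_min(kehc: float, krel: float, k12: float, vmax: float) -> float:
    """Theoretical minimum EHC fraction (%), reached at saturating DC.

    ``100 * kehc / (kehc + krel + k12 + vmax)``; always <= :func:`ehc_max`.
    """
    denom = kehc + krel + k12 + vmax
    if denom <= 0:
        raise ValidationError("kehc + krel + k12 + vmax must be > 0")
    return 100.0 * kehc / denom
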