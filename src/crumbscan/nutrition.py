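"""Starch digestibility, predicted glycemic index, color and texture quality.

In-vitro digestion (Englyst-style) measures glucose released from a food
sample: free glucose FG before digestion, G20 and G120 after 20 and 120
minutes of enzymatic hydrolysis, and total glucose TG after complete
hydrolysis, all in g/100 g. The 0.9 factor converts glucose to anhydrous
starch:

    TS  = (TG - FG) * 0.9        total starch
    RAG = G20                    rapidly available glucose
    RDS = (G20 - FG) * 0.9       rapidly digestible starch
    SDS = (G120 - G20) * 0.9     slowly digestible starch
    SHI = RDS / TS * 100         starch hydrolysis index

The hydrolysis index HI is the area under the digestion curve relative to a
caller-supplied reference food, and the predicted glycemic index is the
affine map pGI = 39.71 + 0.549 * HI.

Color quality uses CIELAB coordinates: the total color difference dE is the
Euclidean distance to a reference triplet, and the browning index is

    BI = 100 * (x - 0.31) / 0.17,   x = (a + 1.79 L) / (5.645 L + a - 3.012 b)

Physical quality: specific volume (mL/g), baking weight loss (%), and the
hardness-increase rate over storage (N/day).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateColorError,
    DegenerateProfileError,
    ParameterError,
    ProfileValidationError,
)

__all__ = [
    "DigestionProfile",
    "StarchFractions",
    "ColorTriplet",
    "TextureSeries",
    "GLUCOSE_TO_STARCH",
    "PGI_INTERCEPT",
    "PGI_SLOPE",
    "starch_fractions",
    "implied_free_glucose",
    "hydrolysis_index",
    "predicted_gi",
    "delta_e",
    "browning_index",
    "specific_volume",
    "weight_loss",
    "hardness_rate",
]

#: anhydrous glucose -> starch conversion factor
GLUCOSE_TO_STARCH = 0.9
#: predicted-GI affine coefficients (pGI = intercept + slope * HI)
PGI_INTERCEPT = 39.71
PGI_SLOPE = 0.549


@dataclass(frozen=True)
class DigestionProfile:
    """Glucose-release measurements from one in-vitro digestion (g/100 g).

    ``curve`` optionally carries the percent of total starch digested on the
    0-180 min grid, used for the hydrolysis index.
    """

    FG: float
    TG: float
    G20: float
    G120: float
    curve: list[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        checks = [
            ("0 <= FG", self.FG >= 0),
            ("FG <= G20", self.FG <= self.G20 + 1e-12),
            ("G20 <= G120", self.G20 <= self.G120 + 1e-12),
            ("G120 <= TG", self.G120 <= self.TG + 1e-12),
        ]
        violated = [name for name, ok in checks if not ok]
        if violated:
            raise ProfileValidationError(
                "digestion profile violates: " + ", ".join(violated)
            )
        if self.curve is not None:
            t = np.array([p[0] for p in self.curve])
            if len(t) < 2 or np.any(np.diff(t) <= 0):
                raise ProfileValidationError("curve times must be strictly increasing")
            if not (t[0] == 0 and t[-1] == 180):
                raise ProfileValidationError("curve must span [0, 180] minutes")


@dataclass(frozen=True)
class StarchFractions:
    """Derived starch fractions; HI/pGI are None until a reference is given."""

    TS: float
    RAG: float
    RDS: float
    SDS: float
    SHI: float
    HI: float | None = None
    pGI: float | None = None


@dataclass(frozen=True)
class ColorTriplet:
    """CIELAB color coordinates (L* lightness, a* red-green, b* yellow-blue)."""

    L: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if not 0 <= self.L <= 100:
            raise ParameterError("L* must lie in [0, 100]")


@dataclass(frozen=True)
class TextureSeries:
    """Hardness (N) and springiness (%) over storage days."""

    day: list[int]
    hardness_N: list[float]
    springiness_pct: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.day) != len(self.hardness_N):
            raise ParameterError("day and hardness_N must have equal lengths")
        if self.springiness_pct and len(self.springiness_pct) != len(self.day):
            raise ParameterError("springiness_pct length must match day")
        if np.any(np.diff(self.day) <= 0):
            raise ParameterError("days must be strictly increasing")
        if any(h < 0 for h in self.hardness_N):
            raise ParameterError("hardness must be non-negative")


def starch_fractions(profile: DigestionProfile) -> StarchFractions:
    """Englyst starch fractions from a digestion profile.

    Raises
    ------
    DegenerateProfileError
        If total starch is non-positive (TG <= FG).
    """
    f = GLUCOSE_TO_STARCH
    TS = (profile.TG - profile.FG) * f
    if TS <= 0:
        raise DegenerateProfileError("total starch is non-positive (TG <= FG)")
    RDS = (profile.G20 - profile.FG) * f
    SDS = (profile.G120 - profile.G20) * f
    return StarchFractions(
        TS=TS,
        RAG=profile.G20,
        RDS=RDS,
        SDS=SDS,
        SHI=RDS / TS * 100.0,
    )


def implied_free_glucose(RAG: float, RDS: float) -> float:
    """Free glucose implied by a published (RAG, RDS) pair: FG = RAG - RDS/0.9.

    A negative result flags an internally inconsistent row (RDS > 0.9 RAG),
    since free glucose cannot be negative; constructing a
    :class:`DigestionProfile` from such a row raises
    :class:`~crumbscan.errors.ProfileValidationError`.
    """
    return RAG - RDS / GLUCOSE_TO_STARCH


def hydrolysis_index(
    curve: list[tuple[float, float]],
    reference_curve: list[tuple[float, float]],
) -> float:
    """HI = 100 x AUC(sample) / AUC(reference), trapezoidal, same interval.

    Both curves are (time_min, % starch digested) with >= 2 points each.
    """
    for name, c in (("curve", curve), ("reference_curve", reference_curve)):
        if len(c) < 2:
            raise ParameterError(f"{name} needs at least 2 points")
    t_s, y_s = np.asarray(curve, dtype=float).T
    t_r, y_r = np.asarray(reference_curve, dtype=float).T
    if not (t_s[0] == t_r[0] and t_s[-1] == t_r[-1]):
        raise ParameterError("curves must cover the same time interval")
    auc_ref = float(np.trapezoid(y_r, t_r))
    if auc_ref <= 0:
        raise ParameterError("reference AUC must be positive")
    return 100.0 * float(np.trapezoid(y_s, t_s)) / auc_ref


def predicted_gi(HI: float) -> float:
    """Predicted glycemic index from the hydrolysis index."""
    if HI < 0:
        raise ParameterError("HI must be non-negative")
    return PGI_INTERCEPT + PGI_SLOPE * HI


def delta_e(color: ColorTriplet, reference: ColorTriplet) -> float:
    """Total color difference: Euclidean distance in (L*, a*, b*)."""
    return math.sqrt(
        (color.L - reference.L) ** 2
        + (color.a - reference.a) ** 2
        + (color.b - reference.b) ** 2
    )


def browning_index(
    color: ColorTriplet,
    x_coeff_L: float = 1.79,
    x_offset: float = 0.31,
    x_scale: float = 0.17,
) -> float:
    """Browning index of a baked surface.

    The default coefficients (1.79, 0.31, 0.17) follow the convention used
    for cake crust; the common literature variant (1.75, 0.31, 0.172) can be
    selected through the keyword arguments.
    """
    den = 5.645 * color.L + color.a - 3.012 * color.b
    if den == 0:
        raise DegenerateColorError("browning-index denominator is zero")
    x = (color.a + x_coeff_L * color.L) / den
    return 100.0 * (x - x_offset) / x_scale


def specific_volume(volume_mL: float, weight_g: float) -> float:
    """Specific volume in cm^3/g (= mL/g)."""
    if not weight_g > 0:
        raise ParameterError("weight must be positive")
    return volume_mL / weight_g


def weight_loss(initial_g: float, final_g: float) -> float:
    """Baking weight loss as a percentage of the initial (batter) weight.

    A final weight above the initial one yields a negative loss, reported
    as-is (the caller may warn).
    """
    if not initial_g > 0:
        raise ParameterError("initial weight must be positive")
    if final_g < 0:
        raise ParameterError("final weight must be non-negative")
    return (initial_g - final_g) / initial_g * 100.0


def hardness_rate(series: TextureSeries) -> float:
    """Hardness-increase rate over storage: endpoint slope in N/day."""
    if len(series.day) < 2:
        raise ParameterError("need at least two time points")
    return (series.hardness_N[-1] - series.hardness_N[0]) / (
        series.day[-1] - series.day[0]
    )
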