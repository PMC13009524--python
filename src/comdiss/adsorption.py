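"""Langmuir analysis of inhibitor adsorption on the crystal surface.

An adsorbing inhibitor blocks a fraction θ of the active dissolution sites,
reducing the rate to Rᵢ = R₀(1 − θ).  Two linearizations of the Langmuir
model are fitted:

* kinetic:    R₀/(R₀ − Rᵢ) = 1 + 1/(K_L·C), regressed on 1/C (slope → K_L);
* isotherm:   C/θ = C + 1/K_ads, regressed on C (intercept → K_ads);

and the standard Gibbs free energy of adsorption is
ΔG_ads = −RT·ln(55.5·K_ads), the 55.5 mol dm⁻³ factor converting the
dm³ mol⁻¹ constant to the mole-fraction (water-displacement) standard state.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .constants import R_GAS, T_GIBBS_K, WATER_MOLARITY
from .errors import FitError, ValidationError

__all__ = [
    "InhibitionPoint",
    "LangmuirFit",
    "surface_coverage",
    "langmuir_kinetic_fit",
    "langmuir_isotherm_fit",
    "gibbs_adsorption",
]


@dataclass(frozen=True)
class InhibitionPoint:
    """One (inhibitor concentration, inhibited rate, control rate) triple."""

    conc: float            # mol dm-3
    rate_inhibited: float  # mol m-2 min-1
    rate_control: float    # mol m-2 min-1

    def __post_init__(self):
        if self.conc <= 0:
            raise ValidationError("inhibitor concentration must be positive")
        if self.rate_inhibited <= 0 or self.rate_control <= 0:
            raise ValidationError("rates must be positive")


@dataclass
class LangmuirFit:
    """Result of a linearized Langmuir regression."""

    constant: float        # K_L or K_ads, dm3 mol-1
    slope: float
    intercept: float
    r_squared: float
    kind: str              # "kinetic" | "isotherm"
    theta_series: list[float] = field(default_factory=list)
    delta_g: float | None = None  # kJ mol-1, isotherm kind only
    excluded: list[float] = field(default_factory=list)  # concentrations dropped
    water_molarity: float | None = None
    temperature: float | None = None


def surface_coverage(point: InhibitionPoint) -> float:
    """θ = 1 − Rᵢ/R₀, the blocked fraction of active sites.

    A rate above the control gives a (flagged) negative coverage.
    """
    theta = 1.0 - point.rate_inhibited / point.rate_control
    if theta < 0:
        warnings.warn("negative coverage: inhibited rate exceeds control", stacklevel=2)
    return theta


def langmuir_kinetic_fit(points: list[InhibitionPoint]) -> LangmuirFit:
    """K_L from OLS of R₀/(R₀−Rᵢ) on 1/C; ideal intercept is 1.

    Points with Rᵢ = R₀ (infinite response) are excluded with a warning.
    """
    usable, dropped = [], []
    for p in points:
        if p.rate_inhibited >= p.rate_control:
            dropped.append(p.conc)
        else:
            usable.append(p)
    if dropped:
        warnings.warn(
            f"excluded {len(dropped)} point(s) with no measurable inhibition",
            stacklevel=2,
        )
    if len(usable) < 3:
        raise FitError("need at least 3 usable points for the kinetic Langmuir fit")
    x = np.array([1.0 / p.conc for p in usable])
    if np.ptp(x) == 0:
        raise FitError("degenerate design: all concentrations identical")
    y = np.array([p.rate_control / (p.rate_control - p.rate_inhibited) for p in usable])
    res = stats.linregress(x, y)
    if res.slope <= 0:
        raise FitError("non-positive kinetic Langmuir slope: model inapplicable")
    return LangmuirFit(
        constant=float(1.0 / res.slope),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2),
        kind="kinetic",
        theta_series=[surface_coverage(p) for p in usable],
        excluded=dropped,
    )


def langmuir_isotherm_fit(
    points: list[InhibitionPoint],
    temperature: float = T_GIBBS_K,
    water_molarity: float = WATER_MOLARITY,
) -> LangmuirFit:
    """K_ads from OLS of C/θ on C; ideal slope is 1.

    θ is recomputed from the rates (never trusted from a table); points with
    θ = 0 are excluded with a warning.  ΔG_ads is evaluated from the fitted
    constant at the given temperature.
    """
    usable, dropped = [], []
    for p in points:
        if surface_coverage(p) <= 0:
            dropped.append(p.conc)
        else:
            usable.append(p)
    if dropped:
        warnings.warn(
            f"excluded {len(dropped)} point(s) with zero/negative coverage",
            stacklevel=2,
        )
    if len(usable) < 3:
        raise FitError("need at least 3 usable points for the isotherm fit")
    c = np.array([p.conc for p in usable])
    if np.ptp(c) == 0:
        raise FitError("degenerate design: all concentrations identical")
    theta = np.array([surface_coverage(p) for p in usable])
    res = stats.linregress(c, c / theta)
    if res.intercept <= 0:
        raise FitError("non-positive isotherm intercept: model inapplicable")
    k_ads = float(1.0 / res.intercept)
    return LangmuirFit(
        constant=k_ads,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2),
        kind="isotherm",
        theta_series=list(map(float, theta)),
        delta_g=gibbs_adsorption(k_ads, temperature, water_molarity),
        excluded=dropped,
        water_molarity=water_molarity,
        temperature=temperature,
    )


def gibbs_adsorption(
    k_ads: float,
    temperature: float = T_GIBBS_K,
    water_molarity: float = WATER_MOLARITY,
) -> float:
    """ΔG_ads = −RT·ln(water_molarity × K_ads) in kJ mol⁻¹.

    With ``water_molarity = 55.5`` (default) the constant is referred to the
    mole-fraction standard state of the displaced water; ``water_molarity=1``
    gives the literal molar-scale −RT·ln K_ads.  Negative for favorable
    adsorption whenever the ln argument exceeds 1.
    """
    if k_ads <= 0 or temperature <= 0 or water_molarity <= 0:
        raise ValidationError("k_ads, temperature and water_molarity must be positive")
    return -R_GAS * temperature * math.log(water_molarity * k_ads) / 1000.0
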