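"""Dissolution kinetics: undersaturation, rate extraction, power rate law.

The driving force for dissolution of a sparingly soluble 1:1 salt is the
relative undersaturation σ = (H₀^{1/2} − H^{1/2})/H₀^{1/2}, where H^{1/2} is
the square root of the free-ion concentration product and H₀^{1/2} its value
at equilibrium.  Surface-normalized rates follow the empirical power law
R = k·s·σⁿ with the site factor s normalized to 1; n and k are obtained by
ordinary least squares on the log–log linearization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .constants import BET_SSA, H0_SQRT_COM, T_EXPERIMENT_K
from .errors import FitError, SupersaturationError, ValidationError

__all__ = [
    "RatePoint",
    "DissolutionRun",
    "RateLawFit",
    "TitrationTrace",
    "relative_undersaturation",
    "rate_from_titration",
    "fit_rate_law",
    "percent_inhibition",
]


@dataclass(frozen=True)
class RatePoint:
    """One measured (σ, R) pair with its experimental conditions."""

    sigma: float                 # relative undersaturation, dimensionless
    rate: float                  # mol m-2 min-1
    t_ca: float | None = None    # total calcium, mol dm-3
    seed_mass: float = 10.0      # mg
    stirring: float = 300.0      # rpm
    inhibitor_conc: float = 0.0  # mol dm-3; 0 for control

    def __post_init__(self):
        if not 0.0 <= self.sigma < 1.0:
            raise ValidationError(f"sigma {self.sigma} outside [0, 1)")
        if self.rate <= 0:
            raise ValidationError("rate must be positive")
        if self.seed_mass <= 0:
            raise ValidationError("seed mass must be positive")


@dataclass
class DissolutionRun:
    """An ordered series of rate points sharing one set of conditions."""

    points: list[RatePoint]
    label: str = "control"
    temperature: float = T_EXPERIMENT_K
    pH: float = 6.0
    ionic_strength: float = 0.15

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([p.sigma for p in self.points])

    @property
    def rates(self) -> np.ndarray:
        return np.array([p.rate for p in self.points])


@dataclass
class RateLawFit:
    """OLS result for log₁₀R = n·log₁₀σ + log₁₀k (s = 1)."""

    n: float                 # apparent reaction order (slope)
    k: float                 # rate constant, mol m-2 min-1 (10^intercept)
    r_squared: float
    n_stderr: float
    log10_k_stderr: float
    s: float = 1.0
    label: str = ""
    n_points: int = 0

    @property
    def n_rounded(self) -> int:
        """Order rounded to the nearest integer (conventional reporting)."""
        return int(round(self.n))


@dataclass
class TitrationTrace:
    """Cumulative titrant volume against time from a constant-composition run.

    The titrant replaces lattice ions consumed by dissolution, so the slope
    of moles-added versus time is the absolute dissolution rate; dividing by
    the seed surface area (seed mass × BET specific surface area) gives the
    surface-normalized rate.
    """

    times: Sequence[float]          # min
    titrant_volume: Sequence[float]  # cm3, cumulative
    titrant_conc: float             # mol dm-3
    seed_mass: float                # mg
    specific_surface_area: float = BET_SSA  # m2 g-1

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.titrant_volume, dtype=float)
        if t.size != v.size:
            raise ValidationError("times and volumes differ in length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValidationError("times must be strictly increasing")
        if v.size >= 2 and np.any(np.diff(v) < -1e-12 * max(1.0, float(np.max(np.abs(v))))):
            raise ValidationError("titrant volume must be non-decreasing")


def relative_undersaturation(h_sqrt: float, h0_sqrt: float = H0_SQRT_COM) -> float:
    """σ = (H₀^{1/2} − H^{1/2}) / H₀^{1/2}.

    0 at saturation, 1 in pure solvent.  An ion product above solubility
    means the solution is supersaturated and the dissolution model does not
    apply.
    """
    if h0_sqrt <= 0:
        raise ValidationError("h0_sqrt must be positive")
    if h_sqrt < 0:
        raise ValidationError("h_sqrt must be non-negative")
    if h_sqrt > h0_sqrt:
        raise SupersaturationError(
            f"ion product sqrt {h_sqrt:g} exceeds solubility {h0_sqrt:g}: "
            "solution is supersaturated"
        )
    return (h0_sqrt - h_sqrt) / h0_sqrt


def rate_from_titration(trace: TitrationTrace, burn_in_fraction: float = 0.0) -> float:
    """Surface-normalized dissolution rate from a titrant-volume record.

    Least-squares slope of moles-added versus time over the steady segment
    (optionally discarding a leading ``burn_in_fraction`` of the samples),
    divided by seed area = seed_mass × SSA.  Units: mol m⁻² min⁻¹.
    """
    if not 0.0 <= burn_in_fraction < 1.0:
        raise ValidationError("burn_in_fraction must be in [0, 1)")
    t = np.asarray(trace.times, dtype=float)
    v = np.asarray(trace.titrant_volume, dtype=float)
    if t.size < 2:
        raise ValidationError("need at least two titration samples")
    start = int(burn_in_fraction * t.size)
    if t.size - start < 2:
        start = t.size - 2
    t, v = t[start:], v[start:]
    moles = v * 1e-3 * trace.titrant_conc  # cm3 -> dm3
    slope = np.polyfit(t, moles, 1)[0]
    area_m2 = trace.seed_mass * 1e-3 * trace.specific_surface_area
    return float(slope / area_m2)


def fit_rate_law(run: DissolutionRun) -> RateLawFit:
    """Fit R = k·σⁿ (s = 1) by OLS on log₁₀R vs log₁₀σ.

    Slope = n, 10^intercept = k.  Equivalent to the conventional
    −log R vs −log σ plot (same slope, same intercept).  Stirring speed is
    deliberately not part of the model: for a surface-controlled reaction the
    rate is transport-independent.
    """
    if len(run.points) < 3:
        raise ValidationError("need at least 3 points to fit the rate law")
    sig, r = run.sigmas, run.rates
    if np.any(sig <= 0) or np.any(r <= 0):
        raise ValidationError("all sigma and rate values must be positive")
    x, y = np.log10(sig), np.log10(r)
    if np.ptp(x) == 0:
        raise FitError("degenerate design: all sigma values identical")
    res = stats.linregress(x, y)
    return RateLawFit(
        n=float(res.slope),
        k=float(10.0 ** res.intercept),
        r_squared=float(res.rvalue ** 2),
        n_stderr=float(res.stderr),
        log10_k_stderr=float(res.intercept_stderr),
        label=run.label,
        n_points=len(run.points),
    )


def percent_inhibition(rate_control: float, rate_inhibited: float) -> float:
    """Percent reduction of the dissolution rate, 100·(R₀ − Rᵢ)/R₀.

    A rate above the control (promotion) yields a negative value and a
    warning rather than an error.
    """
    if rate_control <= 0:
        raise ValidationError("control rate must be positive")
    if rate_inhibited <= 0:
        raise ValidationError("inhibited rate must be positive")
    value = 100.0 * (rate_control - rate_inhibited) / rate_control
    if value < 0:
        warnings.warn(
            "inhibited rate exceeds control: promotion (negative inhibition)",
            stacklevel=2,
        )
    return value
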