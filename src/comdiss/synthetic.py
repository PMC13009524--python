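"""Synthetic dissolution experiments with known ground truth.

The generators embody the same models the analysis fits — the power rate law
R = k·σⁿ, Langmuir site blocking Rᵢ = R₀(1 − θ) with θ = K·C/(1 + K·C), and
a linear constant-composition titration record — with multiplicative
log-normal noise (rates are strictly positive and span half a decade, so
relative noise is the natural model).  Defaults clone the experimental
design: the σ grid and inhibitor-concentration grid of the printed tables,
the reported rate constant and order, and a 2 % coefficient of variation.
Everything is bit-reproducible for a fixed ``rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .adsorption import InhibitionPoint
from .constants import BET_SSA, H0_SQRT_COM
from .errors import ValidationError
from .kinetics import DissolutionRun, RatePoint, TitrationTrace

__all__ = [
    "SyntheticConfig",
    "generate_rate_table",
    "generate_inhibition_table",
    "generate_titration_series",
    "SIGMA_GRID_DEFAULT",
    "CONC_GRID_DEFAULT",
]

#: σ grid of the dissolution experiments (8 runs, 0.10–0.28).
SIGMA_GRID_DEFAULT = (0.10, 0.12, 0.15, 0.17, 0.20, 0.25, 0.27, 0.28)

#: Inhibitor concentration grid, mol dm⁻³ (11 runs, 2–10 µM).
CONC_GRID_DEFAULT = tuple(
    c * 1e-6 for c in (2.0, 2.22, 2.5, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0)
)


@dataclass
class SyntheticConfig:
    """Ground-truth parameters and design of a synthetic experiment.

    ``k_true`` and ``kl_true`` default to the experimentally reported rate
    constant and Langmuir affinity; ``n_true`` to the reported order 2.
    """

    k_true: float = 4.769e-5       # mol m-2 min-1
    n_true: float = 2.0
    kl_true: float = 2.274e4       # dm3 mol-1
    h0_sqrt: float = H0_SQRT_COM   # mol dm-3
    sigma_grid: tuple = SIGMA_GRID_DEFAULT
    conc_grid: tuple = CONC_GRID_DEFAULT
    noise_cv: float = 0.02         # relative (multiplicative) noise; 0 = exact
    rng_seed: int = 0
    seed_mass: float = 10.0        # mg
    stirring: float = 300.0        # rpm

    def __post_init__(self):
        if self.k_true <= 0 or self.n_true <= 0 or self.kl_true <= 0:
            raise ValidationError("k_true, n_true, kl_true must be positive")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be non-negative")
        if not self.sigma_grid or not self.conc_grid:
            raise ValidationError("sigma_grid and conc_grid must be non-empty")
        for s in self.sigma_grid:
            if not 0.0 < s < 1.0:
                raise ValidationError(f"sigma {s} outside (0, 1)")


def _noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    return np.exp(rng.normal(0.0, cv, size))


def generate_rate_table(config: SyntheticConfig) -> DissolutionRun:
    """One rate point per σ in the grid: R = k·σⁿ·exp(ε), ε ~ N(0, cv)."""
    rng = np.random.default_rng(config.rng_seed)
    sig = np.asarray(config.sigma_grid, dtype=float)
    rates = config.k_true * sig ** config.n_true * _noise(rng, config.noise_cv, sig.size)
    points = [
        RatePoint(
            sigma=float(s),
            rate=float(r),
            t_ca=float(config.h0_sqrt * (1.0 - s)),
            seed_mass=config.seed_mass,
            stirring=config.stirring,
        )
        for s, r in zip(sig, rates)
    ]
    return DissolutionRun(points=points, label="synthetic")


def generate_inhibition_table(
    config: SyntheticConfig, r0: float
) -> list[InhibitionPoint]:
    """Langmuir-blocked rates Rᵢ = R₀·(1 − θ(C))·exp(ε), θ = K·C/(1+K·C)."""
    if r0 <= 0:
        raise ValidationError("control rate r0 must be positive")
    rng = np.random.default_rng(config.rng_seed + 1)  # independent of the rate table
    c = np.asarray(config.conc_grid, dtype=float)
    theta = config.kl_true * c / (1.0 + config.kl_true * c)
    rates = r0 * (1.0 - theta) * _noise(rng, config.noise_cv, c.size)
    return [
        InhibitionPoint(conc=float(ci), rate_inhibited=float(ri), rate_control=r0)
        for ci, ri in zip(c, rates)
    ]


def generate_titration_series(
    rate: float,
    seed_mass: float = 10.0,
    ssa: float = BET_SSA,
    titrant_conc: float = 0.01,
    duration: float = 30.0,
    interval: float = 1.0,
    noise_cv: float = 0.0,
    rng_seed: int = 0,
) -> TitrationTrace:
    """Constant-composition titration record for a given dissolution rate.

    Mean volume slope is rate·(seed area)/titrant concentration; noise is
    multiplicative on the per-interval volume increments, so the cumulative
    record stays non-decreasing.  Units: rate mol m⁻² min⁻¹, seed mass mg,
    SSA m² g⁻¹, titrant mol dm⁻³, time min, volume cm³.
    """
    if rate < 0:
        raise ValidationError("rate must be non-negative")
    if min(seed_mass, ssa, titrant_conc, duration, interval) <= 0:
        raise ValidationError("all titration parameters must be positive")
    n_steps = round(duration / interval)
    if abs(n_steps * interval - duration) > 1e-9 * duration:
        raise ValidationError("interval must divide duration")
    rng = np.random.default_rng(rng_seed)
    area_m2 = seed_mass * 1e-3 * ssa
    dv = rate * area_m2 / titrant_conc * 1e3 * interval  # cm3 per interval
    increments = dv * _noise(rng, noise_cv, n_steps)
    times = np.arange(n_steps + 1, dtype=float) * interval
    volumes = np.concatenate([[0.0], np.cumsum(increments)])
    return TitrationTrace(
        times=times,
        titrant_volume=volumes,
        titrant_conc=titrant_conc,
        seed_mass=seed_mass,
        specific_surface_area=ssa,
    )
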