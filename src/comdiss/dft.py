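"""Scalar energy bookkeeping for the electronic-structure results.

Only arithmetic over pre-computed total and frontier-orbital energies lives
here: the HOMO–LUMO gap, the adsorption (binding) energy of a complex
relative to its isolated parts, and the physisorption classification.
No electronic-structure calculation is performed.
"""

from __future__ import annotations

from dataclasses import dataclass

from .constants import PHYSISORPTION_THRESHOLD_EV
from .errors import ValidationError

__all__ = [
    "EnergyRecord",
    "energy_gap",
    "adsorption_energy",
    "is_physisorption",
    "gap_widening",
]


@dataclass(frozen=True)
class EnergyRecord:
    """Energies (eV) of one system; orbital energies and gap are optional.

    A pre-computed gap may be supplied directly via ``e_gap`` when the
    underlying orbital energies are not available.
    """

    label: str
    e_total: float | None = None
    e_homo: float | None = None
    e_lumo: float | None = None
    e_gap: float | None = None

    def __post_init__(self):
        if self.e_homo is not None and self.e_lumo is not None:
            if self.e_lumo < self.e_homo:
                raise ValidationError(
                    f"{self.label}: LUMO below HOMO ({self.e_lumo} < {self.e_homo})"
                )
        if self.e_gap is not None and self.e_gap < 0:
            raise ValidationError(f"{self.label}: negative energy gap")


def energy_gap(record: EnergyRecord) -> float:
    """E_g = E_LUMO − E_HOMO in eV; falls back to a directly supplied gap."""
    if record.e_homo is not None and record.e_lumo is not None:
        return record.e_lumo - record.e_homo
    if record.e_gap is not None:
        return record.e_gap
    raise ValidationError(f"{record.label}: no orbital energies or gap available")


def adsorption_energy(
    complex_: EnergyRecord, part_a: EnergyRecord, part_b: EnergyRecord
) -> float:
    """E_a = E_complex − (E_a + E_b) in eV; negative means favorable binding."""
    for rec in (complex_, part_a, part_b):
        if rec.e_total is None:
            raise ValidationError(f"{rec.label}: total energy missing")
    return complex_.e_total - (part_a.e_total + part_b.e_total)


def is_physisorption(
    e_a: float, threshold: float = PHYSISORPTION_THRESHOLD_EV
) -> bool:
    """True when the binding is weaker than the chemisorption threshold.

    Convention: |E_a| below ~0.5 eV (i.e. E_a above −0.5 eV for a bound
    complex) indicates hydrogen-bond/van-der-Waals physisorption.
    """
    return e_a > threshold


def gap_widening(gap_before: float, gap_after: float) -> float:
    """Change in HOMO–LUMO gap on complexation, eV (positive = widening)."""
    if gap_before < 0 or gap_after < 0:
        raise ValidationError("gaps must be non-negative")
    return gap_after - gap_before
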