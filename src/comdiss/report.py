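"""End-to-end analysis: rate law → Langmuir adsorption → energetics.

``run_paper_analysis`` composes the individual stages in the order the
experiments dictate and returns a single serializable report; the CLI and
the analysis drivers are thin wrappers around it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

from . import __version__ as _version
from .adsorption import (
    InhibitionPoint,
    LangmuirFit,
    langmuir_isotherm_fit,
    langmuir_kinetic_fit,
)
from .constants import H0_SQRT_COM, T_GIBBS_K, WATER_MOLARITY
from .dft import EnergyRecord, adsorption_energy, energy_gap, gap_widening, is_physisorption
from .errors import ValidationError
from .kinetics import DissolutionRun, RateLawFit, fit_rate_law, percent_inhibition

__all__ = ["AnalysisConfig", "AnalysisReport", "run_paper_analysis"]


@dataclass
class AnalysisConfig:
    """Shared constants of one analysis."""

    h0_sqrt: float = H0_SQRT_COM
    temperature_k: float = T_GIBBS_K
    water_molarity: float = WATER_MOLARITY
    sigma_mode: str = "total"  # "total" | "speciated"; recorded in the report


@dataclass
class AnalysisReport:
    """Structured result of a full analysis; JSON round-trips losslessly."""

    rate_law: dict = field(default_factory=dict)       # label -> fit dict
    adsorption: dict | None = None
    energetics: dict | None = None
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "rate_law": self.rate_law,
            "adsorption": self.adsorption,
            "energetics": self.energetics,
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        """Deterministic serialization: sorted keys, repr floats, no times."""
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisReport":
        d = json.loads(text)
        return cls(
            rate_law=d.get("rate_law", {}),
            adsorption=d.get("adsorption"),
            energetics=d.get("energetics"),
            provenance=d.get("provenance", {}),
        )


def _fit_dict(fit: RateLawFit | LangmuirFit) -> dict:
    return asdict(fit)


def hash_file(path) -> str:
    with open(path, "rb") as fh:
        return hashlib.sha256(fh.read()).hexdigest()


def run_paper_analysis(
    runs: list[DissolutionRun],
    inhibition: list[InhibitionPoint] | None = None,
    energies: dict[str, EnergyRecord] | None = None,
    config: AnalysisConfig | None = None,
    provenance: dict | None = None,
) -> AnalysisReport:
    """Run the complete pipeline on in-memory inputs.

    At least one run labelled ``control`` (or the single run provided) is
    required; the adsorption and energetics stages are optional and omitted
    from the report when their inputs are absent.  The result is a pure
    function of the inputs — rerunning yields an identical report.
    """
    config = config or AnalysisConfig()
    if not runs:
        raise ValidationError("at least one (control) dissolution run is required")
    labels = [r.label for r in runs]
    if "control" not in labels and len(runs) > 1:
        raise ValidationError("no run labelled 'control' among multiple runs")

    report = AnalysisReport(
        provenance={
            "software": f"comdiss {_version}",
            "config": asdict(config),
            **(provenance or {}),
        }
    )

    for run in runs:
        try:
            report.rate_law[run.label] = _fit_dict(fit_rate_law(run))
        except Exception as exc:
            raise type(exc)(f"rate-law stage ({run.label}): {exc}") from exc

    if inhibition:
        try:
            kin = langmuir_kinetic_fit(inhibition)
            iso = langmuir_isotherm_fit(
                inhibition,
                temperature=config.temperature_k,
                water_molarity=config.water_molarity,
            )
        except Exception as exc:
            raise type(exc)(f"adsorption stage: {exc}") from exc
        table = [
            {
                "conc_molar": p.conc,
                "rate_inhibited": p.rate_inhibited,
                "rate_control": p.rate_control,
                "percent_inhibition": percent_inhibition(p.rate_control, p.rate_inhibited),
                "theta": 1.0 - p.rate_inhibited / p.rate_control,
            }
            for p in inhibition
        ]
        report.adsorption = {
            "kinetic_fit": _fit_dict(kin),
            "isotherm_fit": _fit_dict(iso),
            "K_L": kin.constant,
            "K_ads": iso.constant,
            "delta_G_ads_kJ_per_mol": iso.delta_g,
            "inhibition_table": table,
        }

    if energies:
        ener: dict = {"records": {k: asdict(v) for k, v in energies.items()}}
        if {"complex", "caffeine", "caox"} <= set(energies):
            e_a = adsorption_energy(
                energies["complex"], energies["caffeine"], energies["caox"]
            )
            ener["adsorption_energy_eV"] = e_a
            ener["physisorption"] = is_physisorption(e_a)
        gaps = {
            k: energy_gap(v)
            for k, v in energies.items()
            if v.e_gap is not None or (v.e_homo is not None and v.e_lumo is not None)
        }
        ener["gaps_eV"] = gaps
        if {"caffeine", "complex"} <= set(gaps):
            ener["gap_widening_eV"] = gap_widening(gaps["caffeine"], gaps["complex"])
        report.energetics = ener

    return report
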