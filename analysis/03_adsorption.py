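#!/usr/bin/env python
"""Langmuir analysis of the inhibition series: K_L, K_ads and ΔG_ads.

Recomputes surface coverage θ = 1 − Rᵢ/R₀ from the rates, fits the kinetic
(R₀/(R₀−Rᵢ) vs 1/C) and equilibrium (C/θ vs C) linearizations, and
evaluates the Gibbs free energy of adsorption with the 55.5 mol dm⁻³
water standard-state convention.  Writes results/adsorption.json and
results/inhibition_table.csv.
"""

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from comdiss.adsorption import (
    gibbs_adsorption,
    langmuir_isotherm_fit,
    langmuir_kinetic_fit,
    surface_coverage,
)
from comdiss.datasets import load_inhibition_points
from comdiss.kinetics import percent_inhibition

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    r0, points = load_inhibition_points()
    kin = langmuir_kinetic_fit(points)
    iso = langmuir_isotherm_fit(points)

    table = pd.DataFrame(
        {
            "conc_molar": [p.conc for p in points],
            "rate_inhibited": [p.rate_inhibited for p in points],
            "percent_inhibition": [
                percent_inhibition(p.rate_control, p.rate_inhibited) for p in points
            ],
            "theta": [surface_coverage(p) for p in points],
        }
    )
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "inhibition_table.csv", index=False)
    payload = {
        "r0": r0,
        "kinetic_fit": asdict(kin),
        "isotherm_fit": asdict(iso),
        "delta_G_ads_literal_kJ_per_mol": gibbs_adsorption(iso.constant, 310.0, 1.0),
    }
    (OUT / "adsorption.json").write_text(json.dumps(payload, indent=2, sort_keys=True))

    print(table.to_string(index=False, float_format=lambda x: f"{x:.4g}"))
    print(
        f"\nkinetic Langmuir:  K_L   = {kin.constant:.4g} dm3/mol "
        f"(intercept {kin.intercept:.3f}, ideal 1; r² = {kin.r_squared:.4f})"
    )
    print(
        f"isotherm Langmuir: K_ads = {iso.constant:.4g} dm3/mol "
        f"(slope {iso.slope:.3f}, ideal 1; r² = {iso.r_squared:.4f})"
    )
    print(
        f"dG_ads = {iso.delta_g:.3f} kJ/mol with the 55.5 M water convention "
        f"({payload['delta_G_ads_literal_kJ_per_mol']:.3f} kJ/mol on the literal "
        "molar scale) — strong, favorable physisorption-level adsorption."
    )
    print(
        "The two independent linearizations agree to "
        f"{abs(kin.constant - iso.constant) / iso.constant:.1%}, supporting "
        "single-site Langmuir blocking; coverage at 10 µM is only "
        f"{table.theta.iloc[-1]:.0%}, i.e. inhibition is far from saturation."
    )
    print(f"wrote {OUT / 'adsorption.json'} and {OUT / 'inhibition_table.csv'}")


if __name__ == "__main__":
    main()
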