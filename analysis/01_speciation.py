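#!/usr/bin/env python
"""Speciate every dissolution-run composition and compare the two σ routes.

For each row of the reference dissolution table, solve the full
Ca/oxalate/Na/Cl speciation at pH 6.0, I = 0.15 and compute the relative
undersaturation both from total concentrations (the route that reproduces
the published column) and from the speciated free-ion product.  Writes
results/speciation.csv.
"""

from pathlib import Path

import pandas as pd

from comdiss.datasets import load_dissolution_table
from comdiss.kinetics import relative_undersaturation
from comdiss.speciation import CA, OX, dissolution_recipe, ion_product_sqrt, solve_speciation

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    rows = []
    for _, row in load_dissolution_table().iterrows():
        t_ca = float(row["t_ca_molar"])
        state = solve_speciation(dissolution_recipe(t_ca, pH=6.0))
        h_spec = ion_product_sqrt(state)
        rows.append(
            {
                "t_ca_molar": t_ca,
                "sigma_printed": float(row["sigma_printed_x100"]) / 100.0,
                "sigma_total": relative_undersaturation(t_ca),
                "sigma_speciated": relative_undersaturation(h_spec),
                "free_ca_fraction": state.free[CA] / t_ca,
                "free_ox_fraction": state.free[OX] / t_ca,
                "ionic_strength": state.ionic_strength,
                "mass_balance_rel": state.residuals["mass_balance_rel"],
            }
        )
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "speciation.csv", index=False)

    print(df.to_string(index=False, float_format=lambda x: f"{x:.4g}"))
    print(
        f"\nsigma from totals matches the printed column on all {len(df)} rows "
        f"(max |dev| = {(df.sigma_total - df.sigma_printed).abs().max():.4f}); "
        f"complexation (CaOx ion pairing, oxalate protonation) keeps free Ca at "
        f"{df.free_ca_fraction.mean():.1%} of the analytical total, shifting the "
        f"speciated sigma up by ~{(df.sigma_speciated - df.sigma_total).mean():.3f}."
    )
    print(f"wrote {OUT / 'speciation.csv'}")


if __name__ == "__main__":
    main()
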