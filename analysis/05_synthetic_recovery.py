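#!/usr/bin/env python
"""Parameter-recovery study on synthetic data with known ground truth.

Generates 500 replicate experiments at the reference design (8-point σ grid,
11-point concentration grid, 2% multiplicative rate noise) and measures how
well the fitting pipeline recovers the generating parameters.  The rate
order is recovered essentially perfectly; the Langmuir constants are not —
at coverages of 0.04–0.19 the response R₀ − Rᵢ is noise-dominated and the
reciprocal linearizations amplify the scatter (median relative error
~20–30%).  Writes results/synthetic_recovery.json.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from comdiss.adsorption import langmuir_isotherm_fit, langmuir_kinetic_fit
from comdiss.kinetics import fit_rate_law
from comdiss.synthetic import SyntheticConfig, generate_inhibition_table, generate_rate_table

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--replicates", type=int, default=500)
    args = parser.parse_args()

    n_err, kl_err, ka_err = [], [], []
    base = (args.seed * 100003 + 7) % (2**31 - 1)
    for i in range(args.replicates):
        cfg = SyntheticConfig(noise_cv=0.02, rng_seed=(base + i) % (2**31 - 1))
        fit = fit_rate_law(generate_rate_table(cfg))
        n_err.append(abs(fit.n - cfg.n_true))
        r0 = cfg.k_true * 0.20 ** cfg.n_true
        pts = [p for p in generate_inhibition_table(cfg, r0)
               if p.rate_inhibited < p.rate_control]
        kl_err.append(abs(langmuir_kinetic_fit(pts).constant - cfg.kl_true) / cfg.kl_true)
        ka_err.append(abs(langmuir_isotherm_fit(pts).constant - cfg.kl_true) / cfg.kl_true)

    payload = {
        "replicates": args.replicates,
        "noise_cv": 0.02,
        "median_abs_n_error": float(np.median(n_err)),
        "median_rel_KL_error": float(np.median(kl_err)),
        "median_rel_Kads_error": float(np.median(ka_err)),
        "q90_rel_KL_error": float(np.quantile(kl_err, 0.9)),
    }
    OUT.mkdir(exist_ok=True)
    (OUT / "synthetic_recovery.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True)
    )

    print(f"{args.replicates} replicates at 2% multiplicative rate noise:")
    print(f"  median |n_hat - 2|          = {payload['median_abs_n_error']:.3f}")
    print(f"  median rel. error of K_L    = {payload['median_rel_KL_error']:.3f}")
    print(f"  median rel. error of K_ads  = {payload['median_rel_Kads_error']:.3f}")
    print(
        "\nThe rate order is robust; the Langmuir constants are noise-limited "
        "at these low coverages, so the near-exact agreement of the reference "
        "table fits with the published constants implies the measured rates "
        "carry far less than 2% independent scatter."
    )
    print(f"wrote {OUT / 'synthetic_recovery.json'}")


if __name__ == "__main__":
    main()
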