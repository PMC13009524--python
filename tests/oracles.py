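"""Independent oracles used to cross-check the package's solvers.

The speciation oracle is a damped fixed-point (successive-substitution)
iteration written in plain scalar Python — deliberately sharing no code
with the Newton solver it checks.
"""

from __future__ import annotations

import math


def davies_gamma(charge: int, ionic_strength: float, A: float) -> float:
    if charge == 0 or ionic_strength == 0.0:
        return 1.0
    s = math.sqrt(ionic_strength)
    return 10.0 ** (-A * charge * charge * (s / (1.0 + s) - 0.3 * ionic_strength))


def fixed_point_speciation(
    totals: dict[str, float],
    pH: float,
    reactions,
    charges: dict[str, int],
    A: float = 0.5215,
    charge_balance_on: str = "Cl-",
    damp: float = 0.5,
    tol: float = 1e-14,
    max_inner: int = 200000,
    max_outer: int = 200,
):
    """Free concentrations by damped successive substitution.

    Mass-balance components are updated as c ← c·(T/T_calc)^damp; the
    charge-balance component (assumed complex-free) is set directly from
    electroneutrality.  Activity coefficients are refreshed in an outer
    loop until the ionic strength is stable to 1e-9.
    """
    comp = [n for n in totals if n != "H+"]
    a_h = 10.0 ** (-pH)
    c = {n: max(totals[n], 1e-12) for n in comp}
    scale = max(list(totals.values()) + [a_h])
    I = 0.5 * sum(totals[n] * charges[n] ** 2 for n in comp) + 0.5 * a_h

    for _outer in range(max_outer):
        gamma = {n: davies_gamma(charges[n], I, A) for n in charges}
        h_free = a_h / gamma["H+"]
        for _ in range(max_inner):
            # complexes from mass action on activities
            cx = {}
            for rxn in reactions:
                log_a = rxn.logK
                ok = True
                for r, nu in rxn.reactants.items():
                    a_r = a_h if r == "H+" else gamma[r] * c[r]
                    if a_r <= 0.0:
                        if nu > 0:
                            ok = False
                            break
                        raise ZeroDivisionError
                    log_a += nu * math.log10(a_r)
                cx[rxn.product] = (10.0 ** log_a) / gamma[rxn.product] if ok else 0.0
            # reconstruct totals
            t_calc = {n: c[n] for n in comp}
            for rxn in reactions:
                for r, nu in rxn.reactants.items():
                    if r in t_calc:
                        t_calc[r] += nu * cx[rxn.product]
            worst = 0.0
            for n in comp:
                if n == charge_balance_on:
                    continue
                if totals[n] == 0.0:
                    c[n] = 0.0
                    continue
                worst = max(worst, abs(t_calc[n] - totals[n]) / scale)
                c[n] = c[n] * (totals[n] / t_calc[n]) ** damp
            # electroneutrality fixes the background anion
            if charge_balance_on is not None:
                net = h_free * charges["H+"]
                for n in comp:
                    if n != charge_balance_on:
                        net += charges[n] * c[n]
                for name, conc in cx.items():
                    net += charges[name] * conc
                required = net / (-charges[charge_balance_on])
                if required <= 0:
                    raise ValueError("charge balance infeasible")
                worst = max(worst, abs(required - c[charge_balance_on]) / scale)
                c[charge_balance_on] = required
            if worst <= tol:
                break
        else:
            raise RuntimeError("fixed-point iteration did not converge")
        species = dict(c)
        species["H+"] = h_free
        species.update(cx)
        I_new = 0.5 * sum(charges[n] * charges[n] * v for n, v in species.items())
        if abs(I_new - I) <= 1e-9:
            I = I_new
            break
        I = I_new
    else:
        raise RuntimeError("ionic-strength loop did not converge")

    return species, I
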