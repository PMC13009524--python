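"""Aqueous speciation of the Ca²⁺/oxalate/Na⁺/Cl⁻ system.

Free-ion concentrations are obtained from total (analytical) concentrations
by solving the coupled mass-balance equations under mass-action constraints,
with activity coefficients from the Davies modification of the extended
Debye–Hückel equation and the proton activity fixed by pH.  The solver is a
Newton iteration on log-concentrations (which keeps every concentration
strictly positive) wrapped in an outer loop that re-estimates the ionic
strength and the activity coefficients until self-consistent.

The quantity this module ultimately feeds the kinetics stage is
``sqrt([Ca2+][C2O4 2-])``, the square root of the free-ion concentration
product whose equilibrium value defines the solubility of calcium oxalate
monohydrate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml

from .constants import DAVIES_A_37C, T_EXPERIMENT_K
from .errors import ConvergenceError, StateError, ValidationError

__all__ = [
    "IonSpecies",
    "EquilibriumReaction",
    "SolutionRecipe",
    "SpeciationState",
    "SpeciationConstants",
    "load_constants",
    "default_constants",
    "ionic_strength",
    "davies_log_gamma",
    "solve_speciation",
    "ion_product_sqrt",
    "dissolution_recipe",
]

# canonical species names used throughout the package
CA = "Ca2+"
OX = "Ox2-"
NA = "Na+"
CL = "Cl-"
H = "H+"

#: Charges of the bundled species; a user constants file may extend this.
DEFAULT_CHARGES: dict[str, int] = {
    CA: 2, OX: -2, NA: 1, CL: -1, H: 1,
    "OH-": -1, "CaOx": 0, "CaHOx+": 1, "HOx-": -1, "H2Ox": 0,
    "NaOx-": -1, "CaOH+": 1,
}


@dataclass(frozen=True)
class IonSpecies:
    """A dissolved species: a free component or a derived complex."""

    name: str
    charge: int
    role: str = "component"  # "component" | "complex"

    def __post_init__(self):
        if abs(self.charge) > 3:
            raise ValidationError(
                f"species {self.name!r}: |charge| {abs(self.charge)} > 3 "
                "is outside the supported set"
            )
        if self.role not in ("component", "complex"):
            raise ValidationError(f"species {self.name!r}: unknown role {self.role!r}")


@dataclass(frozen=True)
class EquilibriumReaction:
    """Formation of one complex from components.

    ``reactants`` maps component names to stoichiometric coefficients; a
    negative coefficient on H⁺ denotes proton release (water implicit), so
    OH⁻ is ``{H+: -1}`` with ``logK = -pKw``.  ``logK`` is the thermodynamic
    (activity-scale) association constant at the working temperature.
    """

    product: str
    reactants: Mapping[str, float]
    logK: float
    source: str = ""

    def __post_init__(self):
        if not math.isfinite(self.logK):
            raise ValidationError(f"reaction {self.product!r}: logK must be finite")

    def charge_balance_defect(self, charges: Mapping[str, int]) -> float:
        """Product charge minus summed reactant charge; 0 for a valid reaction."""
        rhs = sum(nu * charges[r] for r, nu in self.reactants.items())
        return charges[self.product] - rhs


@dataclass(frozen=True)
class SolutionRecipe:
    """Analytical composition of one experimental solution.

    Parameters
    ----------
    totals
        Total (analytical) molar concentrations of the components, e.g.
        ``{"Ca2+": 1.791e-4, "Ox2-": 1.791e-4, "Na+": ..., "Cl-": ...}``.
    pH
        Fixes the proton *activity*: a(H⁺) = 10^(−pH).
    temperature
        Kelvin; informational (no logK temperature correction is applied).
    target_ionic_strength
        The NaCl-adjusted design value, mol dm⁻³; used only as the starting
        guess for the self-consistent ionic-strength loop.
    """

    totals: Mapping[str, float]
    pH: float = 6.0
    temperature: float = T_EXPERIMENT_K
    target_ionic_strength: float | None = None

    def __post_init__(self):
        for name, t in self.totals.items():
            if t < 0:
                raise ValidationError(f"total concentration of {name} is negative")
        if not 0.0 < self.pH < 14.0:
            raise ValidationError(f"pH {self.pH} outside (0, 14)")
        if self.temperature <= 0:
            raise ValidationError("temperature must be positive")


@dataclass
class SpeciationState:
    """Converged (or failed) speciation result."""

    free: dict[str, float]
    gamma: dict[str, float]
    ionic_strength: float
    converged: bool
    residuals: dict[str, float]
    #: totals actually satisfied (the charge-balancing component's total is
    #: adjusted by the solver; all others equal the recipe's input).
    totals_effective: dict[str, float] = field(default_factory=dict)
    iterations: int = 0


@dataclass
class SpeciationConstants:
    """Bundle of species definitions, reactions and physical constants."""

    species: dict[str, IonSpecies]
    reactions: list[EquilibriumReaction]
    physical: dict[str, float]
    #: reactions present in the file but excluded from the default set
    disabled_reactions: list[EquilibriumReaction] = field(default_factory=list)

    @property
    def charges(self) -> dict[str, int]:
        return {name: sp.charge for name, sp in self.species.items()}


def load_constants(path=None) -> SpeciationConstants:
    """Load a constants config (YAML); default to the packaged file.

    The file has three blocks: ``species`` (name, charge, role),
    ``reactions`` (product, reactants, logK, enabled, source) and
    ``physical`` (Debye–Hückel A, water molarity, gas constant, ...).
    Charge conservation is checked for every reaction.
    """
    if path is None:
        text = (resources.files("comdiss") / "data" / "constants.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    species = {
        s["name"]: IonSpecies(s["name"], int(s["charge"]), s.get("role", "component"))
        for s in raw["species"]
    }
    charges = {name: sp.charge for name, sp in species.items()}
    enabled, disabled = [], []
    for r in raw["reactions"]:
        rxn = EquilibriumReaction(
            product=r["product"],
            reactants=dict(r["reactants"]),
            logK=float(r["logK"]),
            source=r.get("source", ""),
        )
        defect = rxn.charge_balance_defect(charges)
        if defect != 0:
            raise ValidationError(
                f"reaction forming {rxn.product!r} violates charge conservation "
                f"(defect {defect:+d})"
            )
        (enabled if r.get("enabled", True) else disabled).append(rxn)
    return SpeciationConstants(
        species=species,
        reactions=enabled,
        physical={k: float(v) for k, v in raw["physical"].items()},
        disabled_reactions=disabled,
    )


_DEFAULT: SpeciationConstants | None = None


def default_constants() -> SpeciationConstants:
    """The packaged constants, loaded once and cached."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_constants()
    return _DEFAULT


def ionic_strength(
    free: Mapping[str, float], charges: Mapping[str, int] | None = None
) -> float:
    """Ionic strength ``I = ½ Σ cᵢ zᵢ²`` in mol dm⁻³.

    ``charges`` defaults to the bundled species registry; every species in
    ``free`` must have a known charge.
    """
    if charges is None:
        charges = DEFAULT_CHARGES
    total = 0.0
    for name, c in free.items():
        if c < 0:
            raise ValidationError(f"negative concentration for {name}")
        total += c * charges[name] ** 2
    return 0.5 * total


def davies_log_gamma(charge: int, I: float, A: float = DAVIES_A_37C) -> float:
    """log₁₀ activity coefficient from the Davies equation.

    ``log γ = −A z² (√I/(1+√I) − 0.3 I)``; zero for neutral species and at
    infinite dilution.  Empirically valid up to I ≈ 0.5 mol dm⁻³.
    """
    if I < 0:
        raise ValidationError("ionic strength must be non-negative")
    if A <= 0:
        raise ValidationError("Debye-Hueckel constant A must be positive")
    if charge == 0 or I == 0.0:
        return 0.0
    sqrt_i = math.sqrt(I)
    return -A * charge * charge * (sqrt_i / (1.0 + sqrt_i) - 0.3 * I)


def dissolution_recipe(
    t_ca: float,
    t_ox: float | None = None,
    pH: float = 6.0,
    ionic_strength_target: float = 0.15,
) -> SolutionRecipe:
    """Recipe for a dissolution experiment made from CaCl₂, Na₂C₂O₄ and NaCl.

    Sodium and chloride totals follow the salt stoichiometry
    (T_Na = 2·T_Ox + x, T_Cl = 2·T_Ca + x) with the NaCl addition ``x``
    chosen so the nominal (fully dissociated) ionic strength matches the
    target.  The resulting totals are electroneutral by construction.
    """
    if t_ox is None:
        t_ox = t_ca
    x = ionic_strength_target - 3.0 * (t_ca + t_ox)
    if x < 0:
        raise ValidationError(
            "target ionic strength below the contribution of the Ca/oxalate salts"
        )
    return SolutionRecipe(
        totals={CA: t_ca, OX: t_ox, NA: 2.0 * t_ox + x, CL: 2.0 * t_ca + x},
        pH=pH,
        target_ionic_strength=ionic_strength_target,
    )


def _gamma_map(names, charges, I, A):
    return {n: 10.0 ** davies_log_gamma(charges[n], I, A) for n in names}


def solve_speciation(
    recipe: SolutionRecipe,
    reactions: Sequence[EquilibriumReaction] | None = None,
    A: float | None = None,
    *,
    constants: SpeciationConstants | None = None,
    charge_balance_on: str | None = CL,
    tol: float = 1e-13,
    max_newton: int = 200,
    max_outer: int = 100,
    outer_tol: float = 1e-9,
) -> SpeciationState:
    """Solve for free-ion concentrations.

    Unknowns are the log-concentrations of the components with nonzero
    totals; [H⁺] is fixed by pH (activity basis, [H⁺] = 10^(−pH)/γ₁).  Each
    component contributes one mass-balance equation
    ``T_X = [X] + Σ ν·[complexes]``; if ``charge_balance_on`` names a
    component (chloride by default), its mass balance is replaced by the
    electroneutrality condition ``Σ z·c = 0`` and its effective total is
    reported in ``totals_effective`` — this is how the inert background
    electrolyte absorbs the small charge carried by H⁺/OH⁻.

    A Newton iteration with an analytic Jacobian and damped, backtracked
    steps runs inside an outer loop that recomputes the ionic strength from
    the full species list and updates the Davies activity coefficients until
    ``|ΔI| ≤ outer_tol``.

    Raises
    ------
    ConvergenceError
        If either loop exhausts its iteration cap; carries the residuals.
    """
    consts = constants if constants is not None else default_constants()
    if reactions is None:
        reactions = consts.reactions
    if A is None:
        A = consts.physical.get("debye_huckel_A", DAVIES_A_37C)
    charges = dict(DEFAULT_CHARGES)
    charges.update(consts.charges)

    comp_names = [n for n in recipe.totals if n != H]
    for rxn in reactions:
        for r in rxn.reactants:
            if r != H and r not in comp_names:
                raise ValidationError(
                    f"reaction forming {rxn.product!r} uses undeclared component {r!r}"
                )

    totals = {n: float(recipe.totals[n]) for n in comp_names}
    # unknowns: components with mass > 0, plus the charge-balancing one
    unknowns = [
        n for n in comp_names if totals[n] > 0 or n == charge_balance_on
    ]
    if charge_balance_on is not None and charge_balance_on not in comp_names:
        raise ValidationError(
            f"charge-balance component {charge_balance_on!r} not in recipe"
        )
    absent = [n for n in comp_names if n not in unknowns]
    n_unk = len(unknowns)
    idx = {n: i for i, n in enumerate(unknowns)}

    # complexes that involve an absent component can never form
    active_rxns = [
        r for r in reactions
        if all((c == H or c in unknowns) for c in r.reactants if r.reactants[c] > 0)
        and all(r.reactants.get(a, 0) >= 0 for a in absent)
    ]
    prod_names = [r.product for r in active_rxns]
    all_names = unknowns + [H, "OH-"] + [p for p in prod_names if p != "OH-"]

    # stoichiometry matrices over the unknown components and over H+
    nu = np.array(
        [[r.reactants.get(n, 0.0) for n in unknowns] for r in active_rxns]
    ).reshape(len(active_rxns), n_unk)  # (n_rxn, n_unk)
    nu_h = np.array([r.reactants.get(H, 0.0) for r in active_rxns])
    logK = np.array([r.logK for r in active_rxns])
    z_unk = np.array([charges[n] for n in unknowns], dtype=float)
    z_prod = np.array([charges[r.product] for r in active_rxns], dtype=float)

    maxT = max([*totals.values(), 10.0 ** (-recipe.pH), 1e-30])
    t_vec = np.array([totals[n] for n in unknowns])
    target = t_vec.copy()
    cb_row = idx.get(charge_balance_on) if charge_balance_on else None

    ln10 = math.log(10.0)
    a_h = 10.0 ** (-recipe.pH)

    # starting guesses; the charge-balance component starts from nominal
    # electroneutrality over fully dissociated totals
    c0 = np.maximum(t_vec, 1e-10)
    if cb_row is not None:
        net = float(z_unk @ np.where(np.arange(n_unk) == cb_row, 0.0, t_vec)) + a_h
        z_cb = z_unk[cb_row]
        guess = net / (-z_cb) if z_cb != 0 else 0.0
        if guess > 0:
            c0[cb_row] = guess
    u = np.log(c0)
    I = recipe.target_ionic_strength
    if I is None:
        I = ionic_strength(
            {n: totals[n] for n in unknowns} | {H: a_h}, charges
        )

    state_gamma: dict[str, float] = {}
    outer_iters = 0
    newton_total = 0
    for outer in range(max_outer):
        outer_iters = outer + 1
        gamma = _gamma_map(all_names, charges, I, A)
        state_gamma = gamma
        lg_unk = np.array([math.log10(gamma[n]) for n in unknowns])
        lg_prod = np.array([math.log10(gamma[r.product]) for r in active_rxns])
        # ln [complex] = ln10*(logK - log g_prod + nu_H*log a_H + nu.(log g + log c))
        const_term = ln10 * (logK - lg_prod + nu_h * (-recipe.pH) + nu @ lg_unk)
        h_free = a_h / gamma[H]

        def concentrations(u_vec):
            c_free = np.exp(u_vec)
            c_prod = np.exp(const_term + nu @ u_vec) if len(active_rxns) else np.empty(0)
            return c_free, c_prod

        def residual(u_vec):
            c_free, c_prod = concentrations(u_vec)
            res = c_free + (nu.T @ c_prod if len(active_rxns) else 0.0) - target
            if cb_row is not None:
                charge = float(z_unk @ c_free) + h_free
                if len(active_rxns):
                    charge += float(z_prod @ c_prod)
                res[cb_row] = charge
            return res, c_free, c_prod

        converged_inner = False
        res, c_free, c_prod = residual(u)
        for _ in range(max_newton):
            newton_total += 1
            if np.max(np.abs(res)) <= tol * maxT:
                converged_inner = True
                break
            J = np.diag(c_free)
            if len(active_rxns):
                J = J + nu.T @ (c_prod[:, None] * nu)
            if cb_row is not None:
                row = z_unk * c_free
                if len(active_rxns):
                    row = row + z_prod @ (c_prod[:, None] * nu)
                J[cb_row, :] = row
            try:
                du = np.linalg.solve(J, -res)
            except np.linalg.LinAlgError as exc:  # pragma: no cover - singular J
                raise ConvergenceError(
                    "singular Jacobian in speciation solve",
                    residuals={"max_abs": float(np.max(np.abs(res)))},
                ) from exc
            # damp (direction-preserving) and backtrack
            biggest = float(np.max(np.abs(du)))
            step = du if biggest <= 3.0 else du * (3.0 / biggest)
            norm0 = float(np.linalg.norm(res))
            lam = 1.0
            for _bt in range(40):
                trial = u + lam * step
                res_t, cf_t, cp_t = residual(trial)
                if float(np.linalg.norm(res_t)) < norm0 or lam < 1e-6:
                    u, res, c_free, c_prod = trial, res_t, cf_t, cp_t
                    break
                lam *= 0.5
        if not converged_inner and np.max(np.abs(res)) > tol * maxT:
            raise ConvergenceError(
                "speciation Newton iteration did not converge",
                residuals={"max_abs": float(np.max(np.abs(res))), "rel": float(np.max(np.abs(res)) / maxT)},
            )

        oh = c_prod[prod_names.index("OH-")] if "OH-" in prod_names else 0.0
        conc_all = {n: float(c) for n, c in zip(unknowns, c_free)}
        conc_all[H] = h_free
        for name, c in zip(prod_names, c_prod):
            conc_all[name] = float(c)
        I_new = ionic_strength(conc_all, charges)
        if abs(I_new - I) <= outer_tol:
            I = I_new
            break
        I = I_new
    else:
        raise ConvergenceError(
            "ionic-strength loop did not converge", residuals={"delta_I": abs(I_new - I)}
        )

    free = {n: float(c) for n, c in zip(unknowns, c_free)}
    for n in absent:
        free[n] = 0.0
    free[H] = h_free
    for name, c in zip(prod_names, c_prod):
        free[name] = float(c)

    # effective totals (charge-balance component reports what it absorbed)
    totals_eff = dict(totals)
    if charge_balance_on is not None:
        reconst = free[charge_balance_on]
        for r, c in zip(active_rxns, c_prod):
            reconst += r.reactants.get(charge_balance_on, 0.0) * c
        totals_eff[charge_balance_on] = float(reconst)

    # report residuals against the effective totals
    mass_res = 0.0
    for j, n in enumerate(unknowns):
        reconst = c_free[j]
        if len(active_rxns):
            reconst += float(nu[:, j] @ c_prod)
        mass_res = max(mass_res, abs(reconst - totals_eff[n]))
    charge_sum = sum(charges[n] * c for n, c in free.items())
    charge_scale = sum(abs(charges[n]) * c for n, c in free.items())

    return SpeciationState(
        free=free,
        gamma={n: state_gamma.get(n, 1.0) for n in free},
        ionic_strength=I,
        converged=True,
        residuals={
            "mass_balance_rel": mass_res / maxT,
            "charge_imbalance_rel": abs(charge_sum) / charge_scale if charge_scale else 0.0,
        },
        totals_effective=totals_eff,
        iterations=newton_total,
    )


def ion_product_sqrt(state: SpeciationState) -> float:
    """``√([Ca²⁺]·[C₂O₄²⁻])`` from a converged state, mol dm⁻³."""
    if not state.converged:
        raise StateError("speciation state is not converged")
    ca = state.free.get(CA, 0.0)
    ox = state.free.get(OX, 0.0)
    return math.sqrt(ca * ox)
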