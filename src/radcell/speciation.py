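"""Aqueous Ag-Cl speciation by mass balance.

Species considered: free Ag⁺, the neutral complex AgCl(aq) with overall
formation constant β₁ = [AgCl]/([Ag⁺][Cl⁻]), the dichloroargentate anion
AgCl₂⁻ with β₂ = [AgCl₂⁻]/([Ag⁺][Cl⁻]²), and the solid AgCl(s) governed by
the solubility product Ksp = [Ag⁺][Cl⁻] at saturation.  Concentrations are
treated as activities (no ionic-strength correction).

The solver does bracketed 1-D root finding on free chloride: at fixed
[Cl⁻] the silver mass balance is linear in free [Ag⁺], so the chloride
balance is a monotone scalar equation.  If the resulting ion product
exceeds Ksp, the saturated branch solves for the amount of solid that puts
the residual solution exactly at Ksp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

from .constants import (
    AGCL2_BETA2,
    AGCL_BETA1,
    AGCL_KSP,
    SOLUTION_TOTAL_AG,
    SOLUTION_TOTAL_CL,
)

__all__ = [
    "EquilibriumConstants",
    "SolutionComposition",
    "SpeciationResult",
    "DEFAULT_CONSTANTS",
    "ADMINISTERED_SOLUTION",
    "speciate",
    "saturation_check",
]

_RTOL = 1e-14  # relative tolerance of the outer chloride root


@dataclass(frozen=True)
class EquilibriumConstants:
    """Thermodynamic constants of the Ag-Cl system (activities = concentrations)."""

    ksp: float = AGCL_KSP        # M², AgCl(s) <-> Ag⁺ + Cl⁻
    beta1: float = AGCL_BETA1    # M⁻¹, Ag⁺ + Cl⁻ <-> AgCl(aq)
    beta2: float = AGCL2_BETA2   # M⁻², Ag⁺ + 2Cl⁻ <-> AgCl₂⁻

    def __post_init__(self) -> None:
        if min(self.ksp, self.beta1, self.beta2) <= 0:
            raise ValueError("equilibrium constants must be positive")


@dataclass(frozen=True)
class SolutionComposition:
    """Analytical (total) concentrations of silver and chloride, M."""

    total_ag: float
    total_cl: float

    def __post_init__(self) -> None:
        if self.total_ag < 0 or self.total_cl < 0:
            raise ValueError("total concentrations must be non-negative")


DEFAULT_CONSTANTS = EquilibriumConstants()
#: The solution administered to the cell cultures.
ADMINISTERED_SOLUTION = SolutionComposition(SOLUTION_TOTAL_AG, SOLUTION_TOTAL_CL)


@dataclass(frozen=True)
class SpeciationResult:
    """Equilibrium composition.  Fractions are mole fractions of total
    silver; when solid is present they still sum to 1 together with
    ``fraction_solid``."""

    fraction_free_ag: float
    fraction_agcl: float
    fraction_agcl2: float
    fraction_solid: float
    free_ag: float       # M
    free_cl: float       # M
    solid: float         # M (formally dissolved concentration of AgCl(s))
    saturated: bool
    ion_product: float   # [Ag⁺][Cl⁻], M²

    def as_dict(self) -> dict:
        return {
            "fraction_free_ag": self.fraction_free_ag,
            "fraction_agcl": self.fraction_agcl,
            "fraction_agcl2": self.fraction_agcl2,
            "fraction_solid": self.fraction_solid,
            "free_ag_M": self.free_ag,
            "free_cl_M": self.free_cl,
            "solid_M": self.solid,
            "saturated": self.saturated,
            "ion_product_M2": self.ion_product,
        }


def saturation_check(free_ag: float, free_cl: float,
                     k: EquilibriumConstants = DEFAULT_CONSTANTS) -> tuple[bool, float]:
    """Ion product [Ag⁺][Cl⁻] and whether it exceeds Ksp."""
    if free_ag < 0 or free_cl < 0:
        raise ValueError("concentrations must be non-negative")
    q = free_ag * free_cl
    return q > k.ksp, q


def _free_ag(free_cl: float, total_ag: float, k: EquilibriumConstants) -> float:
    """Free silver from the (linear) silver mass balance at fixed chloride."""
    return total_ag / (1.0 + k.beta1 * free_cl + k.beta2 * free_cl ** 2)


def _cl_residual(free_cl: float, comp: SolutionComposition,
                 k: EquilibriumConstants) -> float:
    ag = _free_ag(free_cl, comp.total_ag, k)
    bound_cl = ag * (k.beta1 * free_cl + 2.0 * k.beta2 * free_cl ** 2)
    return free_cl + bound_cl - comp.total_cl


def speciate(comp: SolutionComposition = ADMINISTERED_SOLUTION,
             k: EquilibriumConstants = DEFAULT_CONSTANTS) -> SpeciationResult:
    """Solve the full Ag-Cl equilibrium for a given analytical composition.

    Returns mole fractions of total silver in each species, the free-ion
    concentrations, and the saturation state.  Raises if the root bracket
    fails (never returns an unconverged answer silently).
    """
    if comp.total_ag == 0.0:
        # no silver: chloride stays free; report all-free by convention
        return SpeciationResult(1.0, 0.0, 0.0, 0.0, 0.0, comp.total_cl,
                                0.0, False, 0.0)
    if comp.total_cl == 0.0:
        return SpeciationResult(1.0, 0.0, 0.0, 0.0, comp.total_ag, 0.0,
                                0.0, False, 0.0)

    # Unsaturated branch: monotone residual in free Cl on [0, total_cl].
    lo, hi = 0.0, comp.total_cl
    f_lo, f_hi = _cl_residual(lo, comp, k), _cl_residual(hi, comp, k)
    if f_lo > 0 or f_hi < 0:  # pragma: no cover - cannot happen for valid input
        raise RuntimeError("chloride mass-balance bracket failed")
    free_cl = brentq(_cl_residual, lo, hi, args=(comp, k),
                     rtol=max(_RTOL, 8.9e-16), xtol=1e-300, maxiter=200)
    free_ag = _free_ag(free_cl, comp.total_ag, k)
    saturated, q = saturation_check(free_ag, free_cl, k)

    solid = 0.0
    if saturated:
        free_cl, free_ag, solid = _solve_saturated(comp, k)
        q = free_ag * free_cl

    agcl = k.beta1 * free_ag * free_cl
    agcl2 = k.beta2 * free_ag * free_cl ** 2
    return SpeciationResult(
        fraction_free_ag=free_ag / comp.total_ag,
        fraction_agcl=agcl / comp.total_ag,
        fraction_agcl2=agcl2 / comp.total_ag,
        fraction_solid=solid / comp.total_ag,
        free_ag=free_ag, free_cl=free_cl, solid=solid,
        saturated=saturated, ion_product=q,
    )


def _solve_saturated(comp: SolutionComposition,
                     k: EquilibriumConstants) -> tuple[float, float, float]:
    """Equilibrium with AgCl(s) present: [Ag⁺] = Ksp/[Cl⁻] exactly.

    Eliminating the solid between the two mass balances gives a monotone
    scalar equation in free chloride; the solid amount follows from the
    silver balance and must come out non-negative.
    """

    def g(c: float) -> float:
        ag = k.ksp / c
        # (Ag_T - s) - (Cl_T - s) expressed through the free concentrations
        return ag * (1.0 - k.beta2 * c ** 2) - c - (comp.total_ag - comp.total_cl)

    hi = comp.total_cl
    lo = hi
    for _ in range(2000):
        lo *= 0.5
        if g(lo) > 0:
            break
    else:  # pragma: no cover
        raise RuntimeError("saturated-branch bracket failed (lower bound)")
    if g(hi) > 0:
        raise RuntimeError("saturated-branch bracket failed (upper bound)")
    free_cl = brentq(g, lo, hi, rtol=max(_RTOL, 8.9e-16), xtol=1e-300,
                     maxiter=200)
    free_ag = k.ksp / free_cl
    dissolved = free_ag * (1.0 + k.beta1 * free_cl + k.beta2 * free_cl ** 2)
    solid = comp.total_ag - dissolved
    if solid < -1e-12 * comp.total_ag:  # pragma: no cover
        raise RuntimeError("saturated branch produced negative solid")
    return free_cl, free_ag, max(solid, 0.0)
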