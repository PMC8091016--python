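"""Steady-state chemostat physiology: rates, yields, CO2 estimate, carbon balance.

At steady state in a chemostat the specific growth rate equals the dilution
rate D, so from one steady-state observation (feed and residual substrate,
biomass, product concentrations) the biomass-specific substrate consumption
rate and the yields follow directly:

    q_s       = -D * (S_in - S_res) / X      (g / g_biomass / h, negative =
                                              consumption)
    Y_biomass = X / (S_in - S_res)           (g / g_substrate)
    Y_p,i     = P_i / (S_in - S_res)         (g / g_substrate)

These satisfy the algebraic identity |q_s| * Y_biomass = D.

Because CO2 leaves in the off-gas and is not measured directly, its yield is
estimated stoichiometrically from the fermentation products: each mole of
ethanol and acetate is accompanied by one mole of CO2 at the pyruvate node,
while each mole of formate replaces one mole of CO2, so

    Y_CO2 = M_CO2 * (Y_ethanol/M_ethanol + Y_acetate/M_acetate
                     - Y_formate/M_formate)

Carbon recovery is the percentage of consumed substrate carbon found in the
measured products, optionally including biomass carbon (from total-organic-
carbon analysis of the pellet) and the stoichiometric CO2 estimate.

The module also converts spectrophotometric NAD(P)H rate assays into enzyme
specific activities (U per mg protein, 1 U = 1 umol substrate per min).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .io_formats import ChemostatRecord

__all__ = [
    "CompoundSpec",
    "COMPOUNDS",
    "PhysiologyResult",
    "ActivityResult",
    "steady_state_physiology",
    "co2_yield_estimate",
    "carbon_recovery",
    "enzyme_specific_activity",
    "yield_from_consumption_rate",
]

#: Molar extinction coefficient of NAD(P)H at 340 nm, AU L mmol^-1 cm^-1.
NADPH_EXTINCTION = 6.22

#: Atomic mass of carbon, g/mol.
CARBON_MASS = 12.011


@dataclass(frozen=True)
class CompoundSpec:
    """Molar mass (g/mol) and carbon atoms per molecule of a compound."""

    name: str
    molar_mass: float
    n_carbon: int

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError("molar mass must be > 0")
        if self.n_carbon < 0:
            raise ValueError("carbon count must be >= 0")

    @property
    def carbon_per_gram(self) -> float:
        """mol carbon per gram of compound."""
        return self.n_carbon / self.molar_mass


#: Built-in compound table.  Organic acids use free-acid molar masses,
#: consistent with HPLC quantification of acidified supernatant.
COMPOUNDS: dict[str, CompoundSpec] = {
    spec.name: spec
    for spec in [
        CompoundSpec("cellobiose", 342.30, 12),
        CompoundSpec("glucose", 180.16, 6),
        CompoundSpec("fructose", 180.16, 6),
        CompoundSpec("ethanol", 46.07, 2),
        CompoundSpec("acetate", 60.05, 2),
        CompoundSpec("formate", 46.03, 1),
        CompoundSpec("lactate", 90.08, 3),
        CompoundSpec("pyruvate", 88.06, 3),
        CompoundSpec("malate", 134.09, 4),
        CompoundSpec("co2", 44.01, 1),
    ]
}


def _compound(name: str) -> CompoundSpec:
    try:
        return COMPOUNDS[name]
    except KeyError:
        raise ValueError(
            f"unknown compound {name!r}; known compounds: {sorted(COMPOUNDS)}"
        ) from None


@dataclass
class PhysiologyResult:
    """Derived steady-state physiology of one chemostat record.

    ``q_substrate`` carries a negative sign for consumption; yields are in
    g per g substrate consumed; ``carbon_recovery`` is a percentage (NaN
    when it cannot be computed).
    """

    substrate: str
    D: float
    q_substrate: float
    Y_biomass: float
    Y_products: dict[str, float]
    Y_co2_est: float
    carbon_recovery: float = math.nan
    flags: list[str] = field(default_factory=list)


@dataclass
class ActivityResult:
    """Enzyme specific activity, U per mg protein (1 U = 1 umol/min)."""

    specific_activity: float
    rate_umol_per_min: float
    cofactor: str = ""

    @property
    def display(self) -> str:
        return f"{self.specific_activity:.2f}"


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def co2_yield_estimate(
    Y_ethanol: float, Y_acetate: float, Y_formate: float
) -> float:
    """Stoichiometric CO2 yield estimate (g/g) from product mass yields.

    The molar CO2 yield is ethanol + acetate - formate; the mass yields are
    converted through the molar masses and back through M_CO2.  A negative
    result (formate-dominated) is possible and flagged by callers.
    """
    if min(Y_ethanol, Y_acetate, Y_formate) < 0:
        raise ValueError("yields must be >= 0")
    mol = (
        Y_ethanol / COMPOUNDS["ethanol"].molar_mass
        + Y_acetate / COMPOUNDS["acetate"].molar_mass
        - Y_formate / COMPOUNDS["formate"].molar_mass
    )
    return COMPOUNDS["co2"].molar_mass * mol


def carbon_recovery(
    rec: ChemostatRecord,
    include_biomass: bool = True,
    include_co2_estimate: bool = True,
) -> float:
    """Percent of consumed substrate carbon recovered in products.

    All terms are mol carbon per litre.  Biomass carbon enters via the TOC
    measurement when present; the stoichiometric CO2 estimate is added only
    when no measured ``co2`` concentration is among the products (so the
    two never double-count).  Both contributions are toggleable.
    """
    consumed = rec.S_in - rec.S_res
    if consumed <= 0:
        raise ValueError("no substrate consumed; carbon recovery undefined")
    substrate = _compound(rec.substrate)
    consumed_c = consumed * substrate.carbon_per_gram
    product_c = 0.0
    for name, conc in rec.products.items():
        product_c += conc * _compound(name).carbon_per_gram
    if include_biomass and rec.biomass_TOC is not None:
        product_c += rec.biomass_TOC / CARBON_MASS
    if include_co2_estimate and "co2" not in rec.products:
        co2_conc = co2_yield_estimate(
            rec.products.get("ethanol", 0.0),
            rec.products.get("acetate", 0.0),
            rec.products.get("formate", 0.0),
        )
        product_c += max(co2_conc, 0.0) * COMPOUNDS["co2"].carbon_per_gram
    return 100.0 * product_c / consumed_c


def steady_state_physiology(
    rec: ChemostatRecord,
    include_biomass_carbon: bool = True,
    include_co2_in_recovery: bool = True,
) -> PhysiologyResult:
    """Rates, yields, CO2 estimate and carbon recovery for one record.

    Requires a substrate-limited steady state: X > 0 and S_in > S_res.
    The returned result satisfies |q_substrate| * Y_biomass == D exactly
    (to floating-point rounding).
    """
    consumed = rec.S_in - rec.S_res
    if rec.X <= 0 or consumed <= 0:
        raise ValueError("not substrate-limited / invalid state: need X > 0 and S_in > S_res")
    q_substrate = -rec.D * consumed / rec.X
    Y_biomass = rec.X / consumed
    Y_products = {name: conc / consumed for name, conc in rec.products.items()}
    Y_co2 = co2_yield_estimate(
        Y_products.get("ethanol", 0.0),
        Y_products.get("acetate", 0.0),
        Y_products.get("formate", 0.0),
    )
    flags = []
    if Y_co2 < 0:
        flags.append("negative_co2_estimate")
    try:
        recovery = carbon_recovery(
            rec,
            include_biomass=include_biomass_carbon,
            include_co2_estimate=include_co2_in_recovery,
        )
    except ValueError:
        recovery = math.nan
    return PhysiologyResult(
        substrate=rec.substrate,
        D=rec.D,
        q_substrate=q_substrate,
        Y_biomass=Y_biomass,
        Y_products=Y_products,
        Y_co2_est=Y_co2,
        carbon_recovery=recovery,
        flags=flags,
    )


def yield_from_consumption_rate(D: float, q_substrate: float) -> float:
    """Biomass yield implied by the steady-state identity Y = D / |q|."""
    if q_substrate == 0:
        raise ValueError("consumption rate must be non-zero")
    if D <= 0:
        raise ValueError("dilution rate must be > 0")
    return D / abs(q_substrate)


def enzyme_specific_activity(
    dA_per_min: float,
    reaction_volume_mL: float,
    protein_mg: float,
    path_cm: float = 1.0,
    stoich_factor: float = 1.0,
    cofactor: str = "",
) -> ActivityResult:
    """Convert a blank-corrected A340 slope into a specific activity.

    rate (umol/min) = dA_per_min * V_mL / (6.22 * path_cm * stoich_factor);
    specific activity = rate / protein_mg.  ``stoich_factor`` is the number
    of NAD(P)H turned over per reaction of interest in coupled assays.
    """
    if dA_per_min < 0:
        raise ValueError("dA_per_min must be >= 0 (blank-corrected)")
    if reaction_volume_mL <= 0 or path_cm <= 0 or stoich_factor <= 0:
        raise ValueError("volume, path length and stoichiometric factor must be > 0")
    if protein_mg <= 0:
        raise ValueError("protein_mg must be > 0")
    rate = dA_per_min * reaction_volume_mL / (NADPH_EXTINCTION * path_cm * stoich_factor)
    return ActivityResult(
        specific_activity=rate / protein_mg,
        rate_umol_per_min=rate,
        cofactor=cofactor,
    )
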