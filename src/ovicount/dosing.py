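"""Chemical-exposure arithmetic: serial dilution planning and intake dosing.

Test chemicals are prepared as 1000x stocks in 100% DMSO, diluted 1:100
with water to a 10x working solution in 1% DMSO, and 30 uL of that working
solution is added to each 300 uL well. By the bench convention of treating
"30 uL into a 300 uL well" as a 10-fold dilution, the final condition is
nominally 1x chemical in 0.1% DMSO; volumetrically the factor is 30/330,
so the exact final concentration is 10/11 of nominal. Both numbers are
reported, labelled, and never silently mixed.

Dietary intake assumes an adult fly consumes ~1.5 uL of food and water per
day, so a media concentration c (uM) of a compound with molecular weight
MW (g/mol) corresponds to c * MW * 1.5e-3 ng ingested per day.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "DilutionStep",
    "DilutionPlan",
    "IntakeEstimate",
    "plan_dilution",
    "intake_ng_per_day",
    "round_intake",
    "MOLECULAR_WEIGHTS",
]

# convenience values; user-supplied MW always wins
MOLECULAR_WEIGHTS = {
    "rapamycin": 914.17,  # g/mol
    "bendiocarb": 223.23,
}


@dataclass(frozen=True)
class DilutionStep:
    name: str
    diluent: str
    volume_transferred_uL: float
    total_volume_uL: float
    fold_concentration: float  # x-fold relative to the final nominal 1x
    dmso_percent: float
    convention: str = "nominal"  # or "exact"


@dataclass(frozen=True)
class DilutionPlan:
    steps: tuple[DilutionStep, ...]

    @property
    def final_nominal(self) -> DilutionStep:
        return [s for s in self.steps if s.convention == "nominal"][-1]

    @property
    def final_exact(self) -> DilutionStep:
        return [s for s in self.steps if s.convention == "exact"][-1]


@dataclass(frozen=True)
class IntakeEstimate:
    chemical: str
    mw_g_per_mol: float
    conc_uM: float
    consumption_uL_per_day: float
    ng_per_day: float


def plan_dilution(
    stock_fold: float = 1000.0,
    step1_ratio: float = 100.0,
    well_media_volume_uL: float = 300.0,
    added_volume_uL: float = 30.0,
) -> DilutionPlan:
    """Plan the stock -> working -> in-well serial dilution.

    Step 1 dilutes the DMSO stock ``step1_ratio``-fold with water
    (1000x/100% DMSO -> 10x/1% DMSO at the defaults). Step 2 adds
    ``added_volume_uL`` of working solution to a well already holding
    ``well_media_volume_uL`` of media; its nominal fold uses the bench
    convention well_volume/added_volume, and the exact volumetric value
    added/(added+well) is reported alongside, flagged "exact".
    """
    if min(stock_fold, step1_ratio, well_media_volume_uL, added_volume_uL) <= 0:
        raise ValueError("volumes and ratios must be positive")
    stock_dmso = 100.0
    working_fold = stock_fold / step1_ratio
    working_dmso = stock_dmso / step1_ratio
    nominal_factor = added_volume_uL / well_media_volume_uL  # bench convention
    exact_factor = added_volume_uL / (added_volume_uL + well_media_volume_uL)

    steps = (
        DilutionStep("stock", "DMSO", 0.0, 0.0, stock_fold, stock_dmso),
        DilutionStep(
            "working", "water", 1.0, step1_ratio, working_fold, working_dmso
        ),
        DilutionStep(
            "in-well", "media", added_volume_uL,
            well_media_volume_uL + added_volume_uL,
            working_fold * nominal_factor, working_dmso * nominal_factor,
            convention="nominal",
        ),
        DilutionStep(
            "in-well", "media", added_volume_uL,
            well_media_volume_uL + added_volume_uL,
            working_fold * exact_factor, working_dmso * exact_factor,
            convention="exact",
        ),
    )
    return DilutionPlan(steps)


def intake_ng_per_day(
    conc_uM: float,
    mw_g_per_mol: float,
    consumption_uL: float = 1.5,
    chemical: str = "",
) -> IntakeEstimate:
    """Daily dietary intake in ng from a media concentration.

    intake (ng/day) = conc (umol/L) * MW (g/mol) * consumption (uL/day) * 1e-3.
    Strictly linear and separately homogeneous in each factor.
    """
    if conc_uM <= 0 or mw_g_per_mol <= 0 or consumption_uL <= 0:
        raise ValueError("concentration, molecular weight and consumption must be positive")
    ng = conc_uM * mw_g_per_mol * consumption_uL * 1e-3
    return IntakeEstimate(chemical, mw_g_per_mol, conc_uM, consumption_uL, ng)


def round_intake(ng_per_day: float) -> float:
    """Display rounding: 2 decimals below 1 ng/day, 1 decimal at or above."""
    if ng_per_day < 1.0:
        return round(ng_per_day, 2)
    return round(ng_per_day, 1)
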