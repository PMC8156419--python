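"""Physiological arithmetic behind serine dose setting.

Closed-form unit conversions, arterio-venous organ flux balances, allometric
scaling, the bioavailability-volume algebra, endogenous-production and
hepatic-uptake estimates, and the dose plan.  These are deliberately small
exact functions: they let fitted PK ratios be confronted with independent
physiological measurements, and chain into a dose recommendation.

Sign convention for arterio-venous (AV) differences: arterial minus venous,
so a positive value is net uptake by the organ and a negative value net
release.  Functions report direction labels rather than relying on the sign
alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "PhysioConstants",
    "conc_mg_per_100ml_to_umol_per_L",
    "conc_umol_per_L_to_mg_per_100ml",
    "molar_dose_to_mass",
    "organ_flux",
    "muscle_perfusion",
    "allometric_volume",
    "dog_blood_volume",
    "bioavailability_from_volume",
    "volume_from_bioavailability",
    "endogenous_production",
    "daily_dose_to_mg_per_min",
    "tissue_shares",
    "total_hepatic_fraction",
    "dose_for_uptake_multiplier",
    "dose_rationale",
]


@dataclass(frozen=True)
class PhysioConstants:
    """Physiological constants with standard literature defaults.

    molar_mass : g/mol of L-serine.
    renal_perfusion, hepatic_perfusion : L/min.
    specific_muscle_flow : L/(kg·min) of muscle tissue.
    muscle_fraction : fraction of body mass that is muscle.
    reference_weight : kg.
    dog_blood_per_kg : ml blood per kg body weight in dogs.
    """

    molar_mass: float = 105.09
    renal_perfusion: float = 1.2
    hepatic_perfusion: float = 1.4
    specific_muscle_flow: float = 0.08
    muscle_fraction: float = 0.42
    reference_weight: float = 70.0
    dog_blood_per_kg: float = 79.0

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive")


_DEFAULT = PhysioConstants()


def conc_mg_per_100ml_to_umol_per_L(x: float, constants: PhysioConstants = _DEFAULT) -> float:
    """Convert a concentration from mg/100 ml to µmol/L."""
    if x < 0:
        raise ValueError("concentration must be non-negative")
    return x * 10.0 * 1000.0 / constants.molar_mass


def conc_umol_per_L_to_mg_per_100ml(x: float, constants: PhysioConstants = _DEFAULT) -> float:
    """Inverse of :func:`conc_mg_per_100ml_to_umol_per_L` (exact round trip)."""
    if x < 0:
        raise ValueError("concentration must be non-negative")
    return x * constants.molar_mass / 10_000.0


def molar_dose_to_mass(mmol_per_kg: float, weight: float, constants: PhysioConstants = _DEFAULT) -> float:
    """Oral dose in grams equivalent to a molar dose per body weight."""
    if mmol_per_kg < 0 or weight <= 0:
        raise ValueError("molar dose must be non-negative and weight positive")
    return mmol_per_kg * weight * constants.molar_mass / 1000.0


@dataclass(frozen=True)
class OrganFlux:
    """Net organ flux in three unit systems plus a direction label."""

    umol_per_min: float
    mg_per_min: float
    mg_per_h: float
    direction: str  # "uptake", "release" or "none"


def organ_flux(av_diff: float, perfusion: float, constants: PhysioConstants = _DEFAULT) -> OrganFlux:
    """Net organ flux from an AV concentration difference and a perfusion.

    ``av_diff`` is arterial minus venous in µmol/L (negative = net release);
    the magnitude of the sign is preserved in every unit.
    """
    if perfusion <= 0:
        raise ValueError("perfusion must be positive")
    umol_min = av_diff * perfusion
    mg_min = umol_min * constants.molar_mass / 1000.0
    direction = "uptake" if av_diff > 0 else ("release" if av_diff < 0 else "none")
    return OrganFlux(umol_min, mg_min, 60.0 * mg_min, direction)


def muscle_perfusion(weight: float, constants: PhysioConstants = _DEFAULT) -> float:
    """Total muscle blood flow (L/min) for a body weight, linear in weight."""
    if weight < 0:
        raise ValueError("weight must be non-negative")
    return constants.specific_muscle_flow * constants.muscle_fraction * weight


def allometric_volume(v_animal: float, w_animal: float, w_target: float) -> float:
    """Scale a volume of distribution proportionally to body weight."""
    if v_animal <= 0 or w_animal <= 0 or w_target <= 0:
        raise ValueError("volumes and weights must be positive")
    return v_animal * w_target / w_animal


def dog_blood_volume(weight: float, constants: PhysioConstants = _DEFAULT) -> float:
    """Blood volume (L) of a dog of the given weight."""
    if weight < 0:
        raise ValueError("weight must be non-negative")
    return constants.dog_blood_per_kg * weight / 1000.0


@dataclass(frozen=True)
class Bioavailability:
    value: float
    feasible: bool  # a fraction above 1 is physically impossible


def bioavailability_from_volume(f_over_v: float, v: float) -> Bioavailability:
    """F implied by a fitted F/V ratio and an assumed volume of distribution."""
    if f_over_v <= 0 or v <= 0:
        raise ValueError("inputs must be positive")
    f = f_over_v * v
    return Bioavailability(f, f <= 1.0)


def volume_from_bioavailability(f: float, f_over_v: float) -> float:
    """Volume of distribution implied by a bioavailability and a fitted F/V."""
    if f <= 0 or f_over_v <= 0:
        raise ValueError("inputs must be positive")
    return f / f_over_v


def endogenous_production(
    kgen_over_v: float, v: float, constants: PhysioConstants = _DEFAULT
) -> tuple[float, float]:
    """Endogenous production in mg/h from k_gen/V (µmol/L/h) and a volume.

    Returns (raw, rounded to 2 significant figures).
    """
    if kgen_over_v < 0 or v <= 0:
        raise ValueError("kgen_over_v must be non-negative and volume positive")
    raw = kgen_over_v * v * constants.molar_mass / 1000.0
    return raw, _round_sig(raw, 2)


def daily_dose_to_mg_per_min(grams_per_day: float) -> float:
    """Average a daily dose in grams over 24 h, in mg/min."""
    if grams_per_day < 0:
        raise ValueError("dose must be non-negative")
    return grams_per_day * 1000.0 / (24.0 * 60.0)


def _round_sig(x: float, sig: int) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


@dataclass(frozen=True)
class TissueShares:
    liver: float
    muscle: float


def tissue_shares(liver_flux: float, muscle_flux: float) -> TissueShares:
    """Normalized liver/muscle shares of arterial serine clearance."""
    if liver_flux < 0 or muscle_flux < 0:
        raise ValueError("fluxes must be non-negative")
    total = liver_flux + muscle_flux
    if total == 0:
        raise ValueError("at least one flux must be positive")
    return TissueShares(liver_flux / total, muscle_flux / total)


def total_hepatic_fraction(first_pass: float, systemic_liver_share: float) -> float:
    """Overall hepatic fraction of an oral dose.

    First-pass extraction plus the liver's share of what survives into
    systemic circulation: fp + share·(1 - fp).
    """
    for name, v in (("first_pass", first_pass), ("systemic_liver_share", systemic_liver_share)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1]")
    return first_pass + systemic_liver_share * (1.0 - first_pass)


@dataclass(frozen=True)
class DosePlan:
    """Oral dose required to multiply hepatic serine uptake."""

    daily_grams: float
    per_administration_grams: float
    regimen_splits: int
    exceeds_safety_bound: bool
    safety_bound_grams: float


def dose_for_uptake_multiplier(
    baseline_hepatic_uptake: float,
    hepatic_fraction: float,
    multiplier: float,
    regimen_splits: int = 1,
    safety_bound: float = 30.0,
) -> DosePlan:
    """Daily oral dose needed to multiply baseline hepatic uptake.

    ``baseline_hepatic_uptake`` is the liver's endogenous intake in g/day;
    only ``hepatic_fraction`` of an oral dose reaches the liver, so the dose
    to raise uptake to ``multiplier``× baseline is
    baseline·(multiplier - 1)/fraction.  Doses above ``safety_bound`` g/day
    are flagged, never blocked: the module reports, it does not prescribe.
    """
    if baseline_hepatic_uptake <= 0:
        raise ValueError("baseline uptake must be positive")
    if not (0.0 < hepatic_fraction <= 1.0):
        raise ValueError("hepatic fraction must lie in (0, 1]")
    if multiplier < 1.0:
        raise ValueError("multiplier must be at least 1")
    if regimen_splits < 1:
        raise ValueError("regimen_splits must be at least 1")
    daily = baseline_hepatic_uptake * (multiplier - 1.0) / hepatic_fraction
    return DosePlan(
        daily_grams=daily,
        per_administration_grams=daily / regimen_splits,
        regimen_splits=regimen_splits,
        exceeds_safety_bound=daily > safety_bound,
        safety_bound_grams=safety_bound,
    )


def dose_rationale(
    kgen_over_v: float = 29.6,
    volume: float = 140.0,
    liver_flux_mg_min: float = 3.0,
    muscle_flux_mg_min: float = 2.6,
    first_pass: float = 0.40,
    multiplier: float = 2.0,
    regimen_splits: int = 2,
    constants: PhysioConstants = _DEFAULT,
) -> dict[str, float | dict]:
    """The full dose-setting chain as one call.

    Fitted k_gen/V and an assumed volume give endogenous production (mg/h);
    liver/muscle flux estimates split systemic clearance into tissue shares;
    first-pass plus the liver's systemic share gives the overall hepatic
    fraction of an oral dose; the liver's share of endogenous production
    gives its baseline intake (g/day); and the dose plan states the oral
    dose that multiplies that intake.
    """
    prod_raw, prod_2sf = endogenous_production(kgen_over_v, volume, constants)
    shares = tissue_shares(liver_flux_mg_min, muscle_flux_mg_min)
    hepatic = total_hepatic_fraction(first_pass, shares.liver)
    baseline_uptake_g_day = prod_raw * 24.0 * shares.liver / 1000.0
    plan = dose_for_uptake_multiplier(baseline_uptake_g_day, hepatic, multiplier, regimen_splits)
    return {
        "endogenous_production_mg_h": prod_raw,
        "endogenous_production_mg_h_2sf": prod_2sf,
        "liver_share": shares.liver,
        "muscle_share": shares.muscle,
        "total_hepatic_fraction": hepatic,
        "baseline_liver_uptake_g_day": baseline_uptake_g_day,
        "dose_plan": {
            "daily_grams": plan.daily_grams,
            "per_administration_grams": plan.per_administration_grams,
            "regimen_splits": plan.regimen_splits,
            "exceeds_safety_bound": plan.exceeds_safety_bound,
        },
    }
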