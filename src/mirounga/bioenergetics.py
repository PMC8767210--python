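"""Mass and energy accounting for foraging trips.

Arrival and departure masses are measured on shore, some days after the
seal actually hauls out, so the at-sea gain has to be corrected for
onshore fasting losses before foraging success can be scored:

* females lose mass at ``0.51 + 0.0076 x mass`` kg per day (an empirical
  fasting regression), applied day by day on the declining mass;
* males are corrected through a metabolic model — daily energy use is a
  multiple of the Kleiber basal prediction (2x while moulting, 3.1x while
  breeding), converted to mass through the fasting fuel mix.

Mass gain is partitioned into adipose and lean tissue and converted to
energy with fixed tissue compositions (adipose 90% lipid, lean 27%
protein) and gross energy densities (37.3 kJ/g lipid, 23.5 kJ/g protein).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class EnergyConstants:
    lipid_energy_kj_g: float = 37.3
    protein_energy_kj_g: float = 23.5
    adipose_lipid_fraction: float = 0.90
    lean_protein_fraction: float = 0.27


@dataclass(frozen=True)
class FemaleOnshoreModel:
    """Daily onshore mass loss: ``0.51 + 0.0076 x mass`` kg/d."""

    intercept_kg_d: float = 0.51
    slope_per_d: float = 0.0076


@dataclass(frozen=True)
class MaleOnshoreModel:
    """Onshore metabolic model: multiplier x Kleiber basal rate.

    ``basal_kj_d_kg075`` is the Kleiber coefficient (kJ per day per
    kg^0.75); fasting males fuel ~93% of metabolism from lipid and ~7%
    from protein.
    """

    basal_kj_d_kg075: float = 293.1
    exponent: float = 0.75
    multiplier: dict = None
    lipid_energy_fraction: float = 0.93

    def __post_init__(self):
        if self.multiplier is None:
            object.__setattr__(self, "multiplier", {"moult": 2.0, "breeding": 3.1})


@dataclass
class EnergyBudget:
    """The eight foraging-success metrics for one deployment."""

    departure_mass_kg: float
    mass_gain_kg: float
    mass_gain_rate_kg_d: float
    mass_gain_rate_feeding_kg_d: float
    proportion_mass_gain: float
    energy_gain_mj: float
    energy_gain_rate_mj_d: float
    energy_gain_rate_feeding_mj_d: float


def female_onshore_mass_change(
    mass_kg: float,
    days_ashore: float,
    model: FemaleOnshoreModel | None = None,
    pup_mass_kg: float = 0.0,
) -> float:
    """Total mass (kg) a female loses fasting ashore for ``days_ashore``.

    The daily rate ``0.51 + 0.0076 x mass`` is evaluated day by day on the
    declining mass, starting from ``mass_kg`` (a fractional final day is
    prorated).  Any pup mass (post-moult arrivals are weighed after
    parturition) is added back first, since the regression describes the
    intact female.
    """
    if days_ashore < 0:
        raise ValueError("days ashore must be non-negative")
    if mass_kg <= 0:
        raise ValueError("mass must be positive")
    model = model or FemaleOnshoreModel()
    mass = float(mass_kg) + float(pup_mass_kg)
    remaining = float(days_ashore)
    total = 0.0
    while remaining > 1e-12:
        step = min(1.0, remaining)
        loss = step * (model.intercept_kg_d + model.slope_per_d * mass)
        total += loss
        mass -= loss
        remaining -= step
    return total


def apply_female_onshore_loss(
    mass_at_haulout_kg: float, days_ashore: float, model: FemaleOnshoreModel | None = None
) -> float:
    """Generator side: censused mass after fasting ashore.

    Solves ``census + change(census, days) = haulout`` by fixed point, so
    that correcting the censused mass recovers the haul-out mass exactly.
    """
    model = model or FemaleOnshoreModel()
    mass = float(mass_at_haulout_kg)
    census = mass
    for _ in range(60):
        new = mass - female_onshore_mass_change(census, days_ashore, model)
        if abs(new - census) < 1e-10:
            break
        census = new
    return census


def _male_daily_loss_kg(mass_kg: float, phase: str, model: MaleOnshoreModel,
                        constants: EnergyConstants) -> float:
    if phase not in model.multiplier:
        raise ValueError(f"unknown phase {phase!r}; expected one of {sorted(model.multiplier)}")
    energy_kj = model.multiplier[phase] * model.basal_kj_d_kg075 * mass_kg ** model.exponent
    lipid_g = energy_kj * model.lipid_energy_fraction / constants.lipid_energy_kj_g
    protein_g = energy_kj * (1.0 - model.lipid_energy_fraction) / constants.protein_energy_kj_g
    return (lipid_g + protein_g) / 1000.0


def male_onshore_mass_change(
    mass_kg: float,
    phase: str,
    days_ashore: float,
    model: MaleOnshoreModel | None = None,
    constants: EnergyConstants | None = None,
) -> float:
    """Total mass (kg) a male loses fasting ashore for ``days_ashore``.

    Daily energy expenditure is ``multiplier x 293.1 x mass^0.75`` kJ
    (2x basal during the moult, 3.1x during breeding), converted to tissue
    mass via the fasting fuel mix and iterated day by day on the declining
    mass.
    """
    if mass_kg <= 0:
        raise ValueError("mass must be positive")
    if days_ashore < 0:
        raise ValueError("days ashore must be non-negative")
    model = model or MaleOnshoreModel()
    constants = constants or EnergyConstants()
    mass = float(mass_kg)
    remaining = float(days_ashore)
    total = 0.0
    while remaining > 1e-12:
        step = min(1.0, remaining)
        loss = step * _male_daily_loss_kg(mass, phase, model, constants)
        total += loss
        mass -= loss
        remaining -= step
    return total


def apply_male_onshore_loss(
    mass_at_haulout_kg: float,
    phase: str,
    days_ashore: float,
    model: MaleOnshoreModel | None = None,
    constants: EnergyConstants | None = None,
) -> float:
    """Generator side: censused male mass after fasting ashore (exact inverse)."""
    model = model or MaleOnshoreModel()
    constants = constants or EnergyConstants()
    mass = float(mass_at_haulout_kg)
    census = mass
    for _ in range(60):
        new = mass - male_onshore_mass_change(census, phase, days_ashore, model, constants)
        if abs(new - census) < 1e-10:
            break
        census = new
    return census


def energy_gain(adipose_gain_kg: float, lean_gain_kg: float,
                constants: EnergyConstants | None = None) -> float:
    """Energy (MJ) in a tissue gain; negative gains give negative energy."""
    c = constants or EnergyConstants()
    kj = (
        c.adipose_lipid_fraction * adipose_gain_kg * 1000.0 * c.lipid_energy_kj_g
        + c.lean_protein_fraction * lean_gain_kg * 1000.0 * c.protein_energy_kj_g
    )
    return kj / 1000.0


def foraging_success(
    departure_mass_kg: float,
    corrected_gain_kg: float,
    trip_days: float,
    feeding_days: float,
    adipose_fraction: float,
    constants: EnergyConstants | None = None,
) -> EnergyBudget:
    """Assemble the eight foraging-success metrics for one trip.

    ``feeding_days`` is the proportion of time feeding times the trip
    length; relative rates divide by it.  ``adipose_fraction`` partitions
    the corrected mass gain into adipose vs lean tissue.
    """
    if feeding_days > trip_days:
        raise ValueError("feeding days cannot exceed trip days")
    adipose = corrected_gain_kg * adipose_fraction
    lean = corrected_gain_kg - adipose
    e = energy_gain(adipose, lean, constants)
    if feeding_days > 0:
        rel_mass = corrected_gain_kg / feeding_days
        rel_energy = e / feeding_days
    else:
        rel_mass = float("nan")
        rel_energy = float("nan")
    return EnergyBudget(
        departure_mass_kg=departure_mass_kg,
        mass_gain_kg=corrected_gain_kg,
        mass_gain_rate_kg_d=corrected_gain_kg / trip_days,
        mass_gain_rate_feeding_kg_d=rel_mass,
        proportion_mass_gain=corrected_gain_kg / departure_mass_kg,
        energy_gain_mj=e,
        energy_gain_rate_mj_d=e / trip_days,
        energy_gain_rate_feeding_mj_d=rel_energy,
    )


def corrected_trip_gain(
    departure_mass_kg: float,
    arrival_mass_measured_kg: float,
    sex: str,
    trip: str,
    days_ashore: float,
    pup_mass_kg: float = 0.0,
) -> float:
    """At-sea mass gain corrected for onshore fasting before the census."""
    if sex == "female":
        loss = female_onshore_mass_change(
            arrival_mass_measured_kg, days_ashore, pup_mass_kg=pup_mass_kg
        )
        arrival = arrival_mass_measured_kg + pup_mass_kg + loss
    else:
        phase = "breeding" if trip == "post_moult" else "moult"
        loss = male_onshore_mass_change(arrival_mass_measured_kg, phase, days_ashore)
        arrival = arrival_mass_measured_kg + loss
    return arrival - departure_mass_kg
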