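"""Bioenergetics-based food-web bioaccumulation.

Three invertebrate compartments feed the fish: benthic invertebrates
equilibrate with the organic-carbon-normalized active-bed concentration,
water-column invertebrates with the dissolved water concentration, and
terrestrial invertebrates are by definition uncontaminated.  Fish (creek
chub, longear sunfish) are simulated as age-class cohorts with a whole-body
tissue balance

    dnu/dt = k_u * f_d * C_w  +  alpha_d * I * sum_i p_i(month) * C_prey_i
             - (k_e + G) * nu

housing gill uptake, dietary uptake, gill elimination and growth dilution.
Ingestion closes the energy budget, I = (R + G) / AE, with respiration
R = alpha_R * w^(-gamma) * exp(theta * T).  Diet fractions and lipid vary
monthly; fish are stationary at a station (home ranges are short relative to
reach lengths).  Concentrations are whole-body wet weight (mg/kg).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SpeciesParams",
    "InvertebrateParams",
    "FishState",
    "invertebrate_concentrations",
    "bioenergetics_rates",
    "simulate_fish",
]

DAYS_PER_YEAR = 365


@dataclass(frozen=True)
class InvertebrateParams:
    """Invertebrate bioaccumulation factors.

    beta_soc:
        Benthic accumulation factor, (mg/kg lipid) per (mg/kg OC) in the bed.
    baf_w:
        Water-column bioaccumulation factor (L/kg lipid) on the dissolved phase.
    """

    beta_soc: float = 1.0
    baf_w: float = 2.0e5
    lipid_benthic: float = 0.02
    lipid_water_column: float = 0.02

    def __post_init__(self):
        if self.beta_soc < 0 or self.baf_w < 0:
            raise ValueError("accumulation factors must be >= 0")


def _monthly(values, lo, hi, peak_month):
    if values is not None:
        return tuple(values)
    m = np.arange(12)
    return tuple(lo + (hi - lo) * 0.5 * (1 + np.cos(2 * np.pi * (m - peak_month) / 12)))


@dataclass(frozen=True)
class SpeciesParams:
    """Bioenergetics and toxicokinetic parameters for one fish species.

    weight_at_age is (coefficient, exponent) of w = c * age_yr^p in grams.
    diet_by_month holds 12 (benthic, water_column, terrestrial) fraction
    triples summing to 1; lipid_by_month holds 12 whole-body lipid fractions.
    Rates: gill uptake k_u (L/kg/d), elimination k_e (1/d), dietary chemical
    assimilation alpha_d, respiration (alpha_R, gamma, theta) giving
    R = alpha_R * w^-gamma * exp(theta*T) (1/d), food assimilation AE.
    """

    name: str
    weight_at_age: tuple = (12.0, 1.1)
    age_classes: tuple = (1, 2, 3)
    lipid_by_month: tuple = None
    diet_by_month: tuple = None
    k_u: float = 500.0
    k_e: float = 0.01
    alpha_d: float = 0.8
    respiration: tuple = (0.02, 0.25, 0.06)
    assimilation: float = 0.8
    lipid_modulates_loss: bool = True

    def __post_init__(self):
        if self.lipid_by_month is None:
            object.__setattr__(self, "lipid_by_month",
                               _monthly(None, 0.015, 0.035, peak_month=9))
        if self.diet_by_month is None:
            summer = (0.45, 0.30, 0.25)
            winter = (0.60, 0.30, 0.10)
            diet = tuple(summer if 3 <= m <= 9 else winter for m in range(12))
            object.__setattr__(self, "diet_by_month", diet)
        for m, d in enumerate(self.diet_by_month):
            if abs(sum(d) - 1.0) > 1e-9:
                raise ValueError(f"diet fractions for month {m} must sum to 1")
        for lip in self.lipid_by_month:
            if not 0 < lip < 1:
                raise ValueError("lipid fractions must be in (0, 1)")
        for r in (self.k_u, self.k_e, self.alpha_d, self.assimilation):
            if r < 0:
                raise ValueError("rates must be >= 0")


@dataclass
class FishState:
    """Whole-body PCB trajectories (mg/kg wet) per age class plus station mean."""

    days: np.ndarray
    conc_by_age: dict          # age class -> array over days
    weight_by_age: dict        # age class -> array (g)
    station_mean: np.ndarray   # unweighted mean over sampled age classes


def invertebrate_concentrations(c_bed, foc, dissolved_ngL, params: InvertebrateParams):
    """Invertebrate compartment concentrations (mg/kg wet).

    benthic  = beta_soc * (C_bed / foc) * lipid
    water    = BAF_w * C_dissolved * lipid        (ng/L * L/kg lipid -> mg/kg)
    terrestrial = 0 by definition.
    """
    c_bed = np.asarray(c_bed, dtype=float)
    dis = np.asarray(dissolved_ngL, dtype=float)
    foc_a = np.asarray(foc, dtype=float)
    if np.any((foc_a <= 0) & (c_bed > 0)):
        raise ValueError("bed foc must be positive where bed PCBs are present")
    benthic = params.beta_soc * np.where(foc_a > 0, c_bed / np.maximum(foc_a, 1e-12), 0.0) \
        * params.lipid_benthic
    water = params.baf_w * dis * 1e-6 * params.lipid_water_column
    terrestrial = np.zeros_like(benthic)
    return {"benthic": benthic, "water_column": water, "terrestrial": terrestrial}


def bioenergetics_rates(weight_g, temp_C, params: SpeciesParams):
    """Specific growth G (1/d) and ingestion I (g food / g fish / d).

    G comes from the age-weight power curve evaluated at the current weight;
    I closes the energy budget, I = (R + G) / AE.
    """
    if weight_g <= 0:
        raise ValueError("weight must be positive")
    if params.assimilation == 0:
        raise ValueError("food assimilation efficiency must be nonzero")
    c, p = params.weight_at_age
    if p == 0:
        growth = 0.0
    else:
        age_yr = (weight_g / c) ** (1.0 / p)
        growth = p / (age_yr * DAYS_PER_YEAR)
    alpha_r, gamma, theta = params.respiration
    resp = alpha_r * weight_g ** (-gamma) * np.exp(theta * temp_C)
    ingest = (resp + growth) / params.assimilation
    return growth, ingest


def simulate_fish(
    exposure: dict,
    species: SpeciesParams,
    inv_params: InvertebrateParams,
    temperature=None,
    start_month: int = 0,
    nu0: float = 0.0,
    growth_override: float | None = None,
):
    """Simulate fish age-class cohorts at a station.

    Parameters
    ----------
    exposure:
        Dict with daily arrays ``dissolved_ngL`` (f_d * C_w), ``c_bed``
        (mg/kg), and scalar or array ``foc``.
    temperature:
        Daily water temperature (degC); default is a sinusoidal annual cycle
        5-25 degC peaking in July.
    start_month:
        Calendar month (0-based) of day 0, used for diet/lipid switching.

    Cohorts age continuously; on each birthday (day 0 of the model year) the
    age-class states shift down the ladder (class k inherits class k-1) and
    the youngest class restarts at ``nu0``.  The station mean is the
    unweighted mean over ``species.age_classes``.
    """
    dis = np.asarray(exposure["dissolved_ngL"], dtype=float)
    c_bed = np.asarray(exposure["c_bed"], dtype=float)
    foc = exposure.get("foc", 0.04)
    nd = len(dis)
    if temperature is None:
        doy = (np.arange(nd) + start_month * 30.4) % DAYS_PER_YEAR
        temperature = 15.0 + 10.0 * np.cos(2 * np.pi * (doy - 196) / DAYS_PER_YEAR)
    temperature = np.asarray(temperature, dtype=float)

    classes = list(species.age_classes)
    max_class = max(classes)
    c_w, p_w = species.weight_at_age
    mean_lipid = float(np.mean(species.lipid_by_month))

    # state: age (yr) and concentration for cohorts 0..max_class
    ages = np.array([float(k) for k in range(max_class + 1)])
    nu = np.full(max_class + 1, float(nu0))
    out = {k: np.zeros(nd) for k in classes}
    wts = {k: np.zeros(nd) for k in classes}

    prey = invertebrate_concentrations(c_bed, foc, dis, inv_params)
    month_of_day = ((np.arange(nd) / 30.4375).astype(int) + start_month) % 12

    for d in range(nd):
        month = month_of_day[d]
        p_b, p_wc, p_t = species.diet_by_month[month]
        lipid = species.lipid_by_month[month]
        diet_conc = p_b * prey["benthic"][d] + p_wc * prey["water_column"][d] \
            + p_t * prey["terrestrial"][d]
        k_e = species.k_e * (mean_lipid / lipid if species.lipid_modulates_loss else 1.0)
        for i in range(len(nu)):
            age = max(ages[i], 0.05)
            w = c_w * age ** p_w
            growth, ingest = bioenergetics_rates(w, temperature[d], species)
            if growth_override is not None:
                growth = growth_override
                ingest = (species.respiration[0] * w ** (-species.respiration[1])
                          * np.exp(species.respiration[2] * temperature[d])
                          + growth) / species.assimilation
            uptake = species.k_u * dis[d] * 1e-6 \
                + species.alpha_d * ingest * diet_conc
            k_tot = k_e + growth
            if k_tot > 0:
                phi = np.exp(-k_tot)
                nu[i] = nu[i] * phi + uptake / k_tot * (1 - phi)
            else:
                nu[i] = nu[i] + uptake
        ages += 1.0 / DAYS_PER_YEAR
        for k in classes:
            out[k][d] = nu[k]
            wts[k][d] = c_w * max(ages[k], 0.05) ** p_w
        if (d + 1) % DAYS_PER_YEAR == 0:
            nu[1:] = nu[:-1]
            nu[0] = nu0
            ages = np.array([float(k) for k in range(max_class + 1)])

    mean = np.mean([out[k] for k in classes], axis=0)
    return FishState(days=np.arange(nd), conc_by_age=out, weight_by_age=wts,
                     station_mean=mean)
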