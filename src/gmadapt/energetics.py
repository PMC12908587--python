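"""Energy-expenditure computation.

Resting metabolic rate from whole-room calorimetry gas-exchange traces
(Weir equation over the final 20 minutes), total daily energy expenditure
from doubly-labeled-water records (two-point isotope elimination), FFM
normalisation, and the metabolic-adaptation statistic (measured minus
body-composition-predicted change in energy expenditure).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

WEIR_VO2_COEF = 3.9  # kcal per litre O2
WEIR_VCO2_COEF = 1.1  # kcal per litre CO2

TBW_FFM_FRACTION = 0.73  # total body water as a fraction of fat-free mass

TRACE_MINUTES = 60
RMR_WINDOW_START = 40  # final-20-minute averaging window


@dataclass(frozen=True)
class DLWConstants:
    """Constants of the doubly-labeled-water calculation chain.

    The two-point CO2-production equation is the Schoeller-form variant
    rCO2 [mol/day] = co2_coef * TBW_mol * (ko_weight*k_O - kd_weight*k_D),
    with isotopic-exchange corrections applied to the dilution spaces and
    VSMOW reference ratios for the delta-notation conversion.  Every
    constant is overridable.
    """

    rq: float = 0.86
    exchange_2h: float = 1.041
    exchange_18o: float = 1.007
    r_std_2h: float = 155.76e-6  # VSMOW 2H/1H
    r_std_18o: float = 2005.20e-6  # VSMOW 18O/16O
    molar_mass_water: float = 18.02  # g/mol
    co2_litres_per_mol: float = 22.4  # STP
    co2_coef: float = 0.4554
    ko_weight: float = 1.01
    kd_weight: float = 1.04


DEFAULT_DLW = DLWConstants()


@dataclass
class DLWRecord:
    """One subject-timepoint doubly-labeled-water measurement.

    Enrichments are delta-per-mil values against the reference standard;
    plateau samples are the 4 h and 5 h post-dose urine voids and the final
    samples the day-10 second and third voids.
    """

    dose_18o_g: float
    dose_2h_g: float
    ape_18o: float  # atom percent excess of the 18O dose water
    ape_2h: float
    baseline_18o: float
    plateau4_18o: float
    plateau5_18o: float
    final2_18o: float
    final3_18o: float
    baseline_2h: float
    plateau4_2h: float
    plateau5_2h: float
    final2_2h: float
    final3_2h: float
    elapsed_days: float
    body_mass_kg: float

    def validate(self) -> None:
        if self.dose_18o_g <= 0 or self.dose_2h_g <= 0:
            raise ValueError("isotope doses must be positive")
        if self.elapsed_days <= 0:
            raise ValueError("elapsed_days must be positive")


@dataclass
class EnergyOutcome:
    """Derived DLW kinetics and energy expenditure for one record."""

    k_d: float
    k_o: float
    n_d: float
    n_o: float
    tbw_kg: float
    rco2_l_day: float
    tdee: float
    rq: float
    flags: list[str] = field(default_factory=list)


def tbw_from_ffm(ffm_kg: float) -> float:
    """Estimate total body water (kg) from fat-free mass (73% rule)."""
    if ffm_kg <= 0:
        raise ValueError("fat-free mass must be positive")
    return TBW_FFM_FRACTION * ffm_kg


# ---------------------------------------------------------------------------
# Calorimetry


def weir_energy(vo2_l: float, vco2_l: float) -> float:
    """Energy (kcal) from gas volumes via the Weir equation."""
    vo2_l = np.asarray(vo2_l, dtype=float)
    vco2_l = np.asarray(vco2_l, dtype=float)
    if np.any(vo2_l < 0) or np.any(vco2_l < 0):
        raise ValueError("gas volumes must be non-negative")
    out = WEIR_VO2_COEF * vo2_l + WEIR_VCO2_COEF * vco2_l
    return float(out) if out.ndim == 0 else out


def rmr_from_trace(trace: pd.DataFrame) -> float:
    """RMR (kcal/day) from a 60-minute gas-exchange trace.

    Mean per-minute Weir energy over minutes 40-59 scaled to a day; the
    settling period (minutes 0-39) is ignored.
    """
    required = {"minute", "vo2_L", "vco2_L"}
    if not required.issubset(trace.columns):
        raise ValueError(f"trace must have columns {sorted(required)}")
    if len(trace) < TRACE_MINUTES:
        raise ValueError(
            f"trace must cover {TRACE_MINUTES} one-minute readings, got {len(trace)}"
        )
    trace = trace.sort_values("minute")
    minutes = trace["minute"].to_numpy()
    if np.any(np.diff(minutes) <= 0):
        raise ValueError("minute index must be strictly increasing")
    win = trace[trace["minute"] >= RMR_WINDOW_START]
    ee_per_min = weir_energy(win["vo2_L"].to_numpy(), win["vco2_L"].to_numpy())
    return float(np.mean(ee_per_min) * 1440.0)


# ---------------------------------------------------------------------------
# DLW chain


def delta_to_mole_fraction(delta_permil, r_std: float):
    """Convert delta-per-mil enrichment to heavy-isotope mole fraction."""
    r = r_std * (1.0 + np.asarray(delta_permil, dtype=float) / 1000.0)
    return r / (1.0 + r)


def mole_fraction_to_delta(x, r_std: float):
    x = np.asarray(x, dtype=float)
    r = x / (1.0 - x)
    return (r / r_std - 1.0) * 1000.0


def dilution_space(
    dose_g: float,
    ape_percent: float,
    molar_mass: float,
    enrichment_rise: float,
) -> float:
    """Isotope dilution space (mol water) from dose and plateau rise.

    ``enrichment_rise`` is the plateau-minus-baseline heavy-isotope mole
    fraction; the dose contributes dose_g/molar_mass * ape/100 mol of
    excess heavy isotope.
    """
    if enrichment_rise <= 0:
        raise ValueError(
            "plateau enrichment does not exceed baseline (rise <= 0); "
            "dose not detected or sample swap"
        )
    if dose_g <= 0 or molar_mass <= 0 or not (0 < ape_percent <= 100):
        raise ValueError("invalid dose parameters")
    excess_mol = dose_g / molar_mass * ape_percent / 100.0
    return excess_mol / enrichment_rise


def total_body_water(
    n_d: float, n_o: float, constants: DLWConstants = DEFAULT_DLW
) -> float:
    """TBW (kg) as the mean of the exchange-corrected dilution spaces."""
    if n_d <= 0 or n_o <= 0:
        raise ValueError("dilution spaces must be positive")
    ratio = n_d / n_o
    if not (1.0 <= ratio <= 1.1):
        warnings.warn(
            f"implausible dilution-space ratio N_D/N_O = {ratio:.4f} "
            "(expected within [1.0, 1.1])",
            stacklevel=2,
        )
    tbw_mol = (n_d / constants.exchange_2h + n_o / constants.exchange_18o) / 2.0
    return tbw_mol * constants.molar_mass_water / 1000.0


def elimination_rate(excess_start: float, excess_end: float, dt_days: float) -> float:
    """Isotope elimination rate (1/day) from two excess enrichments."""
    if excess_start <= 0 or excess_end <= 0:
        raise ValueError("excess enrichments must be positive")
    if dt_days <= 0:
        raise ValueError("dt must be positive")
    if excess_end >= excess_start:
        raise ValueError("no elimination: end enrichment >= start enrichment")
    return math.log(excess_start / excess_end) / dt_days


def rco2_two_point(
    tbw_mol: float, k_o: float, k_d: float, constants: DLWConstants = DEFAULT_DLW
) -> float:
    """CO2 production (L/day) from the two-point elimination rates."""
    if k_d <= 0 or k_o <= 0:
        raise ValueError("elimination rates must be positive")
    rate = constants.ko_weight * k_o - constants.kd_weight * k_d
    if rate <= 0:
        raise ValueError(
            "k_O <= (kd_weight/ko_weight)*k_D implies non-positive CO2 production"
        )
    rco2_mol = constants.co2_coef * tbw_mol * rate
    return rco2_mol * constants.co2_litres_per_mol


def tdee_from_rco2(rco2_l_day: float, rq: float = DEFAULT_DLW.rq) -> float:
    """TDEE (kcal/day) from CO2 production at a fixed respiratory quotient."""
    if not (0.7 <= rq <= 1.0):
        raise ValueError("respiratory quotient outside physiological range [0.7, 1.0]")
    if rco2_l_day < 0:
        raise ValueError("rCO2 must be non-negative")
    return weir_energy(rco2_l_day / rq, rco2_l_day)


def adaptive_ee(ee_kcal_day: float, ffm_kg: float) -> float:
    """Energy expenditure normalised per kg fat-free mass."""
    if ffm_kg <= 0:
        raise ValueError("fat-free mass must be positive")
    return ee_kcal_day / ffm_kg


def process_dlw_record(
    record: DLWRecord, constants: DLWConstants = DEFAULT_DLW
) -> EnergyOutcome:
    """Run the full DLW chain: dilution spaces -> TBW -> k's -> rCO2 -> TDEE."""
    record.validate()
    flags: list[str] = []

    def _excess(base, p4, p5, f2, f3, r_std):
        xb = delta_to_mole_fraction(base, r_std)
        plateau = float(
            np.mean(delta_to_mole_fraction([p4, p5], r_std)) - xb
        )
        final = float(np.mean(delta_to_mole_fraction([f2, f3], r_std)) - xb)
        return plateau, final

    plat_o, fin_o = _excess(
        record.baseline_18o, record.plateau4_18o, record.plateau5_18o,
        record.final2_18o, record.final3_18o, constants.r_std_18o,
    )
    plat_d, fin_d = _excess(
        record.baseline_2h, record.plateau4_2h, record.plateau5_2h,
        record.final2_2h, record.final3_2h, constants.r_std_2h,
    )
    n_o = dilution_space(
        record.dose_18o_g, record.ape_18o, constants.molar_mass_water, plat_o
    )
    n_d = dilution_space(
        record.dose_2h_g, record.ape_2h, constants.molar_mass_water, plat_d
    )
    tbw_kg = total_body_water(n_d, n_o, constants)
    if tbw_kg >= record.body_mass_kg:
        flags.append("tbw_exceeds_body_mass")
    k_o = elimination_rate(plat_o, fin_o, record.elapsed_days)
    k_d = elimination_rate(plat_d, fin_d, record.elapsed_days)
    if k_o <= k_d:
        flags.append("degenerate_kinetics")
    tbw_mol = tbw_kg * 1000.0 / constants.molar_mass_water
    rco2 = rco2_two_point(tbw_mol, k_o, k_d, constants)
    tdee = tdee_from_rco2(rco2, constants.rq)
    return EnergyOutcome(
        k_d=k_d, k_o=k_o, n_d=n_d, n_o=n_o, tbw_kg=tbw_kg,
        rco2_l_day=rco2, tdee=tdee, rq=constants.rq, flags=flags,
    )


# ---------------------------------------------------------------------------
# Metabolic adaptation


def metabolic_adaptation(
    cohort: pd.DataFrame,
    which: Literal["rmr", "tdee"],
    model: Literal["baseline", "delta"] = "baseline",
    cond_threshold: float = 1e8,
) -> tuple[pd.Series, np.ndarray]:
    """Per-subject metabolic adaptation (kcal/day) and fitted coefficients.

    ``baseline`` model: OLS of pre energy expenditure on pre (FFM, FM) with
    intercept across the cohort; predicted post EE applies the fitted
    coefficients to post body composition; adaptation = measured change
    minus predicted change.  ``delta`` model: OLS of the EE change on the
    (FFM, FM) changes; adaptation is the residual of that fit.
    """
    if which not in ("rmr", "tdee"):
        raise ValueError("which must be 'rmr' or 'tdee'")
    cols = [f"{which}_pre", f"{which}_post", "ffm_pre", "ffm_post", "fm_pre", "fm_post"]
    missing = [c for c in cols if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort missing columns: {missing}")
    sub = cohort.dropna(subset=cols)
    if len(sub) < 5:
        raise ValueError("need >= 5 subjects with complete data for the regression")

    ee_pre = sub[f"{which}_pre"].to_numpy(dtype=float)
    ee_post = sub[f"{which}_post"].to_numpy(dtype=float)

    if model == "baseline":
        x_pre = np.column_stack(
            [np.ones(len(sub)), sub["ffm_pre"].to_numpy(), sub["fm_pre"].to_numpy()]
        )
        x_post = np.column_stack(
            [np.ones(len(sub)), sub["ffm_post"].to_numpy(), sub["fm_post"].to_numpy()]
        )
        if np.linalg.cond(x_pre) > cond_threshold:
            raise ValueError(
                "FFM and FM are collinear in this cohort; refit with an "
                "FFM-only model"
            )
        beta, *_ = np.linalg.lstsq(x_pre, ee_pre, rcond=None)
        predicted_delta = (x_post - x_pre) @ beta
        adaptation = (ee_post - ee_pre) - predicted_delta
    elif model == "delta":
        d_ffm = (sub["ffm_post"] - sub["ffm_pre"]).to_numpy()
        d_fm = (sub["fm_post"] - sub["fm_pre"]).to_numpy()
        x = np.column_stack([np.ones(len(sub)), d_ffm, d_fm])
        if np.linalg.cond(x) > cond_threshold:
            raise ValueError(
                "FFM and FM changes are collinear; refit with an FFM-only model"
            )
        beta, *_ = np.linalg.lstsq(x, ee_post - ee_pre, rcond=None)
        adaptation = (ee_post - ee_pre) - x @ beta
    else:
        raise ValueError("model must be 'baseline' or 'delta'")
    return pd.Series(adaptation, index=sub.index, name=f"adaptation_{which}"), beta
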