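"""Human-capital costing of the duration differences.

Wage payments are standardized to hourly rates with the Danish norm of
7.4 working hours per day (37-hour week), truncated to [EUR 6.72,
EUR 268.63] per hour (DKK 50-2000 at 7.44 DKK/EUR), regression-imputed
where missing, and indexed to the 2022 price level with a sex- and
age-specific consumer price index.  A duration difference of
``Delta_k`` days over the two-year window then costs

    C_k = rate * 7.4 * Delta_k / 2        EUR per year

for the recurrent non-work states, and work absenteeism is the wage
value of the work shortfall ``C_A = rate * 7.4 * (-Delta_work) / 2``
(negative when the exposed group works more than the reference).
Per-employee averages use survey weights over the exposed (levels 1-3);
totals multiply the averages by the weighted employee counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .states import SICKNESS, TEMPORARY_OUT, UNEMPLOYMENT, WORK

logger = logging.getLogger(__name__)

__all__ = [
    "WAGE_MIN",
    "WAGE_MAX",
    "HOURS_PER_DAY",
    "DKK_PER_EUR",
    "standardize_hourly_wage",
    "impute_missing_wages",
    "adjust_to_price_level",
    "annual_cost_per_employee",
    "aggregate_costs",
    "component_share",
    "coverage_fraction",
    "total_cost_ratio",
    "reduction_scenario",
]

WAGE_MIN = 6.72  # EUR/hour, DKK 50
WAGE_MAX = 268.63  # EUR/hour, DKK 2000
HOURS_PER_DAY = 7.4  # Danish norm working day (37-hour week)
DKK_PER_EUR = 7.44  # implied by the DKK 50 / DKK 2000 truncation bounds

#: Non-work recurrent states whose excess days are costed as components.
COST_COMPONENT_STATES = (SICKNESS, UNEMPLOYMENT, TEMPORARY_OUT)

_IMPUTATION_PREDICTORS = ("sex", "age_group", "education", "sector", "industry_group")


def standardize_hourly_wage(payment: float, hours: float) -> tuple[float, str]:
    """Hourly rate from a payment record, truncated to the wage bounds.

    Returns ``(rate, source)`` with source one of ``observed``,
    ``truncated_low``, ``truncated_high``, ``missing`` (zero hours with
    positive payment: left for imputation).
    """
    if payment < 0:
        raise ValueError("negative payment")
    if hours <= 0:
        return (np.nan, "missing")
    rate = payment / hours
    if rate < WAGE_MIN:
        return (WAGE_MIN, "truncated_low")
    if rate > WAGE_MAX:
        return (WAGE_MAX, "truncated_high")
    return (rate, "observed")


def impute_missing_wages(baseline: pd.DataFrame) -> pd.DataFrame:
    """Fill missing hourly wages by log-linear regression.

    Fits ``log(rate) ~ sex + age group + education + sector + industry``
    on the observed wages and replaces missing rates with exponentiated
    predictions, clamped to the truncation bounds.  A category unseen at
    fit time falls back to the stratum mean wage (flagged in the log).
    """
    out = baseline.copy()
    if "wage_source" not in out.columns:
        out["wage_source"] = np.where(out["wage_rate"].isna(), "missing", "observed")
    obs = out[out["wage_rate"].notna()]
    miss = out[out["wage_rate"].isna()]
    if not len(miss):
        return out
    if not len(obs):
        raise ValueError("no observed wages to fit the imputation model")
    df = obs.assign(log_rate=np.log(obs["wage_rate"]))
    formula = "log_rate ~ " + " + ".join(f"C({c})" for c in _IMPUTATION_PREDICTORS)
    fit = smf.ols(formula, data=df).fit()

    seen = {c: set(obs[c].unique()) for c in _IMPUTATION_PREDICTORS}
    predictable = miss[
        np.logical_and.reduce([miss[c].isin(seen[c]) for c in _IMPUTATION_PREDICTORS])
    ]
    fallback = miss.drop(predictable.index)
    if len(predictable):
        pred = np.exp(fit.predict(predictable))
        out.loc[predictable.index, "wage_rate"] = np.clip(pred, WAGE_MIN, WAGE_MAX)
        out.loc[predictable.index, "wage_source"] = "imputed"
    if len(fallback):
        logger.warning(
            "%d record(s) with unseen categories imputed by stratum mean wage",
            len(fallback),
        )
        strat_mean = obs.groupby(["sex", "age_group"])["wage_rate"].mean()
        for idx, row in fallback.iterrows():
            key = (row["sex"], row["age_group"])
            val = strat_mean.get(key, obs["wage_rate"].mean())
            out.loc[idx, "wage_rate"] = float(np.clip(val, WAGE_MIN, WAGE_MAX))
            out.loc[idx, "wage_source"] = "imputed_fallback"
    return out


def adjust_to_price_level(
    rate: float, sex: str, age_group: str, year: int, cpi_table: dict
) -> float:
    """Rate at the 2022 price level via the sex/age-specific CPI factor.

    ``cpi_table`` maps ``(sex, age_group, year) -> factor`` with the 2022
    factor equal to 1; a missing entry is a configuration error.
    """
    if year == 2022:
        return float(rate)
    key = (sex, age_group, int(year))
    if key not in cpi_table:
        raise KeyError(f"no consumer price index entry for {key}")
    return float(rate) * float(cpi_table[key])


def annual_cost_per_employee(
    baseline: pd.DataFrame, duration_table: pd.DataFrame
) -> pd.DataFrame:
    """Per-person annual cost components from their cell's deltas.

    Each follow-up is matched to its stratum x exposure-level duration
    differences (days per two years) and costed at its own standardized
    hourly wage.  Adds columns ``cost_absenteeism``, ``cost_sickness``,
    ``cost_unemployment``, ``cost_temporary_out`` and the absorbing-state
    remainder ``cost_absorbing_remainder`` (EUR/year; negative = saving).
    """
    if baseline["wage_rate"].isna().any():
        raise ValueError("wage_rate has missing values; run impute_missing_wages first")
    deltas = duration_table.pivot_table(
        index=["stratum", "exposure_level"], columns="state", values="delta_days"
    )
    out = baseline.merge(
        deltas, left_on=["stratum", "exposure_level"], right_index=True, how="inner"
    )
    if len(out) < len(baseline):
        logger.warning(
            "%d follow-up(s) without a matching duration cell dropped",
            len(baseline) - len(out),
        )
    day_value = out["wage_rate"] * HOURS_PER_DAY / 2.0  # EUR per delta-day per year
    out["cost_absenteeism"] = -out[WORK] * day_value
    out["cost_sickness"] = out[SICKNESS] * day_value
    out["cost_unemployment"] = out[UNEMPLOYMENT] * day_value
    out["cost_temporary_out"] = out[TEMPORARY_OUT] * day_value
    recurrent_sum = out[WORK] + out[SICKNESS] + out[UNEMPLOYMENT] + out[TEMPORARY_OUT]
    out["cost_absorbing_remainder"] = -recurrent_sum * day_value
    return out


_COST_COLS = (
    "cost_absenteeism", "cost_sickness", "cost_unemployment", "cost_temporary_out",
)


def aggregate_costs(
    per_person: pd.DataFrame,
    workforce_count: int | None = None,
    full_time_only: bool = True,
) -> pd.DataFrame:
    """Survey-weighted cost table over exposed employees (levels 1-3).

    One row per sex x age group x exposure level with the weighted
    average annual cost per employee, the weighted employee count and the
    total (average x count); plus one ``Total`` row per sex averaging
    across ages and levels with exposed-count weighting.  When
    ``workforce_count`` is given the table carries the coverage fraction
    of the weighted sample against the national workforce.
    """
    df = per_person[per_person["exposure_level"] > 0].copy()
    if full_time_only and "time_arrangement" in df.columns:
        df = df[df["time_arrangement"] == "full_time"]
    if not len(df):
        raise ValueError("no exposed employees to aggregate")

    rows = []
    for (sex, age, lv), grp in df.groupby(["sex", "age_group", "exposure_level"]):
        wsum = grp["survey_weight"].sum()
        if wsum <= 0:
            logger.warning("cell (%s, %s, %s) has zero weight; omitted", sex, age, lv)
            continue
        row = dict(sex=sex, age_group=age, exposure_level=lv, weighted_n=wsum)
        for c in _COST_COLS:
            avg = np.average(grp[c], weights=grp["survey_weight"])
            row[c] = avg
            row[c + "_total"] = avg * wsum
        rows.append(row)
    for sex, grp in df.groupby("sex"):
        wsum = grp["survey_weight"].sum()
        row = dict(sex=sex, age_group="Total", exposure_level=-1, weighted_n=wsum)
        for c in _COST_COLS:
            avg = np.average(grp[c], weights=grp["survey_weight"])
            row[c] = avg
            row[c + "_total"] = avg * wsum
        row["sickness_share"] = (
            row["cost_sickness_total"] / row["cost_absenteeism_total"]
            if row["cost_absenteeism_total"] else np.nan
        )
        rows.append(row)
    out = pd.DataFrame(rows)
    if workforce_count:
        total_w = per_person["survey_weight"].sum()
        out["coverage"] = coverage_fraction(total_w, workforce_count)
    return out


# -- aggregation identities reused on any printed or computed totals --------

def component_share(component_total: float, absenteeism_total: float) -> float:
    """Share (0-1) of a cost component in the work-absenteeism total."""
    return float(component_total) / float(absenteeism_total)


def coverage_fraction(weighted_sample: float, workforce_count: float) -> float:
    """Weighted sample size over the national workforce count."""
    if workforce_count <= 0:
        raise ValueError("workforce count must be positive")
    return float(weighted_sample) / float(workforce_count)


def total_cost_ratio(total_a: float, total_b: float) -> float:
    """Ratio of two cost totals (e.g. men's over women's)."""
    return float(total_a) / float(total_b)


# ---------------------------------------------------------------------------
# Reduction scenarios
# ---------------------------------------------------------------------------

@dataclass
class ReductionResult:
    fraction: float
    absenteeism_total: float
    sickness_total: float
    absenteeism_reduction_pct: float
    sickness_reduction_pct: float


def reduction_scenario(
    per_person: pd.DataFrame,
    fraction: float,
    seed: int | np.random.Generator = 0,
) -> ReductionResult:
    """Hypothetical removal of work stress from a fraction of the exposed.

    A random ``fraction`` of exposed follow-ups, drawn proportionally
    within each exposure level, is re-assigned to the zero-indicator
    reference (their excess costs vanish); the weighted totals are then
    recomputed and expressed as a percent reduction.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("reduction fraction must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    exposed = per_person[per_person["exposure_level"] > 0]

    def totals(df):
        return (
            float((df["cost_absenteeism"] * df["survey_weight"]).sum()),
            float((df["cost_sickness"] * df["survey_weight"]).sum()),
        )

    base_abs, base_sick = totals(exposed)
    if fraction == 0.0:
        return ReductionResult(0.0, base_abs, base_sick, 0.0, 0.0)
    keep_parts = []
    for _, grp in exposed.groupby("exposure_level"):
        n_remove = int(round(fraction * len(grp)))
        # removal sets are nested across fractions under a fixed seed, so
        # the reported reduction is exactly monotone in the fraction
        perm = rng.permutation(grp.index.to_numpy())
        keep_parts.append(grp.drop(index=perm[:n_remove]))
    kept = pd.concat(keep_parts) if keep_parts else exposed.iloc[:0]
    new_abs, new_sick = totals(kept)
    return ReductionResult(
        fraction=fraction,
        absenteeism_total=new_abs,
        sickness_total=new_sick,
        absenteeism_reduction_pct=100.0 * (1.0 - new_abs / base_abs) if base_abs else 0.0,
        sickness_reduction_pct=100.0 * (1.0 - new_sick / base_sick) if base_sick else 0.0,
    )
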