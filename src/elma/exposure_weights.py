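"""Work-stress exposure coding, sex/age strata, and analysis weights.

The exposure is the count (0-3) of positive binary work-stress
indicators: self-perceived work stress, the Cohen four-item scale
modified to work stress, and job strain (high quantitative demands with
low influence).  Zero indicators is the reference level.

Confounder control enters only through weights: a stabilized inverse
probability weight from a per-stratum multinomial propensity model of
the exposure count on the nine baseline covariates, multiplied by the
register (coverage) weight.  Covariates never enter the hazard models.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

logger = logging.getLogger(__name__)

__all__ = [
    "STRESS_INDICATORS",
    "IPW_COVARIATES",
    "PROPENSITY_FLOOR",
    "count_stress_indicators",
    "add_exposure_level",
    "assign_stratum",
    "assign_strata",
    "estimate_ipw",
]

STRESS_INDICATORS: tuple[str, ...] = ("stress_self", "stress_cohen", "stress_strain")

#: The nine baseline covariates of the propensity model, coded with
#: explicit "not_available" levels rather than imputed.
IPW_COVARIATES: tuple[str, ...] = (
    "bmi", "smoking", "alcohol", "physical_activity", "disease_treatment",
    "time_arrangement", "sector", "education", "n_waves",
)

#: Propensities below this floor are truncated before inversion.
PROPENSITY_FLOOR = 0.001


def count_stress_indicators(indicators) -> int:
    """Number of positive indicators in a (self, Cohen-4, strain) triple."""
    vals = list(indicators)
    if len(vals) != 3:
        raise ValueError("expected exactly three stress indicators")
    for v in vals:
        if v is None or (isinstance(v, float) and np.isnan(v)) or v not in (0, 1):
            raise ValueError(f"stress indicator must be 0 or 1, got {v!r}")
    return int(sum(vals))


def add_exposure_level(baseline: pd.DataFrame) -> pd.DataFrame:
    """Attach ``exposure_level``; follow-ups with a missing indicator are
    excluded with a diagnostic."""
    ind = baseline[list(STRESS_INDICATORS)]
    ok = ind.isin([0, 1]).all(axis=1) & ind.notna().all(axis=1)
    if (~ok).any():
        logger.warning(
            "excluding %d follow-up(s) with missing work-stress indicators",
            int((~ok).sum()),
        )
    out = baseline[ok].copy()
    out["exposure_level"] = ind[ok].sum(axis=1).astype(int)
    return out


def assign_stratum(sex: str, age_at_start: float) -> str:
    """Sex x age-group label, cut points 34/35 and 49/50, ages 18-64."""
    if sex not in ("M", "F"):
        raise ValueError(f"sex must be 'M' or 'F', got {sex!r}")
    age = float(age_at_start)
    if not 18.0 <= age <= 64.0:
        raise ValueError(f"age at start must lie in [18, 64], got {age}")
    if age < 35.0:
        grp = "18-34"
    elif age < 50.0:
        grp = "35-49"
    else:
        grp = "50-64"
    return f"{sex}:{grp}"


def assign_strata(baseline: pd.DataFrame) -> pd.DataFrame:
    out = baseline.copy()
    out["stratum"] = [
        assign_stratum(s, a) for s, a in zip(out["sex"], out["age_at_start"])
    ]
    return out


def estimate_ipw(baseline: pd.DataFrame) -> pd.DataFrame:
    """Stabilized inverse-probability weights per follow-up.

    Per stratum, a multinomial logistic model of the exposure level on
    the nine covariates gives propensities ``p(level | x)``; the weight
    is the stabilized ratio ``P(level) / p(level | x)`` with the
    propensity floored at :data:`PROPENSITY_FLOOR`, multiplied by the
    register weight into the combined analysis weight.

    Returns the baseline frame with ``ipw`` and ``combined_weight``
    columns appended.
    """
    need = {"stratum", "exposure_level", "register_weight"}
    if not need <= set(baseline.columns):
        raise ValueError(f"baseline must carry columns {sorted(need)}")
    out = baseline.copy()
    out["ipw"] = np.nan
    n_floored = 0
    for stratum, grp in out.groupby("stratum"):
        y = grp["exposure_level"].to_numpy()
        marginal = pd.Series(y).value_counts(normalize=True)
        if marginal.size == 1:
            out.loc[grp.index, "ipw"] = 1.0
            continue
        x = pd.get_dummies(grp[list(IPW_COVARIATES)].astype(str), drop_first=True)
        if x.shape[1] == 0 or (x.nunique() <= 1).all():
            out.loc[grp.index, "ipw"] = 1.0
            continue
        model = LogisticRegression(C=np.inf, max_iter=2000)  # plain ML, no penalty
        model.fit(x.to_numpy(float), y)
        proba = model.predict_proba(x.to_numpy(float))
        idx = {lv: k for k, lv in enumerate(model.classes_)}
        p_own = proba[np.arange(len(y)), [idx[v] for v in y]]
        floored = p_own < PROPENSITY_FLOOR
        n_floored += int(floored.sum())
        p_own = np.maximum(p_own, PROPENSITY_FLOOR)
        out.loc[grp.index, "ipw"] = marginal.reindex(y).to_numpy() / p_own
    if n_floored:
        logger.warning("propensity floor applied to %d record(s)", n_floored)
    out["combined_weight"] = out["ipw"] * out["register_weight"]
    return out
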