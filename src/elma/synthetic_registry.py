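"""Synthetic survey + register cohort generator with a known Markov truth.

Emulates the structure of a linked occupational-health survey and
payment-register extract: a long-format episode table (one row per
person-interval in one labor market state, with recorded hours and
payments) plus a baseline table per follow-up (sex/age stratum, three
binary work-stress indicators, nine covariates, weights, start state,
hourly-wage observations).

Trajectories are exact samples from a continuous-time Markov chain whose
7x7 intensity matrix Q depends on the work-stress exposure level (0-3),
discretized to whole days as date-based registers are.  The closed-form
expected occupancy  E*_k = pi' * integral_0^T exp(Qt) dt  is provided as
the independent oracle for every downstream estimator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .states import (
    ABSORBING_STATES,
    AGE_GROUPS,
    EXPOSURE_LEVELS,
    N_STATES,
    RECURRENT_STATES,
    SEXES,
    STATE_INDEX,
    STATES,
    WORK,
)

__all__ = [
    "SimConfig",
    "SyntheticCohort",
    "default_generator_matrices",
    "default_sim_config",
    "simulate_cohort",
    "true_expected_durations",
    "validate_generator",
    "write_cohort",
]


class ConfigurationError(ValueError):
    """Raised for an invalid simulation configuration (e.g. a bad Q)."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

#: Baseline (exposure level 0) daily transition intensities, calibrated so
#: that reference-group occupancies are of the order seen in Danish register
#: cohorts of active employees (roughly 680-710 of 730 days in work for the
#: mid-age groups, 20-30 days of sickness absence).  Rates in 1/day.
_BASE_RATES: dict[tuple[str, str], float] = {
    ("work", "sickness_absence"): 0.002,
    ("work", "unemployment"): 0.0002,
    ("work", "temporary_out"): 0.0004,
    ("work", "retirement"): 0.000006,
    ("work", "disability_pension"): 0.000003,
    ("work", "death"): 0.000002,
    ("sickness_absence", "work"): 0.09,
    ("sickness_absence", "unemployment"): 0.003,
    ("sickness_absence", "temporary_out"): 0.001,
    ("sickness_absence", "retirement"): 0.0002,
    ("sickness_absence", "disability_pension"): 0.0005,
    ("sickness_absence", "death"): 0.0001,
    ("unemployment", "work"): 0.03,
    ("unemployment", "sickness_absence"): 0.002,
    ("unemployment", "temporary_out"): 0.003,
    ("unemployment", "retirement"): 0.0002,
    ("unemployment", "disability_pension"): 0.0001,
    ("unemployment", "death"): 0.00005,
    ("temporary_out", "work"): 0.03,
    ("temporary_out", "sickness_absence"): 0.001,
    ("temporary_out", "unemployment"): 0.003,
    ("temporary_out", "retirement"): 0.0001,
    ("temporary_out", "disability_pension"): 0.00005,
    ("temporary_out", "death"): 0.00005,
}

#: Exposure hazard ratios applied multiplicatively to selected arrows, by
#: exposure level 0..3.  Work-stress raises the work->sickness hazard
#: (ratios 1, 1.5, 1.75, 2.0) and, more weakly, the work->unemployment
#: hazard, and slows return to work from sickness absence.
_EXPOSURE_HR: dict[tuple[str, str], tuple[float, float, float, float]] = {
    ("work", "sickness_absence"): (1.0, 1.5, 1.75, 2.0),
    ("work", "unemployment"): (1.0, 1.2, 1.4, 1.6),
    ("sickness_absence", "work"): (1.0, 0.9, 0.85, 0.8),
}


def _rates_to_q(rates: dict[tuple[str, str], float]) -> np.ndarray:
    q = np.zeros((N_STATES, N_STATES))
    for (h, j), r in rates.items():
        q[STATE_INDEX[h], STATE_INDEX[j]] = r
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def default_generator_matrices() -> dict[int, np.ndarray]:
    """Per-exposure-level intensity matrices with the default calibration."""
    out: dict[int, np.ndarray] = {}
    for level in EXPOSURE_LEVELS:
        rates = {
            hj: r * (_EXPOSURE_HR[hj][level] if hj in _EXPOSURE_HR else 1.0)
            for hj, r in _BASE_RATES.items()
        }
        out[level] = _rates_to_q(rates)
    return out


@dataclass
class SimConfig:
    """Study conditions of one synthetic cohort.

    Parameters
    ----------
    n_persons
        Number of follow-ups simulated (one follow-up per person here).
    horizon_days
        Length of the follow-up window in days (default two years, 730).
    strata
        The sex x age-group cells; persons are allocated uniformly.
    stress_prevalence
        Per-stratum probability that each of the three binary work-stress
        indicators (self-perceived stress, Cohen-4 work stress, job strain)
        is positive; indicators are drawn independently.
    generator_matrices
        Mapping exposure level (0-3) -> 7x7 daily intensity matrix Q.
    wage_model
        Per-stratum (location, scale) of the log-normal hourly wage in
        EUR/hour at the 2022 price level.
    missing_wage_fraction
        Fraction of baseline hourly-wage observations set missing.
    start_distribution
        Probabilities over the four recurrent states at follow-up start.
    smoker_stress_logodds, smoker_sickness_hr
        Optional confounding: smokers get this log-odds shift on every
        stress indicator and this hazard ratio on work->sickness.  Both
        neutral by default.
    seed
        Seed of the single RNG stream driving the whole cohort.
    """

    n_persons: int
    horizon_days: int = 730
    strata: tuple[tuple[str, str], ...] = tuple((s, a) for s in SEXES for a in AGE_GROUPS)
    stress_prevalence: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    generator_matrices: dict[int, np.ndarray] = field(default_factory=default_generator_matrices)
    wage_model: dict[str, tuple[float, float]] = field(default_factory=dict)
    missing_wage_fraction: float = 0.10
    start_distribution: tuple[float, float, float, float] = (0.90, 0.03, 0.03, 0.04)
    smoker_stress_logodds: float = 0.0
    smoker_sickness_hr: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for sex, age in self.strata:
            key = f"{sex}:{age}"
            if key not in self.stress_prevalence:
                self.stress_prevalence[key] = (0.13, 0.18, 0.14)
            if key not in self.wage_model:
                mu = np.log(30.0) if sex == "M" else np.log(22.0)
                self.wage_model[key] = (mu, 0.35)
        for key, p in self.stress_prevalence.items():
            if not all(0.0 <= x <= 1.0 for x in p):
                raise ConfigurationError(f"stress prevalence out of [0,1] for {key}")
        if not 0.0 <= self.missing_wage_fraction <= 1.0:
            raise ConfigurationError("missing_wage_fraction must lie in [0,1]")
        if abs(sum(self.start_distribution) - 1.0) > 1e-9:
            raise ConfigurationError("start_distribution must sum to 1")
        for level, q in self.generator_matrices.items():
            validate_generator(np.asarray(q, dtype=float), label=f"level {level}")


def default_sim_config(n_persons: int = 5000, seed: int = 0, **overrides) -> SimConfig:
    return SimConfig(n_persons=n_persons, seed=seed, **overrides)


def validate_generator(q: np.ndarray, label: str = "Q") -> np.ndarray:
    """Check that Q is a valid intensity matrix for the 7-state model."""
    q = np.asarray(q, dtype=float)
    if q.shape != (N_STATES, N_STATES):
        raise ConfigurationError(f"{label}: expected shape {(N_STATES, N_STATES)}, got {q.shape}")
    off = q - np.diag(np.diag(q))
    if (off < -1e-12).any():
        raise ConfigurationError(f"{label}: negative off-diagonal intensity")
    if np.abs(q.sum(axis=1)).max() > 1e-9:
        raise ConfigurationError(f"{label}: rows must sum to 0")
    for a in ABSORBING_STATES:
        if np.abs(q[STATE_INDEX[a]]).max() > 0:
            raise ConfigurationError(f"{label}: absorbing state {a} must have a zero row")
    return q


# ---------------------------------------------------------------------------
# Closed-form oracle
# ---------------------------------------------------------------------------

def true_expected_durations(
    q: np.ndarray, start: np.ndarray, horizon: float
) -> np.ndarray:
    """Expected days per state: ``pi' * integral_0^T exp(Qt) dt``.

    Computed by the block matrix-exponential identity: the upper-right
    block of ``expm([[Q, I], [0, 0]] * T)`` equals the integral, exact to
    machine precision for any valid generator.
    """
    q = validate_generator(q)
    pi = np.asarray(start, dtype=float)
    if pi.shape != (N_STATES,) or abs(pi.sum() - 1.0) > 1e-9 or (pi < 0).any():
        raise ValueError("start must be a probability vector over the 7 states")
    n = N_STATES
    block = np.zeros((2 * n, 2 * n))
    block[:n, :n] = q
    block[:n, n:] = np.eye(n)
    integral = expm(block * horizon)[:n, n:]
    return pi @ integral


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    """Episodes + baseline tables with the generating truth attached."""

    episodes: pd.DataFrame
    baseline: pd.DataFrame
    truth: pd.DataFrame  # stratum, exposure_level, state, expected_days
    config: SimConfig


def _sample_trajectory(
    rng: np.random.Generator, q: np.ndarray, start_idx: int, horizon: int
) -> list[tuple[int, int, int]]:
    """One day-discretized path: list of (start_day, end_day, state index).

    The continuous-time chain is sampled exactly (exponential holding
    times, embedded jump chain); the path is then read off at each day
    start, so sojourns that never span a day boundary vanish, as they do
    in date-based registers.
    """
    jumps: list[tuple[float, int]] = [(0.0, start_idx)]
    t, s = 0.0, start_idx
    while True:
        rate = -q[s, s]
        if rate <= 0.0:
            break
        t = t + rng.exponential(1.0 / rate)
        if t >= horizon:
            break
        probs = np.maximum(q[s], 0.0)
        probs[s] = 0.0
        s = int(rng.choice(N_STATES, p=probs / probs.sum()))
        jumps.append((t, s))

    # a jump at time t first occupies day ceil(t); within a day the last
    # jump wins (the state occupied at the start of the next day)
    boundaries: list[tuple[int, int]] = [(0, start_idx)]
    for t, s in jumps[1:]:
        day = int(np.ceil(t))
        if day >= horizon:
            break
        if boundaries[-1][0] == day:
            boundaries[-1] = (day, s)
        else:
            boundaries.append((day, s))
    episodes: list[tuple[int, int, int]] = []
    for k, (day, s) in enumerate(boundaries):
        end = boundaries[k + 1][0] if k + 1 < len(boundaries) else horizon
        if episodes and episodes[-1][2] == s:
            episodes[-1] = (episodes[-1][0], end, s)
        elif end > day:
            episodes.append((day, end, s))
    return episodes


# covariate levels mirror the baseline table of the source registers,
# including explicit "Not available" categories
_COVARIATE_LEVELS: dict[str, tuple[tuple[str, float], ...]] = {
    "bmi": (("underweight", 0.01), ("normal", 0.45), ("overweight", 0.35),
            ("obese", 0.14), ("not_available", 0.05)),
    "smoking": (("no", 0.77), ("yes", 0.19), ("not_available", 0.04)),
    "alcohol": (("none", 0.18), ("moderate", 0.40), ("high", 0.38),
                ("not_available", 0.04)),
    "physical_activity": (("no", 0.58), ("yes", 0.42)),
    "disease_treatment": (("no", 0.35), ("yes", 0.15), ("not_available", 0.50)),
    "time_arrangement": (("full_time", 0.80), ("medium", 0.17), ("low", 0.03)),
    "sector": (("private", 0.48), ("public", 0.52)),
    "education": (("low", 0.10), ("middle", 0.40), ("high", 0.49),
                  ("not_available", 0.01)),
    "n_waves": (("1_of_4", 0.73), ("2_of_4", 0.17), ("3_of_4", 0.05), ("4_of_4", 0.05)),
}

_INDUSTRY_LEVELS = ("manufacturing", "services", "public_admin")
_AGE_RANGE = {"18-34": (18, 34), "35-49": (35, 49), "50-64": (50, 64)}


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Draw a full synthetic cohort from the configured study conditions."""
    rng = np.random.default_rng(config.seed)
    n = config.n_persons
    horizon = config.horizon_days
    q_by_level = {lv: np.asarray(q, float) for lv, q in config.generator_matrices.items()}

    stratum_keys = [f"{s}:{a}" for s, a in config.strata]
    stratum_of = rng.choice(len(stratum_keys), size=n)
    start_idx_pool = rng.choice(
        [STATE_INDEX[s] for s in RECURRENT_STATES], size=n, p=config.start_distribution
    )

    base_rows: list[dict] = []
    epi_rows: list[dict] = []
    for pid in range(n):
        key = stratum_keys[stratum_of[pid]]
        sex, age_group = key.split(":")
        lo, hi = _AGE_RANGE[age_group]
        age = float(rng.integers(lo, hi + 1))

        covs = {
            name: levels[int(rng.choice(len(levels), p=[p for _, p in levels]))][0]
            for name, levels in _COVARIATE_LEVELS.items()
        }
        industry = _INDUSTRY_LEVELS[int(rng.integers(len(_INDUSTRY_LEVELS)))]

        prev = np.asarray(config.stress_prevalence[key], float)
        if config.smoker_stress_logodds != 0.0 and covs["smoking"] == "yes":
            logit = np.log(prev / (1 - prev)) + config.smoker_stress_logodds
            prev = 1.0 / (1.0 + np.exp(-logit))
        indicators = (rng.random(3) < prev).astype(int)
        level = int(indicators.sum())

        q = q_by_level[level]
        if config.smoker_sickness_hr != 1.0 and covs["smoking"] == "yes":
            q = q.copy()
            i, j = STATE_INDEX[WORK], STATE_INDEX["sickness_absence"]
            q[i, j] *= config.smoker_sickness_hr
            q[i, i] = -(q[i].sum() - q[i, i])

        start_idx = int(start_idx_pool[pid])
        path = _sample_trajectory(rng, q, start_idx, horizon)

        mu, sigma = config.wage_model[key]
        rate = float(rng.lognormal(mu, sigma))
        arrangement = {"full_time": 1.0, "medium": 0.8, "low": 0.4}[covs["time_arrangement"]]

        for a, b, sidx in path:
            state = STATES[sidx]
            days = b - a
            if state == WORK:
                hours = 7.4 * days * arrangement
                payment = rate * hours
            elif state in ("sickness_absence", "unemployment"):
                hours = 7.4 * days * arrangement
                payment = 0.6 * rate * hours
            else:
                hours, payment = 0.0, 0.0
            epi_rows.append(
                dict(person_id=pid, follow_up_id=pid, start_day=a, end_day=b,
                     state=state, hours=round(hours, 2), payment=round(payment, 2))
            )

        wage_obs = np.nan if rng.random() < config.missing_wage_fraction else round(rate, 4)
        base_rows.append(
            dict(
                person_id=pid, follow_up_id=pid, sex=sex, age_group=age_group,
                age_at_start=age,
                stress_self=int(indicators[0]), stress_cohen=int(indicators[1]),
                stress_strain=int(indicators[2]),
                **covs, industry_group=industry,
                survey_weight=float(rng.lognormal(0.0, 0.25)),
                register_weight=float(rng.lognormal(0.0, 0.10)),
                start_state=STATES[start_idx], employer_id=1000 + pid % 97,
                wage_rate=wage_obs, wage_year=2022,
            )
        )

    truth_rows = []
    for key in stratum_keys:
        for lv, q in q_by_level.items():
            pi = np.zeros(N_STATES)
            for s, p in zip(RECURRENT_STATES, config.start_distribution):
                pi[STATE_INDEX[s]] = p
            e_star = true_expected_durations(q, pi, horizon)
            for s, e in zip(STATES, e_star):
                truth_rows.append(
                    dict(stratum=key, exposure_level=lv, state=s, expected_days=float(e))
                )

    return SyntheticCohort(
        episodes=pd.DataFrame(epi_rows),
        baseline=pd.DataFrame(base_rows),
        truth=pd.DataFrame(truth_rows),
        config=config,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write episodes/baseline as CSV and the truth vector as a JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "episodes": outdir / "episodes.csv",
        "baseline": outdir / "baseline.csv",
        "truth": outdir / "truth.json",
    }
    cohort.episodes.to_csv(paths["episodes"], index=False)
    cohort.baseline.to_csv(paths["baseline"], index=False)
    truth = {
        f"{row.stratum}|{row.exposure_level}|{row.state}": row.expected_days
        for row in cohort.truth.itertuples()
    }
    paths["truth"].write_text(json.dumps(truth, indent=1))
    return paths
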