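"""Expected labor market affiliation (ELMA) estimation.

For each of the 24 permitted transitions a weighted Cox proportional
hazards model is fitted with the exposure count entering as three dummy
variables (levels 1-3 against the zero-indicator reference); ties are
handled and the reference-group baseline cumulative hazard estimated by
the Breslow method.  The per-day cumulative-hazard increments are then
composed through the product integral

    P(0, t) = prod_{t_m <= t} (I + dA(t_m)),

the discrete realization of the Chapman-Kolmogorov equation, giving the
7x7 state probability matrix at every event day.  Integrating the
state-occupation probabilities ``p_k(t) = sum_h pi_h P_hk(0, t)`` over
the 730-day window (exact, since they are step functions) yields the
expected days in each state; differences against the reference exposure
level are the quantities costed downstream.

Confidence intervals come from normally distributed random resamples of
the fitted quantities: per transition, coefficient vectors drawn from
the asymptotic normal of the Cox estimate and baseline increments
perturbed with their Poisson-type standard errors, propagated through
the product integral to the duration scale (percentile intervals).

The Cox partial-likelihood Newton solver is implemented here because the
estimator needs Breslow ties, delayed entry, case weights, and capped
monotone-likelihood handling in one model, a combination the surrounding
survival libraries do not expose together; it is cross-checked against
lifelines on tie-free data in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .states import (
    EXPOSURE_LEVELS,
    N_STATES,
    PERMITTED_TRANSITIONS,
    STATE_INDEX,
    STATES,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TransitionModel",
    "ProbabilityPath",
    "fit_transition_hazard",
    "fit_all_transitions",
    "transition_probability",
    "expected_durations",
    "duration_differences",
    "sample_duration_draws",
    "confidence_intervals",
    "estimate_state_durations",
    "crude_durations",
]

#: Cap on the log hazard ratio under monotone likelihood.
BETA_CAP = 10.0

_N_LEVELS = len(EXPOSURE_LEVELS)
_ARROW_INDEX = {hj: k for k, hj in enumerate(PERMITTED_TRANSITIONS)}
_HS = np.array([STATE_INDEX[h] for h, _ in PERMITTED_TRANSITIONS])
_JS = np.array([STATE_INDEX[j] for _, j in PERMITTED_TRANSITIONS])
# scatter matrices: arrow -> origin / destination state
_M_OUT = np.zeros((len(PERMITTED_TRANSITIONS), N_STATES))
_M_IN = np.zeros((len(PERMITTED_TRANSITIONS), N_STATES))
for _k, (_h, _j) in enumerate(PERMITTED_TRANSITIONS):
    _M_OUT[_k, STATE_INDEX[_h]] = 1.0
    _M_IN[_k, STATE_INDEX[_j]] = 1.0
_M_NET = _M_IN - _M_OUT


# ---------------------------------------------------------------------------
# Per-transition Cox model
# ---------------------------------------------------------------------------

@dataclass
class TransitionModel:
    """Fitted hazard for one permitted transition.

    ``beta[k]`` is the log hazard ratio of exposure level ``k+1`` against
    the zero-indicator reference; ``base_increments`` are the Breslow
    baseline cumulative-hazard jumps at ``event_days`` (reference group),
    with Poisson-type standard errors ``increment_se``.
    """

    from_state: str
    to_state: str
    beta: np.ndarray
    cov: np.ndarray
    event_days: np.ndarray
    base_increments: np.ndarray
    increment_se: np.ndarray
    n_events: int = 0
    flags: list[str] = field(default_factory=list)
    #: weighted events per event day (Breslow numerator d_t)
    event_mass: np.ndarray = field(default_factory=lambda: np.zeros(0))
    #: weighted risk mass per event day and exposure level (nt x 4); the
    #: Breslow denominator is ``level_risk @ exp([0, beta])``, which lets
    #: resampling rebuild the baseline coherently for each coefficient draw
    level_risk: np.ndarray = field(default_factory=lambda: np.zeros((0, 4)))

    def hazard_factor(self, level: int) -> float:
        """exp(beta' z_level); 1 for the reference level."""
        return 1.0 if level == 0 else float(np.exp(self.beta[level - 1]))

    def cumulative_baseline(self, t: float) -> float:
        return float(self.base_increments[self.event_days <= t].sum())


def _risk_mass(entry, exit_, w, times):
    """Weighted number at risk (entry < t <= exit) at each time."""
    o_in = np.argsort(entry, kind="stable")
    o_out = np.argsort(exit_, kind="stable")
    ent_s, went = entry[o_in], np.concatenate([[0.0], np.cumsum(w[o_in])])
    ex_s, wex = exit_[o_out], np.concatenate([[0.0], np.cumsum(w[o_out])])
    entered = went[np.searchsorted(ent_s, times, side="left")]
    left = wex[np.searchsorted(ex_s, times, side="left")]
    return entered - left


def fit_transition_hazard(records: pd.DataFrame) -> TransitionModel:
    """Weighted Cox fit (Breslow ties and baseline) for one arrow.

    ``records`` is the transition-record table restricted to one
    ``(from_state, to_state)`` pair: columns ``entry_day``, ``exit_day``,
    ``event``, ``exposure_level``, ``weight``.

    With no events the model degenerates to a zero hazard.  Exposure
    levels at risk but without events have a monotone partial likelihood;
    their coefficient is capped at -BETA_CAP and flagged.
    """
    h = str(records["from_state"].iloc[0]) if len(records) else "?"
    j = str(records["to_state"].iloc[0]) if len(records) else "?"
    if not len(records) or int(records["event"].sum()) == 0:
        empty = np.zeros(0)
        return TransitionModel(
            h, j, np.zeros(_N_LEVELS - 1), np.zeros((_N_LEVELS - 1, _N_LEVELS - 1)),
            empty.astype(int), empty, empty, n_events=0, flags=["no_events"],
        )

    entry = records["entry_day"].to_numpy(float)
    exit_ = records["exit_day"].to_numpy(float)
    event = records["event"].to_numpy(int)
    level = records["exposure_level"].to_numpy(int)
    w = records["weight"].to_numpy(float)
    if (entry >= exit_).any():
        raise ValueError("transition records require entry_day < exit_day")

    times = np.unique(exit_[event == 1])
    nt = len(times)
    y = np.zeros((nt, _N_LEVELS))  # weighted risk mass per level
    d = np.zeros((nt, _N_LEVELS))  # weighted events per level
    sw2 = np.zeros(nt)  # sum of squared weights of events
    for lv in range(_N_LEVELS):
        m = level == lv
        if m.any():
            y[:, lv] = _risk_mass(entry[m], exit_[m], w[m], times)
        me = m & (event == 1)
        if me.any():
            t_idx = np.searchsorted(times, exit_[me])
            np.add.at(d[:, lv], t_idx, w[me])
            np.add.at(sw2, t_idx, w[me] ** 2)

    beta = np.zeros(_N_LEVELS)
    flags: list[str] = []
    d_tot_level = d.sum(axis=0)
    y_tot_level = y.sum(axis=0)
    free = [
        lv for lv in range(1, _N_LEVELS)
        if d_tot_level[lv] > 0 and y_tot_level[lv] > 0 and y_tot_level[0] > 0
    ]
    for lv in range(1, _N_LEVELS):
        if y_tot_level[lv] > 0 and d_tot_level[lv] == 0:
            beta[lv] = -BETA_CAP
            flags.append(f"monotone_level_{lv}")

    dt = d.sum(axis=1)

    def loglik(b):
        denom = y @ np.exp(b)
        return float((d * b).sum() - (dt * np.log(denom)).sum())

    cov = np.zeros((_N_LEVELS - 1, _N_LEVELS - 1))
    if free:
        fidx = np.array(free)
        ll = loglik(beta)
        for _ in range(50):
            eb = np.exp(beta)
            denom = y @ eb
            p = y * eb / denom[:, None]  # (nt, levels)
            score = d_tot_level[fidx] - (dt[:, None] * p[:, fidx]).sum(axis=0)
            info = np.einsum("t,tk,tl->kl", dt, p[:, fidx], p[:, fidx])
            info = np.diag((dt[:, None] * p[:, fidx]).sum(axis=0)) - info
            try:
                step = np.linalg.solve(info, score)
            except np.linalg.LinAlgError:
                flags.append("singular_information")
                break
            if not np.isfinite(step).all():
                flags.append("diverged")
                break
            alpha = 1.0
            for _half in range(30):
                cand = beta.copy()
                cand[fidx] = np.clip(beta[fidx] + alpha * step, -BETA_CAP, BETA_CAP)
                ll_new = loglik(cand)
                if ll_new >= ll - 1e-12:
                    break
                alpha *= 0.5
            moved = np.abs(cand - beta).max()
            beta, ll = cand, ll_new
            if moved < 1e-10 or np.abs(score).max() < 1e-9:
                break
        if np.abs(beta[fidx]).max() >= BETA_CAP - 1e-9:
            flags.append("beta_capped")
        # model-based covariance on the free levels
        eb = np.exp(beta)
        denom = y @ eb
        p = y * eb / denom[:, None]
        info = np.diag((dt[:, None] * p[:, fidx]).sum(axis=0)) - np.einsum(
            "t,tk,tl->kl", dt, p[:, fidx], p[:, fidx]
        )
        try:
            cov_free = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            cov_free = np.diag(1.0 / np.maximum(np.diag(info), 1e-12))
            flags.append("covariance_fallback")
        for a, lva in enumerate(free):
            for b_, lvb in enumerate(free):
                cov[lva - 1, lvb - 1] = cov_free[a, b_]

    denom = y @ np.exp(beta)
    increments = dt / denom
    inc_se = np.sqrt(sw2) / denom
    return TransitionModel(
        h, j, beta[1:].copy(), cov, times.astype(int), increments, inc_se,
        n_events=int(event.sum()), flags=flags,
        event_mass=dt, level_risk=y,
    )


def fit_all_transitions(records: pd.DataFrame) -> dict[tuple[str, str], TransitionModel]:
    """Fit every permitted arrow; arrows without records degenerate to a
    zero hazard (flagged) so the product integral stays well defined."""
    models: dict[tuple[str, str], TransitionModel] = {}
    grouped = dict(tuple(records.groupby(["from_state", "to_state"])))
    for hj in PERMITTED_TRANSITIONS:
        sub = grouped.get(hj)
        if sub is None:
            h, j = hj
            empty = np.zeros(0)
            models[hj] = TransitionModel(
                h, j, np.zeros(_N_LEVELS - 1),
                np.zeros((_N_LEVELS - 1, _N_LEVELS - 1)),
                empty.astype(int), empty, empty, flags=["no_records"],
            )
        else:
            models[hj] = fit_transition_hazard(sub)
    n_zero = sum(1 for m in models.values() if m.n_events == 0)
    if n_zero:
        logger.info("%d of 24 transitions have no events (zero hazard)", n_zero)
    return models


# ---------------------------------------------------------------------------
# Product-integral transition probabilities and durations
# ---------------------------------------------------------------------------

@dataclass
class ProbabilityPath:
    """State probability matrices P(0, t) along the event-day grid."""

    grid: np.ndarray  # (T+1,) days, grid[0] == 0
    P: np.ndarray  # (T+1, 7, 7)
    exposure_level: int
    start: np.ndarray  # (7,) start distribution pi
    stratum: str | None = None


def _increment_table(models: dict[tuple[str, str], TransitionModel]):
    """Union grid of event days with per-arrow baseline increments/SEs."""
    grid = np.unique(np.concatenate([m.event_days for m in models.values()] + [np.array([], int)]))
    inc = np.zeros((len(grid), len(PERMITTED_TRANSITIONS)))
    se = np.zeros_like(inc)
    for hj, m in models.items():
        if len(m.event_days) == 0:
            continue
        pos = np.searchsorted(grid, m.event_days)
        inc[pos, _ARROW_INDEX[hj]] = m.base_increments
        se[pos, _ARROW_INDEX[hj]] = m.increment_se
    return grid, inc, se


def _level_factors(models, level: int) -> np.ndarray:
    return np.array([models[hj].hazard_factor(level) for hj in PERMITTED_TRANSITIONS])


def transition_probability(
    models: dict[tuple[str, str], TransitionModel],
    exposure_level: int,
    start: np.ndarray,
    stratum: str | None = None,
) -> ProbabilityPath:
    """P(0, t) at every event day for one exposure level.

    Off-diagonal increments are the Breslow baseline jumps scaled by the
    transition's exposure hazard ratio; the diagonal makes rows sum to
    zero.  If heavy ties push a row's total increment above 1 the
    off-diagonals are rescaled to unit mass with a warning, keeping each
    factor ``I + dA`` a stochastic matrix.
    """
    missing = [hj for hj in PERMITTED_TRANSITIONS if hj not in models]
    if missing:
        raise ValueError(f"models missing for transitions: {missing}")
    pi = np.asarray(start, float)
    if pi.shape != (N_STATES,) or abs(pi.sum() - 1.0) > 1e-8 or (pi < 0).any():
        raise ValueError("start must be a probability distribution over the 7 states")

    grid, inc, _ = _increment_table(models)
    inc = inc * _level_factors(models, exposure_level)[None, :]

    eye = np.eye(N_STATES)
    path = np.empty((len(grid) + 1, N_STATES, N_STATES))
    path[0] = eye
    p_mat = eye.copy()
    n_clipped = 0
    for t in range(len(grid)):
        a24 = inc[t]
        out = a24 @ _M_OUT  # (7,) outflow mass per origin state
        over = out > 1.0
        if over.any():
            n_clipped += 1
            scale = np.where(over, 1.0 / np.maximum(out, 1.0), 1.0)
            a24 = a24 * scale[_HS]
            out = a24 @ _M_OUT
            if (out > 1.0 + 1e-9).any():
                raise ValueError("non-stochastic increment row after rescaling")
        da = np.zeros((N_STATES, N_STATES))
        da[_HS, _JS] = a24
        np.fill_diagonal(da, -out)
        p_mat = p_mat @ (eye + da)
        path[t + 1] = p_mat
    if n_clipped:
        logger.warning("increment row mass exceeded 1 on %d grid day(s); rescaled", n_clipped)

    rowsums = path.sum(axis=2)
    if np.abs(rowsums - 1.0).max() > 1e-8:
        raise ValueError("transition probability rows failed to stay stochastic")
    return ProbabilityPath(
        grid=np.concatenate([[0], grid]), P=path,
        exposure_level=exposure_level, start=pi, stratum=stratum,
    )


def expected_durations(path: ProbabilityPath, horizon: int = 730) -> np.ndarray:
    """Expected days per state: exact integral of the step-function
    occupation probabilities over ``[0, horizon]``."""
    pi = path.start
    if abs(pi.sum() - 1.0) > 1e-8:
        raise ValueError("start distribution must sum to 1")
    occ = pi @ path.P  # (T+1, 7)
    times = np.minimum(path.grid, horizon)
    widths = np.diff(np.concatenate([times, [horizon]]))
    return (occ * widths[:, None]).sum(axis=0)


def duration_differences(durations_by_level: dict[int, np.ndarray]) -> dict[int, np.ndarray]:
    """Delta_k(level) = E_k(level) - E_k(0); negative = fewer days."""
    if 0 not in durations_by_level:
        raise ValueError("reference level 0 required")
    ref = durations_by_level[0]
    return {lv: e - ref for lv, e in durations_by_level.items()}


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def sample_duration_draws(
    models: dict[tuple[str, str], TransitionModel],
    start_by_level: dict[int, np.ndarray],
    n_resamples: int = 1000,
    seed: int | np.random.Generator = 0,
    horizon: int = 730,
    include_baseline: bool = True,
    chunk: int = 200,
) -> dict[int, np.ndarray]:
    """Duration resamples per exposure level, shared across levels.

    One set of parameter draws per resample — Cox coefficient vectors
    from their asymptotic normal per transition, plus independent normal
    perturbations of the baseline increments with their Poisson-type
    standard errors — is propagated through the product integral for
    every requested level, so level differences are differences of
    coupled draws.  The Breslow baseline is rebuilt from the stored risk
    masses under each coefficient draw (``d_t / sum_l Y_lt e^{b*_l}``),
    which carries the coefficient uncertainty into the reference-level
    durations as well.  Returns ``{level: (n_resamples, 7) draws}``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    grid, inc0, se = _increment_table(models)
    nt, na = inc0.shape
    widths = np.diff(np.concatenate([[0], np.minimum(grid, horizon), [horizon]]))
    levels = sorted(start_by_level)

    out = {lv: np.empty((n_resamples, N_STATES)) for lv in levels}
    done = 0
    while done < n_resamples:
        b = min(chunk, n_resamples - done)
        factors = {lv: np.ones((b, na)) for lv in levels}
        base = np.empty((b, nt, na))
        base[:] = inc0[None]
        for hj, m in models.items():
            k = _ARROW_INDEX[hj]
            if np.allclose(m.cov, 0.0):
                draws = np.tile(m.beta, (b, 1))
            else:
                draws = rng.multivariate_normal(m.beta, m.cov, size=b, method="svd")
            draws = np.clip(draws, -BETA_CAP, BETA_CAP)
            for lv in levels:
                if lv > 0:
                    factors[lv][:, k] = np.exp(draws[:, lv - 1])
            if len(m.event_days) and m.level_risk.size and m.level_risk.any():
                pos = np.searchsorted(grid, m.event_days)
                eb = np.exp(np.hstack([np.zeros((b, 1)), draws]))  # (b, 4)
                denom = eb @ m.level_risk.T  # (b, nt_m)
                base[:, pos, k] = m.event_mass[None, :] / denom
        if include_baseline and nt:
            pert = base + rng.standard_normal((b, nt, na)) * se[None]
            np.clip(pert, 0.0, None, out=pert)
        else:
            pert = base

        for lv in levels:
            p = np.tile(start_by_level[lv], (b, 1))
            e = p * widths[0]
            for t in range(nt):
                a24 = pert[:, t, :] * factors[lv]
                outm = a24 @ _M_OUT
                over = outm > 1.0
                if over.any():
                    scale = np.where(over, 1.0 / np.maximum(outm, 1.0), 1.0)
                    a24 = a24 * scale[:, _HS]
                flow = p[:, _HS] * a24
                p = p + flow @ _M_NET
                e = e + p * widths[t + 1]
            out[lv][done:done + b] = e
        done += b
    return out


def confidence_intervals(
    draws_by_level: dict[int, np.ndarray], alpha: float = 0.05
) -> dict[int, dict[str, np.ndarray]]:
    """Percentile CIs for durations and their reference differences."""
    qs = (100 * alpha / 2, 100 * (1 - alpha / 2))
    out: dict[int, dict[str, np.ndarray]] = {}
    ref = draws_by_level.get(0)
    for lv, draws in draws_by_level.items():
        lo, hi = np.percentile(draws, qs, axis=0)
        entry = {"low": lo, "high": hi}
        if ref is not None:
            dlo, dhi = np.percentile(draws - ref, qs, axis=0)
            entry["delta_low"], entry["delta_high"] = dlo, dhi
        out[lv] = entry
    return out


# ---------------------------------------------------------------------------
# High-level estimation per stratum
# ---------------------------------------------------------------------------

def _start_distribution(baseline_cell: pd.DataFrame) -> np.ndarray:
    pi = np.zeros(N_STATES)
    if len(baseline_cell):
        freq = baseline_cell["start_state"].value_counts(normalize=True)
        for s, p in freq.items():
            pi[STATE_INDEX[s]] = p
    return pi


def estimate_state_durations(
    records: pd.DataFrame,
    baseline: pd.DataFrame,
    stratum: str | None = None,
    horizon: int = 730,
    n_resamples: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[tuple[str, str], TransitionModel], dict[int, np.ndarray]]:
    """Fit one stratum end to end: Cox models, durations, deltas, CIs.

    The start distribution of each exposure cell is its observed
    start-state frequency (falling back to the stratum-wide frequency
    for empty cells).  Returns the duration table (one row per exposure
    level x state), the fitted models, and the raw duration draws.
    """
    models = fit_all_transitions(records)
    levels = sorted(baseline["exposure_level"].unique())
    if 0 not in levels:
        raise ValueError("reference exposure level 0 absent from the stratum")
    start_by_level: dict[int, np.ndarray] = {}
    pi_all = _start_distribution(baseline)
    for lv in levels:
        cell = baseline[baseline["exposure_level"] == lv]
        pi = _start_distribution(cell)
        start_by_level[lv] = pi if pi.sum() > 0 else pi_all

    e_by_level = {
        lv: expected_durations(
            transition_probability(models, lv, start_by_level[lv], stratum), horizon
        )
        for lv in levels
    }
    deltas = duration_differences(e_by_level)
    draws = sample_duration_draws(
        models, start_by_level, n_resamples=n_resamples, seed=seed, horizon=horizon
    )
    cis = confidence_intervals(draws)

    rows = []
    for lv in levels:
        for k, state in enumerate(STATES):
            rows.append(
                dict(
                    stratum=stratum, exposure_level=lv, state=state,
                    expected_days=e_by_level[lv][k],
                    ci_low=cis[lv]["low"][k], ci_high=cis[lv]["high"][k],
                    delta_days=deltas[lv][k],
                    delta_low=cis[lv].get("delta_low", np.zeros(N_STATES))[k],
                    delta_high=cis[lv].get("delta_high", np.zeros(N_STATES))[k],
                    n_followups=int((baseline["exposure_level"] == lv).sum()),
                )
            )
    return pd.DataFrame(rows), models, draws


# ---------------------------------------------------------------------------
# Crude comparator
# ---------------------------------------------------------------------------

def crude_durations(episodes: pd.DataFrame, baseline: pd.DataFrame) -> pd.DataFrame:
    """Mean observed days per state per stratum x exposure cell.

    The crude estimator: total days spent in the state across all
    employees of the cell divided by the number of employees, ignoring
    the transition structure (and hence biased under censoring).
    """
    need = {"follow_up_id", "stratum", "exposure_level"}
    if not need <= set(baseline.columns):
        raise ValueError(f"baseline must carry columns {sorted(need)}")
    epi = episodes.merge(
        baseline[["follow_up_id", "stratum", "exposure_level"]],
        on="follow_up_id", how="inner",
    )
    epi["days"] = epi["end_day"] - epi["start_day"]
    sums = (
        epi.groupby(["stratum", "exposure_level", "state"], observed=True)["days"]
        .sum()
        .unstack(fill_value=0.0)
        .reindex(columns=list(STATES), fill_value=0.0)
    )
    counts = baseline.groupby(["stratum", "exposure_level"]).size()
    empty = counts[counts == 0]
    if len(empty):
        logger.warning("empty stratum x exposure cells omitted: %s", list(empty.index))
    out = sums.div(counts, axis=0).dropna(how="all")
    out = out.reset_index().melt(
        id_vars=["stratum", "exposure_level"], var_name="state", value_name="crude_days"
    )
    return out.sort_values(["stratum", "exposure_level", "state"]).reset_index(drop=True)
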