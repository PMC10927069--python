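"""Analysis-ready multi-state event histories.

Turns raw dated payment/benefit records into a clean tiling of each
follow-up window by the seven labor market states (state prioritization,
gap handling), applies the censoring scheme (end of two-year window,
age 65, next follow-up, employer change), and expands censored episodes
into per-transition risk-set records for the 24 permitted arrows.

All tables are plain pandas DataFrames; see :data:`SCHEMAS` for the
column contracts.  Day intervals are half-open integers ``[start, end)``
on the clock-forward scale (days since follow-up start).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .states import (
    ABSORBING_PRIORITY,
    PERMITTED_TRANSITIONS,
    RECURRENT_STATES,
    STATES,
    is_absorbing,
    is_recurrent,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SCHEMAS",
    "build_episodes",
    "apply_censoring",
    "to_transition_records",
]

#: Column contracts of the tables exchanged between pipeline stages.
SCHEMAS: dict[str, dict[str, str]] = {
    "raw_records": {
        "person_id": "int — person identifier",
        "follow_up_id": "int — follow-up window identifier",
        "start_day": "int — first day covered (inclusive), days since follow-up start",
        "end_day": "int — first day not covered (exclusive)",
        "state": "str — labor market state implied by the payment type",
        "hours": "float — hours recorded on the payment",
        "payment": "float — gross payment, EUR",
    },
    "episodes": {
        "person_id": "int",
        "follow_up_id": "int",
        "start_day": "int — inclusive, 0 <= start < end <= horizon",
        "end_day": "int — exclusive",
        "state": "str — one of the seven states",
        "hours": "float — hours attributed to the episode",
        "payment": "float — EUR attributed to the episode",
    },
    "transition_records": {
        "follow_up_id": "int",
        "from_state": "str — recurrent state h",
        "to_state": "str — permitted destination j",
        "entry_day": "int — risk-set entry (late entry), days since follow-up start",
        "exit_day": "int — risk-set exit",
        "event": "int — 1 if the h->j transition occurred at exit_day",
        "exposure_level": "int — 0..3 work-stress indicator count",
        "weight": "float — combined analysis weight",
    },
}

_DESTINATIONS: dict[str, tuple[str, ...]] = {
    h: tuple(j for (hh, j) in PERMITTED_TRANSITIONS if hh == h) for h in RECURRENT_STATES
}


class EventHistoryError(ValueError):
    """Raised when raw records violate the event-history contract."""


# ---------------------------------------------------------------------------
# Episode construction
# ---------------------------------------------------------------------------

def build_episodes(raw_records: pd.DataFrame, horizon: int = 730) -> pd.DataFrame:
    """Resolve overlapping dated payment records into one state per day.

    Rules, in order:

    * absorbing states dominate recurrent ones; among simultaneous
      absorbing records death > disability pension > retirement;
    * among simultaneous recurrent payments the one with most recorded
      hours per day wins;
    * an absorbing state is terminal — it extends to the horizon and any
      recurrent record starting after its onset is rejected;
    * days covered by no record inherit the preceding state (registers
      hold no leisure-time records); a leading gap inherits the first
      recorded state.

    Contiguous same-state days are merged into maximal episodes carrying
    the summed hours/payments of the records that won them.
    """
    req = {"person_id", "follow_up_id", "start_day", "end_day", "state", "hours", "payment"}
    missing = req - set(raw_records.columns)
    if missing:
        raise EventHistoryError(f"raw records missing columns: {sorted(missing)}")

    out_rows: list[dict] = []
    for (pid, fid), grp in raw_records.groupby(["person_id", "follow_up_id"], sort=True):
        grp = grp.sort_values(["start_day", "end_day"])
        absorbing = grp[grp["state"].map(is_absorbing)]
        absorb_day, absorb_state = None, None
        if len(absorbing):
            for cand_state in ABSORBING_PRIORITY[::-1]:
                sub = absorbing[absorbing["state"] == cand_state]
                if len(sub):
                    day = int(sub["start_day"].min())
                    if absorb_day is None or day <= absorb_day:
                        absorb_day, absorb_state = day, cand_state
        if absorb_day is not None:
            late = grp[(grp["start_day"] > absorb_day) & ~grp["state"].map(is_absorbing)]
            if len(late):
                raise EventHistoryError(
                    f"person {pid}: {len(late)} record(s) dated after entry into "
                    f"absorbing state {absorb_state} at day {absorb_day}"
                )

        recurrent = grp[grp["state"].map(is_recurrent)]
        window_end = absorb_day if absorb_day is not None else horizon
        # elementary intervals between record boundaries
        cuts = sorted(
            {0, window_end}
            | {int(d) for d in recurrent["start_day"] if 0 <= d < window_end}
            | {int(d) for d in recurrent["end_day"] if 0 < d < window_end}
        )
        day_state: list[tuple[int, int, str, float, float]] = []
        for a, b in zip(cuts[:-1], cuts[1:]):
            cover = recurrent[(recurrent["start_day"] <= a) & (recurrent["end_day"] >= b)]
            if len(cover):
                rate = cover["hours"] / (cover["end_day"] - cover["start_day"]).clip(lower=1)
                win = cover.loc[rate.idxmax()]
                frac = (b - a) / max(win["end_day"] - win["start_day"], 1)
                day_state.append((a, b, win["state"], win["hours"] * frac, win["payment"] * frac))
            else:
                day_state.append((a, b, "", 0.0, 0.0))  # gap, filled below
        # gap inheritance
        first_state = next((s for *_ab, s, _h, _p in day_state if s), None)
        prev = first_state
        filled = []
        for a, b, s, h, p in day_state:
            if not s:
                if prev is None:
                    continue
                s = prev
            prev = s
            filled.append((a, b, s, h, p))
        # merge contiguous same-state stretches
        for a, b, s, h, p in filled:
            if out_rows and out_rows[-1]["person_id"] == pid and out_rows[-1][
                "follow_up_id"
            ] == fid and out_rows[-1]["state"] == s and out_rows[-1]["end_day"] == a:
                out_rows[-1]["end_day"] = b
                out_rows[-1]["hours"] += h
                out_rows[-1]["payment"] += p
            else:
                out_rows.append(
                    dict(person_id=pid, follow_up_id=fid, start_day=a, end_day=b,
                         state=s, hours=h, payment=p)
                )
        if absorb_day is not None and absorb_day < horizon:
            out_rows.append(
                dict(person_id=pid, follow_up_id=fid, start_day=absorb_day,
                     end_day=horizon, state=absorb_state, hours=0.0, payment=0.0)
            )
    return pd.DataFrame(
        out_rows,
        columns=["person_id", "follow_up_id", "start_day", "end_day", "state", "hours", "payment"],
    )


# ---------------------------------------------------------------------------
# Censoring
# ---------------------------------------------------------------------------

def censor_day_of(followup: pd.Series | dict, horizon: int = 730) -> int:
    """First occurrence of: end of window, turning 65, next follow-up,
    or a new employer id."""
    get = followup.get if hasattr(followup, "get") else followup.__getitem__
    candidates = [horizon]
    age = get("age_at_start")
    if age is not None and not (isinstance(age, float) and math.isnan(age)):
        candidates.append(max(0, int(math.ceil((65.0 - float(age)) * 365.25))))
    for key in ("next_followup_start_day", "employer_change_day"):
        v = get(key) if hasattr(followup, "get") else None
        if isinstance(followup, dict):
            v = followup.get(key)
        if v is not None and not (isinstance(v, float) and math.isnan(v)):
            candidates.append(int(v))
    return min(candidates)


def apply_censoring(
    episodes: pd.DataFrame, baseline: pd.DataFrame, horizon: int = 730
) -> pd.DataFrame:
    """Truncate each follow-up's episodes at its censor day.

    ``baseline`` must carry ``follow_up_id`` and ``age_at_start``;
    optional columns ``next_followup_start_day`` and
    ``employer_change_day`` supply the remaining censoring causes.
    """
    base = baseline.set_index("follow_up_id")
    censor = {
        fid: censor_day_of(row, horizon=horizon) for fid, row in base.iterrows()
    }
    out = episodes.copy()
    cvec = out["follow_up_id"].map(censor).fillna(horizon).astype(int)
    out["end_day"] = np.minimum(out["end_day"], cvec)
    out = out[out["start_day"] < out["end_day"]].reset_index(drop=True)
    n_dropped = len(episodes) - len(out)
    if n_dropped:
        logger.info("censoring dropped %d episode(s) past the censor day", n_dropped)
    return out


# ---------------------------------------------------------------------------
# Transition (risk-set) records
# ---------------------------------------------------------------------------

def to_transition_records(
    episodes: pd.DataFrame, baseline: pd.DataFrame
) -> pd.DataFrame:
    """Expand censored episodes into one record per permitted arrow.

    Every recurrent episode ``[a, b)`` in state ``h`` yields six records
    (one per permitted destination ``j``) with ``entry_day=a``,
    ``exit_day=b`` and ``event=1`` only on the destination actually
    entered at ``b`` (all zero when the episode ends by censoring).
    Repeat visits to ``h`` yield repeat records; the shared time scale is
    days since follow-up start (clock forward, late entry at ``a``).
    """
    need = {"follow_up_id", "exposure_level"}
    if not need <= set(baseline.columns):
        raise EventHistoryError("baseline must carry follow_up_id and exposure_level")
    epi = episodes.sort_values(["follow_up_id", "start_day"]).reset_index(drop=True)
    nxt_state = epi.groupby("follow_up_id")["state"].shift(-1)

    bad = epi["state"].map(is_absorbing) & nxt_state.notna()
    if bad.any():
        raise EventHistoryError(
            f"{int(bad.sum())} absorbing episode(s) followed by a later episode"
        )
    epi = epi[epi["state"].map(is_recurrent)].copy()
    epi["next_state"] = nxt_state[epi.index]
    epi = epi[epi["start_day"] < epi["end_day"]]

    cols = baseline[["follow_up_id", "exposure_level"]].copy()
    cols["weight"] = (
        baseline["combined_weight"] if "combined_weight" in baseline.columns else 1.0
    )
    epi = epi.merge(cols, on="follow_up_id", how="left", validate="many_to_one")

    frames = []
    for h, dests in _DESTINATIONS.items():
        sub = epi[epi["state"] == h]
        if not len(sub):
            continue
        for j in dests:
            rec = pd.DataFrame(
                {
                    "follow_up_id": sub["follow_up_id"].to_numpy(),
                    "from_state": h,
                    "to_state": j,
                    "entry_day": sub["start_day"].to_numpy(),
                    "exit_day": sub["end_day"].to_numpy(),
                    "event": (sub["next_state"] == j).astype(int).to_numpy(),
                    "exposure_level": sub["exposure_level"].to_numpy(),
                    "weight": sub["weight"].to_numpy(),
                }
            )
            frames.append(rec)
    out = pd.concat(frames, ignore_index=True)
    unknown = ~epi["next_state"].isna() & ~epi["next_state"].isin(STATES)
    if unknown.any():
        raise EventHistoryError("episode transitions into an unknown state")
    logger.info(
        "built %d transition records (%d events) from %d recurrent episodes",
        len(out), int(out["event"].sum()), len(epi),
    )
    return out
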