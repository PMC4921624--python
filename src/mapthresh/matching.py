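"""Case identification and 1:m risk-set sampling of matched controls.

Cases are subjects whose first CVD hospitalisation falls inside the study
window; each case's event time becomes the index date of its matched set.
Controls are sampled uniformly without replacement from the case's risk set:
subjects of the same sex and practice, within an age caliper, still
event-free at the index date.  Risk-set semantics mean a subject may serve
as a control for several cases and a later case may appear as an earlier
control — this is what makes the conditional-logistic odds ratio estimate
the incidence rate ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("mapthresh")

__all__ = ["MatchedSet", "identify_cases", "risk_set_sample", "matched_frame"]


@dataclass
class MatchedSet:
    """One risk set: a case, its sampled controls, and the shared index date."""

    set_id: int
    case_id: int
    control_ids: list[int]
    index_date: float


def identify_cases(cohort: pd.DataFrame, window_start: float = 0.0,
                   window_end: float = 730.0) -> pd.DataFrame:
    """Subjects whose first event time falls in (window_start, window_end].

    Returns a frame with ``subject_id`` and ``index_date`` (the event time).
    Setting ``window_start=90`` reproduces the early-admission exclusion
    (cases within the first three months dropped).
    """
    if not window_start < window_end:
        raise ValueError("window_start must precede window_end")
    ev = cohort["event"].astype(bool).to_numpy()
    t = cohort["event_time"].to_numpy(dtype=float)
    keep = ev & (t > window_start) & (t <= window_end)
    return pd.DataFrame(
        {"subject_id": cohort.loc[keep, "subject_id"].to_numpy(),
         "index_date": t[keep]}
    )


def risk_set_sample(
    cohort: pd.DataFrame,
    cases: pd.DataFrame,
    ratio: int = 5,
    age_caliper: float = 2.0,
    seed: int | np.random.Generator = 0,
    min_controls: int = 1,
) -> tuple[list[MatchedSet], dict]:
    """Sample up to ``ratio`` matched controls per case by risk-set sampling.

    Eligible controls share the case's sex and practice, are within
    ``age_caliper`` years of age, and have no event strictly before the
    case's index date (event-free subjects and later cases both qualify; the
    case itself never does).  Sampling is uniform without replacement within
    a set and independent across sets.  Sets with fewer than ``min_controls``
    eligible controls are dropped and counted in the match-quality report.
    """
    if ratio < 1:
        raise ValueError("control ratio must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    sid = cohort["subject_id"].to_numpy()
    age = cohort["age"].to_numpy(dtype=float)
    ev = cohort["event"].astype(bool).to_numpy()
    t = cohort["event_time"].to_numpy(dtype=float)
    pos_of = {int(s): i for i, s in enumerate(sid)}

    # candidate pools keyed by (sex, practice); .indices gives positional rows
    pools: dict[tuple, np.ndarray] = {
        key: np.asarray(val)
        for key, val in cohort.groupby(["sex", "practice_id"], sort=False).indices.items()
    }

    sets: list[MatchedSet] = []
    dropped = 0
    under_filled = 0
    n_controls_total = 0
    for set_id, row in enumerate(cases.itertuples(index=False)):
        cpos = pos_of[int(row.subject_id)]
        index_date = float(row.index_date)
        pool = pools.get((cohort["sex"].iat[cpos], cohort["practice_id"].iat[cpos]))
        if pool is None:
            dropped += 1
            continue
        cand = pool[pool != cpos]
        cand = cand[np.abs(age[cand] - age[cpos]) <= age_caliper]
        cand = cand[~ev[cand] | (t[cand] > index_date)]  # still at risk at the index date
        if cand.size < min_controls:
            dropped += 1
            continue
        k = min(ratio, cand.size)
        chosen = rng.choice(cand, size=k, replace=False)
        if k < ratio:
            under_filled += 1
        n_controls_total += k
        sets.append(
            MatchedSet(
                set_id=set_id,
                case_id=int(row.subject_id),
                control_ids=[int(sid[c]) for c in chosen],
                index_date=index_date,
            )
        )

    report = {
        "n_cases": int(len(cases)),
        "sets_formed": len(sets),
        "sets_dropped": dropped,
        "sets_under_filled": under_filled,
        "controls_selected": n_controls_total,
        "achieved_ratio": (n_controls_total / len(sets)) if sets else float("nan"),
        "target_ratio": ratio,
        "age_caliper": age_caliper,
    }
    if dropped:
        logger.info("risk-set sampling dropped %d/%d sets with < %d eligible controls",
                    dropped, len(cases), min_controls)
    return sets, report


def matched_frame(cohort: pd.DataFrame, sets: list[MatchedSet]) -> pd.DataFrame:
    """Long matched dataset: one row per set member with covariates at index date.

    Columns: ``set_id``, ``is_case``, ``index_date`` plus all cohort columns.
    """
    lookup = cohort.set_index("subject_id")
    records = []
    for s in sets:
        for sid, is_case in [(s.case_id, 1)] + [(c, 0) for c in s.control_ids]:
            rec = lookup.loc[sid].to_dict()
            rec.update({"subject_id": sid, "set_id": s.set_id, "is_case": is_case,
                        "index_date": s.index_date})
            records.append(rec)
    frame = pd.DataFrame.from_records(records)
    front = ["set_id", "is_case", "index_date", "subject_id"]
    return frame[front + [c for c in frame.columns if c not in front]]
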