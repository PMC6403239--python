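"""Stimulus classification and memory scoring.

Elaboration is operationalized at the group level: events are ranked by
their total number of "yes" responses across all participants and split into
four quartiles; the two middle quartiles (high cross-participant
disagreement) are high elaboration, the outer two (near-unanimous answers)
are low elaboration.  Congruity is idiosyncratic: for each participant,
events they answered "yes" to are high congruity, "no" low congruity.

Memory scoring follows the three-question test: recognition (Q1), claimed
action memory (Q2), and the action decision itself (Q3).  Full source memory
requires a correct chain through all three; the corrected source score
subtracts wrong action decisions, compensating for lucky Q3 guesses.
Participants with too few trials in any analysis cell, or with overall
source memory below 10%, are excluded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "rank_events",
    "classify_elaboration",
    "classify_congruity",
    "score_memory",
    "filter_participants",
    "compare_conditions",
]

#: analysis cells of the MemoryScores table: (dimension, level)
CELLS = [
    ("elaboration", "high"),
    ("elaboration", "low"),
    ("congruity", "high"),
    ("congruity", "low"),
    ("all", "all"),
]


def rank_events(responses: pd.DataFrame) -> pd.DataFrame:
    """Rank events ascending by total yes-count (ties broken by event id).

    Returns a frame with columns ``event_id, yes_count, rank`` (rank 1 =
    fewest yes responses).
    """
    if len(responses) == 0:
        raise ValueError("empty response table")
    counts = (
        responses.assign(yes=lambda d: (d["response"] == "yes").astype(int))
        .groupby("event_id", sort=True)["yes"]
        .sum()
        .reset_index()
        .rename(columns={"yes": "yes_count"})
    )
    counts = counts.sort_values(["yes_count", "event_id"], kind="mergesort")
    counts["rank"] = np.arange(1, len(counts) + 1)
    return counts.reset_index(drop=True)


def classify_elaboration(ranked: pd.DataFrame) -> pd.DataFrame:
    """Quartile-split ranked events into elaboration categories.

    Bottom quartile -> category "1" (near-unanimous "no"), top quartile ->
    category "3" (near-unanimous "yes"), the two middle quartiles ->
    categories "2a"/"2b".  Level is "high" for the middle categories, "low"
    for the outer ones.  Quartile boundaries sit at rank positions
    ``floor(E/4)``; ties at a boundary are resolved by rank position, not by
    yes-count.
    """
    E = len(ranked)
    if E < 8:
        raise ValueError("need at least 8 events to form quartiles")
    q = E // 4
    half = E // 2
    rank = ranked["rank"].to_numpy()
    category = np.where(
        rank <= q, "1", np.where(rank <= half, "2a", np.where(rank <= E - q, "2b", "3"))
    )
    level = np.where((category == "2a") | (category == "2b"), "high", "low")
    return pd.DataFrame(
        {"event_id": ranked["event_id"], "category": category, "level": level}
    )


def classify_congruity(responses: pd.DataFrame) -> pd.DataFrame:
    """Per-participant congruity labels: "yes" -> high, "no" -> low.

    Missing responses (NaN) are labeled "absent" and excluded from condition
    counts downstream.
    """
    resp = responses["response"]
    level = np.where(resp == "yes", "high", np.where(resp == "no", "low", "absent"))
    return pd.DataFrame(
        {
            "participant_id": responses["participant_id"],
            "event_id": responses["event_id"],
            "level": level,
        }
    )


def _dprime(hits: int, n_hit_trials: int, fas: int, n_fa_trials: int) -> float:
    """Signal-detection d' with extreme rates clipped to [1/2n, 1 - 1/2n]."""
    if n_hit_trials == 0 or n_fa_trials == 0:
        return np.nan
    h = np.clip(hits / n_hit_trials, 1 / (2 * n_hit_trials), 1 - 1 / (2 * n_hit_trials))
    f = np.clip(fas / n_fa_trials, 1 / (2 * n_fa_trials), 1 - 1 / (2 * n_fa_trials))
    return float(stats.norm.ppf(h) - stats.norm.ppf(f))


def score_memory(
    outcomes: pd.DataFrame,
    elaboration: pd.DataFrame,
    congruity: pd.DataFrame,
) -> pd.DataFrame:
    """Per-participant, per-cell memory scores.

    For every participant and analysis cell (high/low elaboration, high/low
    congruity, and "all"):

    - ``source_pct``: percent of the cell's encoded events recognized with
      full source memory (Q1 yes, Q2 yes, Q3 correct);
    - ``corrected_source_pct``: source hits minus wrong Q3 decisions, as a
      percent, floored at 0;
    - ``recognition_hit_rate``: proportion with Q1 yes;
    - ``false_alarm_rate``: per-participant Q1 yes-rate on foils (cell
      independent);
    - ``d_prime``: Phi^-1(hit rate) - Phi^-1(FA rate), rates clipped to
      [1/(2n), 1-1/(2n)].

    Cells with zero trials get NaN scores and ``n_trials`` 0 (the
    participant then becomes excludable downstream).
    """
    old = outcomes[outcomes["old"]].copy()
    foils = outcomes[~outcomes["old"]]
    elab_level = dict(zip(elaboration["event_id"], elaboration["level"]))
    old["elab"] = old["item_id"].map(elab_level)
    congr_key = congruity.set_index(["participant_id", "event_id"])["level"]
    old["congr"] = congr_key.reindex(
        pd.MultiIndex.from_frame(old[["participant_id", "item_id"]])
    ).to_numpy()
    old["source_hit"] = (
        (old["q1"] == "yes") & (old["q2"] == "yes") & (old["q3"] == "correct")
    )
    old["q3_wrong"] = old["q3"] == "wrong"
    old["rec_hit"] = old["q1"] == "yes"

    fa = (
        foils.assign(fa=lambda d: (d["q1"] == "yes").astype(int))
        .groupby("participant_id")
        .agg(n_foils=("fa", "size"), n_fa=("fa", "sum"))
    )

    rows = []
    for pid, g in old.groupby("participant_id"):
        n_foils = int(fa.loc[pid, "n_foils"]) if pid in fa.index else 0
        n_fas = int(fa.loc[pid, "n_fa"]) if pid in fa.index else 0
        for dim, level in CELLS:
            if dim == "all":
                cell = g
            elif dim == "elaboration":
                cell = g[g["elab"] == level]
            else:
                cell = g[g["congr"] == level]
            n = len(cell)
            hits = int(cell["source_hit"].sum())
            wrong = int(cell["q3_wrong"].sum())
            rec = int(cell["rec_hit"].sum())
            rows.append(
                {
                    "participant_id": pid,
                    "dimension": dim,
                    "level": level,
                    "n_trials": n,
                    "n_source_hits": hits,
                    "n_q3_wrong": wrong,
                    "source_pct": 100 * hits / n if n else np.nan,
                    "corrected_source_pct": 100 * max(hits - wrong, 0) / n if n else np.nan,
                    "recognition_hit_rate": rec / n if n else np.nan,
                    "false_alarm_rate": n_fas / n_foils if n_foils else np.nan,
                    "d_prime": _dprime(rec, n, n_fas, n_foils),
                }
            )
    return pd.DataFrame(rows)


def filter_participants(
    scores: pd.DataFrame,
    min_trials: int = 10,
    min_source_frac: float = 0.10,
) -> tuple[list, list[dict]]:
    """Apply the trial-count and overall-source-memory exclusion rules.

    A participant is excluded if any condition cell used by the contrasts
    (high/low elaboration/congruity, split into subsequently remembered-with-
    source vs not) holds fewer than ``min_trials`` trials, or if their
    overall full-source-memory rate is below ``min_source_frac``.

    Returns ``(included_participant_ids, exclusion_log)`` where each log
    entry states which rule fired.
    """
    included, log = [], []
    for pid, g in scores.groupby("participant_id"):
        reasons = []
        overall = g[(g["dimension"] == "all")]
        src = float(overall["source_pct"].iloc[0]) if len(overall) else np.nan
        if not np.isfinite(src) or src < 100 * min_source_frac:
            reasons.append(
                f"overall source memory {src:.1f}% below {100 * min_source_frac:.0f}%"
            )
        cond = g[g["dimension"] != "all"]
        for _, row in cond.iterrows():
            remembered = row["n_source_hits"]
            forgotten = row["n_trials"] - row["n_source_hits"]
            for label, count in (("remembered", remembered), ("forgotten", forgotten)):
                if count < min_trials:
                    reasons.append(
                        f"{row['dimension']}={row['level']} {label}: "
                        f"{int(count)} trials < {min_trials}"
                    )
        if reasons:
            log.append({"participant_id": pid, "excluded": True, "reasons": reasons})
        else:
            included.append(pid)
            log.append({"participant_id": pid, "excluded": False, "reasons": []})
    return included, log


def compare_conditions(
    scores: pd.DataFrame,
    measure: str = "corrected_source_pct",
    pairing: tuple[str, str, str] = ("elaboration", "high", "low"),
    n_planned: int = 4,
) -> dict:
    """Paired t-test between two levels of a condition dimension.

    ``pairing = (dimension, level_a, level_b)``.  Returns the t statistic,
    degrees of freedom, two-sided p, per-condition means/SDs, and the
    Bonferroni-adjusted alpha for ``n_planned`` planned comparisons.
    """
    dim, la, lb = pairing
    wide = scores[scores["dimension"] == dim].pivot(
        index="participant_id", columns="level", values=measure
    )
    wide = wide[[la, lb]].dropna()
    if len(wide) < 3:
        raise ValueError("need at least 3 participants with both conditions")
    a, b = wide[la].to_numpy(float), wide[lb].to_numpy(float)
    d = a - b
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0:
        t = 0.0 if d.mean() == 0 else np.inf * np.sign(d.mean())
        p = 1.0 if d.mean() == 0 else 0.0
    else:
        t = d.mean() / (sd / np.sqrt(n))
        p = 2 * stats.t.sf(abs(t), n - 1)
    return {
        "measure": measure,
        "pairing": pairing,
        "t": float(t),
        "df": n - 1,
        "p": float(p),
        "n": n,
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "sd_a": float(a.std(ddof=1)),
        "sd_b": float(b.std(ddof=1)),
        "bonferroni_alpha": 0.05 / n_planned,
    }
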