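"""Questionnaire shift scores for basic emotions and SAM dimensions.

Participants rate six basic emotions (sadness, happiness, fear, anger,
surprise, disgust) and the three Self-Assessment-Manikin dimensions
(valence, arousal, dominance) on 9-point scales, once for the roaming
baseline and once per stimulus scenario.  The indicator of a stimulus's
emotional impact is the shift relative to baseline:

    Δx_a = x_a − x_r,   Δx_s = x_s − x_r,   Δx_f = x_f − x_r.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

log = logging.getLogger(__name__)

BASIC_EMOTIONS = ("sadness", "happiness", "fear", "anger", "surprise", "disgust")
SAM_DIMENSIONS = ("valence", "arousal", "dominance")
ALL_TERMS = BASIC_EMOTIONS + SAM_DIMENSIONS

SCALE_MIN, SCALE_MAX = 1, 9
EMOTION_SCENARIOS = ("Roaming", "Alarm", "Smoke", "Flame")


class EmotionError(ValueError):
    pass


def _check_score(term: str, scenario: str, score: int) -> int:
    s = int(score)
    if s != score or not SCALE_MIN <= s <= SCALE_MAX:
        raise EmotionError(
            f"score {score!r} for {term}/{scenario} outside the "
            f"{SCALE_MIN}..{SCALE_MAX} scale"
        )
    return s


@dataclass(frozen=True)
class EmotionScores:
    """One participant's 9-point ratings: term → scenario → score."""

    participant: str
    scores: dict  # {term: {scenario: int}}

    def __post_init__(self) -> None:
        for term, by_scen in self.scores.items():
            if term not in ALL_TERMS:
                raise EmotionError(f"unknown questionnaire term {term!r}")
            for scen, score in by_scen.items():
                if scen not in EMOTION_SCENARIOS:
                    raise EmotionError(f"unknown scenario {scen!r}")
                _check_score(term, scen, score)


def emotion_shifts(scores: EmotionScores) -> dict:
    """Per-term baseline-relative shifts (ΔAlarm, ΔSmoke, ΔFlame).

    Exact integer differences in −8..8.  Terms lacking a Roaming baseline or
    a scenario score are excluded (listwise per term) and logged.
    """
    out: dict = {}
    for term, by_scen in scores.scores.items():
        if "Roaming" not in by_scen:
            log.warning(
                "participant %s term %s has no Roaming baseline; skipped",
                scores.participant, term,
            )
            continue
        missing = [s for s in ("Alarm", "Smoke", "Flame") if s not in by_scen]
        if missing:
            log.warning(
                "participant %s term %s missing %s; skipped",
                scores.participant, term, missing,
            )
            continue
        base = by_scen["Roaming"]
        out[term] = tuple(by_scen[s] - base for s in ("Alarm", "Smoke", "Flame"))
    return out


def shift_table(scores_long: pd.DataFrame) -> pd.DataFrame:
    """Shift scores for a long-form cohort table.

    Parameters
    ----------
    scores_long : DataFrame
        Columns ``participant, term, scenario, score`` with one row per
        participant × term × scenario (Roaming, Alarm, Smoke, Flame).

    Returns
    -------
    DataFrame
        Columns ``participant, scenario, metric, value`` where metric is
        ``shift_<term>`` — ready to concatenate into the cohort metric table.
    """
    required = {"participant", "term", "scenario", "score"}
    if not required <= set(scores_long.columns):
        raise EmotionError(f"scores table must have columns {sorted(required)}")
    bad = ~scores_long["score"].between(SCALE_MIN, SCALE_MAX)
    if bad.any():
        raise EmotionError(
            f"{int(bad.sum())} scores outside the {SCALE_MIN}..{SCALE_MAX} scale"
        )
    wide = scores_long.pivot_table(
        index=["participant", "term"], columns="scenario", values="score",
        aggfunc="first",
    )
    rows = []
    for (pid, term), r in wide.iterrows():
        if pd.isna(r.get("Roaming")):
            log.warning("participant %s term %s has no Roaming baseline", pid, term)
            continue
        for scen in ("Alarm", "Smoke", "Flame"):
            if pd.isna(r.get(scen)):
                log.warning("participant %s term %s missing %s", pid, term, scen)
                continue
            rows.append(
                {
                    "participant": pid,
                    "scenario": scen,
                    "metric": f"shift_{term}",
                    "value": float(r[scen] - r["Roaming"]),
                }
            )
    return pd.DataFrame(rows, columns=["participant", "scenario", "metric", "value"])
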