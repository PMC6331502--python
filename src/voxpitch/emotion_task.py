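"""Scoring of the 6-alternative forced-choice vocal-emotion recognition test.

The canonical session presents 120 two-syllable words, each spoken in one of
six expressions (happiness, sadness, fear, anger, disgust, neutral), 20 per
emotion, half by a female and half by a male speaker.  Listeners choose one
of the six labels per trial; chance is 1/6.  Scoring yields per-emotion and
total percent correct and a 6 x 6 confusion matrix (rows are presented
emotions and sum to 100%).  Stimulus-level covariates (independent-rater
emotional-intensity scores and F0 frequency range) can be quartile-binned
into four levels for the level x group analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats_suite import AnovaResult, mixed_anova

__all__ = [
    "EMOTIONS", "SPEAKERS", "N_TRIALS", "TRIALS_PER_EMOTION",
    "TRIALS_PER_EMOTION_SPEAKER", "CHANCE_ACCURACY",
    "DesignReport", "EmotionScore",
    "validate_design", "score_session", "bin_levels", "level_accuracy",
    "level_anova",
]

EMOTIONS = ("happiness", "sadness", "fear", "anger", "disgust", "neutral")
SPEAKERS = ("female", "male")
N_TRIALS = 120
TRIALS_PER_EMOTION = 20
TRIALS_PER_EMOTION_SPEAKER = 10
CHANCE_ACCURACY = 100.0 / len(EMOTIONS)  # 16.67% under random responding

LEVEL_NAMES = ("very low", "low", "high", "very high")


@dataclass(frozen=True)
class DesignReport:
    ok: bool
    n_trials: int
    violations: tuple[str, ...]


@dataclass(frozen=True)
class EmotionScore:
    per_emotion_accuracy: dict[str, float]  # percent correct per emotion
    total_accuracy: float                   # percent correct over all trials
    confusion: pd.DataFrame                 # rows = presented, cols = chosen, %


def _check_columns(trials: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")


def validate_design(trials: pd.DataFrame) -> DesignReport:
    """Check the 120-trial, 20-per-emotion, 10-per-speaker balanced design."""
    _check_columns(trials, ["true_emotion", "response_emotion", "speaker"])
    violations: list[str] = []
    if len(trials) != N_TRIALS:
        violations.append(f"expected {N_TRIALS} trials, found {len(trials)}")
    bad_true = set(trials["true_emotion"]) - set(EMOTIONS)
    bad_resp = set(trials["response_emotion"]) - set(EMOTIONS)
    if bad_true:
        violations.append(f"unknown presented emotions: {sorted(bad_true)}")
    if bad_resp:
        violations.append(f"unknown response emotions: {sorted(bad_resp)}")
    counts = trials["true_emotion"].value_counts()
    for emotion in EMOTIONS:
        if counts.get(emotion, 0) != TRIALS_PER_EMOTION:
            violations.append(
                f"{emotion}: {counts.get(emotion, 0)} trials, "
                f"expected {TRIALS_PER_EMOTION}")
    cell = trials.groupby(["true_emotion", "speaker"]).size()
    for emotion in EMOTIONS:
        for speaker in SPEAKERS:
            if cell.get((emotion, speaker), 0) != TRIALS_PER_EMOTION_SPEAKER:
                violations.append(
                    f"{emotion}/{speaker}: {cell.get((emotion, speaker), 0)} "
                    f"trials, expected {TRIALS_PER_EMOTION_SPEAKER}")
    return DesignReport(not violations, len(trials), tuple(violations))


def score_session(trials: pd.DataFrame, require_valid: bool = True) -> EmotionScore:
    """Per-emotion accuracy, total accuracy and the response confusion matrix."""
    if require_valid:
        report = validate_design(trials)
        if not report.ok:
            raise ValueError("invalid session design: "
                             + "; ".join(report.violations))
    else:
        _check_columns(trials, ["true_emotion", "response_emotion"])
    confusion = pd.crosstab(trials["true_emotion"], trials["response_emotion"])
    confusion = confusion.reindex(index=EMOTIONS, columns=EMOTIONS, fill_value=0)
    row_totals = confusion.sum(axis=1)
    if (row_totals == 0).any():
        raise ValueError("every emotion must have at least one trial to score")
    confusion_pct = confusion.div(row_totals, axis=0) * 100.0
    per_emotion = {e: float(confusion_pct.loc[e, e]) for e in EMOTIONS}
    total = float((trials["true_emotion"] == trials["response_emotion"]).mean()) * 100.0
    return EmotionScore(per_emotion, total, confusion_pct)


def bin_levels(trials: pd.DataFrame, variable: str, n_levels: int = 4) -> pd.Series:
    """Assign each trial to a quartile level of a stimulus covariate.

    Trials are ranked by ``variable`` with ties broken by stable position in
    the table (stimulus-id order), then cut into ``n_levels`` equal-rank bins
    labelled very low .. very high.
    """
    _check_columns(trials, [variable])
    values = trials[variable].to_numpy(dtype=float)
    if np.ptp(values) == 0.0:
        raise ValueError(f"all values of {variable!r} are equal; "
                         "level binning is degenerate")
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values), dtype=int)
    ranks[order] = np.arange(len(values))
    level_idx = (ranks * n_levels) // len(values)
    names = LEVEL_NAMES if n_levels == 4 else tuple(
        f"level{i + 1}" for i in range(n_levels))
    return pd.Series(pd.Categorical.from_codes(level_idx, list(names),
                                               ordered=True),
                     index=trials.index, name=f"{variable}_level")


def level_accuracy(trials: pd.DataFrame, levels: pd.Series) -> pd.Series:
    """Mean percent correct per level for one participant's session."""
    correct = (trials["true_emotion"] == trials["response_emotion"]).astype(float)
    return correct.groupby(levels, observed=False).mean() * 100.0


def level_anova(level_means: pd.DataFrame | np.ndarray,
                groups) -> dict[str, AnovaResult]:
    """Group x level mixed ANOVA on the participants-by-levels accuracy table."""
    return mixed_anova(np.asarray(level_means, dtype=float), groups)
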