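"""Synthetic matched-pair cohorts with the moment structure the analyses assume.

The generator emulates a matched two-group design (default 16 pairs): each
comparison participant is matched to one ASD participant on gender,
handedness, age (difference <= 3 years) and full-scale IQ (difference <= 15
points).  Participant-level scores — per-emotion recognition accuracy,
vocal-pitch and vocal-timbre JNDs, non-vocal pitch accuracy, AQ and (ASD
only) ADOS communication — are drawn from a Gaussian copula:

* each marginal is moment-matched exactly to the target group mean/SD
  (closed-form lognormal for positive JND-like scores; numerically solved
  logit-normal for bounded percentage/questionnaire scores), so generated
  samples are automatically on the legal scale without clamping;
* latent correlations are adjusted (NORTA-style, Gauss-Hermite quadrature)
  so that *observed-scale* Pearson correlations hit their targets despite the
  nonlinear marginal transforms;
* the six per-emotion accuracies share a common within-group correlation
  solved so that the variance of their mean reproduces the target SD of the
  total score, and each carries an equal share of the targeted
  total-score-with-X correlations (emotion-pitchJND, emotion-AQ,
  emotion-ADOS).

Only the published group moments and pairwise correlations constrain the
generator; everything else (copula shape, equicorrelation, uniform error
kernel) is an explicit modelling assumption, not an inference about any real
participant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from . import reference_values as ref
from .emotion_task import EMOTIONS, SPEAKERS, TRIALS_PER_EMOTION_SPEAKER
from .observer_model import Observer, observer_with_p75

__all__ = [
    "CohortSpec", "DEFAULT_COHORT_SPEC", "generate_cohort", "validate_cohort",
    "generate_emotion_session", "default_stimulus_attributes",
    "generate_staircase_observers", "cohort_columns",
]

_GH_NODES = 48


@lru_cache(maxsize=None)
def _gh() -> tuple[np.ndarray, np.ndarray]:
    nodes, weights = np.polynomial.hermite_e.hermegauss(_GH_NODES)
    return nodes, weights / math.sqrt(2.0 * math.pi)


# --------------------------------------------------------------- marginals ----

@dataclass(frozen=True)
class _Marginal:
    """z -> x transform with exactly matched mean/SD."""
    kind: str       # "lognormal" or "logitnormal"
    mean: float
    sd: float
    scale: float    # upper bound for logit-normal marginals
    mu: float
    sigma: float

    def transform(self, z: np.ndarray) -> np.ndarray:
        if self.kind == "lognormal":
            return np.exp(self.mu + self.sigma * z)
        return self.scale * expit(self.mu + self.sigma * z)


@lru_cache(maxsize=None)
def _lognormal_marginal(mean: float, sd: float) -> _Marginal:
    if mean <= 0 or sd <= 0:
        raise ValueError("lognormal marginal needs positive mean and SD")
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return _Marginal("lognormal", mean, sd, math.inf, mu, math.sqrt(sigma2))


@lru_cache(maxsize=None)
def _logitnormal_marginal(mean: float, sd: float, scale: float) -> _Marginal:
    if not (0.0 < mean < scale) or sd <= 0:
        raise ValueError("logit-normal marginal needs 0 < mean < scale, sd > 0")
    nodes, weights = _gh()
    p = mean / scale
    sd_unit = sd / scale
    if sd_unit >= math.sqrt(p * (1.0 - p)):
        raise ValueError(
            f"sd={sd} exceeds the maximum for a [0, {scale}] variable "
            f"with mean {mean}")

    def moments(mu, sigma):
        x = expit(mu + sigma * nodes)
        m1 = float(weights @ x)
        m2 = float(weights @ (x * x))
        return m1, math.sqrt(max(m2 - m1 * m1, 1e-300))

    def mu_for_mean(sigma):
        # E[X] is strictly increasing in mu at fixed sigma
        lim = 50.0 + 15.0 * sigma
        return brentq(lambda mu: moments(mu, sigma)[0] - p,
                      -lim, lim, xtol=1e-13)

    def sd_gap(sigma):
        # SD (with the mean re-matched) is strictly increasing in sigma
        return moments(mu_for_mean(sigma), sigma)[1] - sd_unit

    sigma = brentq(sd_gap, 1e-6, 40.0, xtol=1e-12)
    mu = mu_for_mean(sigma)
    m1, s1 = moments(mu, sigma)
    if abs(m1 - p) > 1e-8 or abs(s1 - sd_unit) > 1e-8:
        raise RuntimeError(
            f"could not moment-match a logit-normal to mean={mean}, sd={sd} "
            f"on [0, {scale}]")
    return _Marginal("logitnormal", mean, sd, scale, float(mu), float(sigma))


def _observed_corr(m1: _Marginal, m2: _Marginal, rho: float) -> float:
    """Observed-scale Pearson correlation induced by latent correlation rho."""
    nodes, weights = _gh()
    z1 = nodes[:, None]
    z2 = rho * nodes[:, None] + math.sqrt(max(1.0 - rho * rho, 0.0)) * nodes[None, :]
    x1 = m1.transform(np.broadcast_to(z1, z2.shape))
    x2 = m2.transform(z2)
    e12 = float(weights @ (x1 * x2) @ weights)
    return (e12 - m1.mean * m2.mean) / (m1.sd * m2.sd)


@lru_cache(maxsize=None)
def _latent_corr(m1: _Marginal, m2: _Marginal, target: float) -> float:
    """Latent Gaussian correlation producing the target observed correlation."""
    if target == 0.0:
        return 0.0
    lo, hi = -0.999, 0.999
    f = lambda rho: _observed_corr(m1, m2, rho) - target
    flo, fhi = f(lo), f(hi)
    if flo > 0 or fhi < 0:
        raise ValueError(
            f"target correlation {target} unreachable for these marginals")
    return float(brentq(f, lo, hi, xtol=1e-10))


# ------------------------------------------------------------------- spec ----

def _group_defaults(group: str) -> dict:
    spec = {
        "emotion": {e: ref.EMOTION_ACCURACY[e][group] for e in EMOTIONS},
        "emotion_total": ref.EMOTION_TOTAL[group],
        "pitch_jnd": ref.PITCH_JND[group],
        "timbre_jnd": ref.TIMBRE_JND[group],
        "nonvocal_pitch_pct": ref.NONVOCAL_PITCH[group],
        "aq": ref.AQ[group],
    }
    if group == "asd":
        spec["ados_comm"] = ref.ADOS_COMMUNICATION["asd"]
    return spec


def _default_correlations() -> dict:
    c = ref.CORRELATIONS
    return {
        "comparison": {
            "pitch_jnd": c[("emotion_total", "pitch_jnd", "comparison",
                            "pearson")]["r"],            # -.554
            "aq": c[("emotion_total", "aq", "comparison")]["r"],   # -.501
        },
        "asd": {
            "pitch_jnd": c[("emotion_total", "pitch_jnd", "asd")]["r"],  # -.346
            "aq": c[("emotion_total", "aq", "asd")]["r"],                # -.197
            "ados_comm": c[("emotion_total", "ados_comm", "asd")]["r"],  # -.672
        },
    }


@dataclass(frozen=True)
class CohortSpec:
    """Target moments and correlation structure for a matched-pair cohort."""

    n_pairs: int = 16
    groups: dict = field(default_factory=lambda: {
        "asd": _group_defaults("asd"),
        "comparison": _group_defaults("comparison")})
    # group -> {variable: target Pearson correlation with the emotion total}
    emotion_correlations: dict = field(default_factory=_default_correlations)
    age_mean_sd: tuple = (ref.AGE["comparison"][0], ref.AGE["comparison"][1])
    iq_mean_sd: tuple = (ref.FULLSCALE_IQ["comparison"][0],
                         ref.FULLSCALE_IQ["comparison"][1])
    age_tolerance: float = ref.AGE_MATCH_TOLERANCE_YEARS
    iq_tolerance: float = ref.IQ_MATCH_TOLERANCE_POINTS
    male_fraction: float = ref.GENDER_COUNTS["male"] / 16
    right_handed_fraction: float = ref.HANDEDNESS_COUNTS["right"] / 16

    def __post_init__(self):
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        for group, spec in self.groups.items():
            for key, value in spec.items():
                entries = value.values() if key == "emotion" else [value]
                for m, s in entries:
                    if s < 0:
                        raise ValueError(f"{group}/{key}: negative SD")


DEFAULT_COHORT_SPEC = CohortSpec()

_PCT_VARS = ("nonvocal_pitch_pct",)
_POSITIVE_VARS = ("pitch_jnd", "timbre_jnd", "ados_comm")


def _marginal_for(var: str, mean: float, sd: float) -> _Marginal:
    if var in _POSITIVE_VARS:
        return _lognormal_marginal(mean, sd)
    if var == "aq":
        return _logitnormal_marginal(mean, sd, 50.0)
    return _logitnormal_marginal(mean, sd, 100.0)  # percentage scales


def _group_model(spec: CohortSpec, group: str):
    """Variables, marginals and the latent correlation matrix for one group."""
    gspec = spec.groups[group]
    emo_ms = [gspec["emotion"][e] for e in EMOTIONS]
    s_e = np.array([s for _, s in emo_ms])
    total_sd = gspec["emotion_total"][1]
    sum_s, sum_s2 = float(s_e.sum()), float((s_e ** 2).sum())
    cross = sum_s ** 2 - sum_s2
    # Common inter-emotion correlation that reproduces the total-score SD:
    # var(mean of 6) = (sum s^2 + rho * sum_{e != f} s_e s_f) / 36.
    rho_emotion = (36.0 * total_sd ** 2 - sum_s2) / cross
    if not (-1.0 / (len(EMOTIONS) - 1) < rho_emotion < 1.0):
        raise ValueError(
            f"{group}: total-score SD {total_sd} infeasible for the "
            f"per-emotion SDs (implied inter-emotion r={rho_emotion:.3f})")
    extra = [v for v in ("pitch_jnd", "timbre_jnd", "nonvocal_pitch_pct",
                         "aq", "ados_comm") if v in gspec]
    variables = [f"acc_{e}" for e in EMOTIONS] + extra
    marginals = (
        [_logitnormal_marginal(m, s, 100.0) for m, s in emo_ms]
        + [_marginal_for(v, *gspec[v]) for v in extra])

    k = len(variables)
    target = np.eye(k)
    ne = len(EMOTIONS)
    for i in range(ne):
        for j in range(i + 1, ne):
            target[i, j] = target[j, i] = rho_emotion
    corr_spec = spec.emotion_correlations.get(group, {})
    for v, r_total in corr_spec.items():
        if v not in extra:
            continue
        jdx = variables.index(v)
        # equal per-emotion share reproducing corr(total, v) = r_total
        c = r_total * len(EMOTIONS) * total_sd / sum_s
        for i in range(ne):
            target[i, jdx] = target[jdx, i] = c
    if np.linalg.eigvalsh(target).min() < -1e-10:
        raise ValueError(f"{group}: target correlation matrix is not PSD")

    latent = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            if target[i, j] != 0.0:
                latent[i, j] = latent[j, i] = _latent_corr(
                    marginals[i], marginals[j], float(target[i, j]))
    # quadrature round-off can leave a tiny negative eigenvalue
    w, V = np.linalg.eigh(latent)
    if w.min() < 1e-10:
        w = np.clip(w, 1e-8, None)
        latent = V @ np.diag(w) @ V.T
        d = np.sqrt(np.diag(latent))
        latent = latent / np.outer(d, d)
    return variables, marginals, latent


def generate_cohort(spec: CohortSpec = DEFAULT_COHORT_SPEC,
                    seed=None) -> pd.DataFrame:
    """Draw one matched-pair cohort as a tidy participant table."""
    rng = np.random.default_rng(seed)
    n = spec.n_pairs
    frames = []
    # pair-level matching variables, shared construction for both members
    age_centre = np.clip(rng.normal(spec.age_mean_sd[0], spec.age_mean_sd[1], n),
                         19.5, 60.0)
    iq_centre = np.clip(rng.normal(spec.iq_mean_sd[0], spec.iq_mean_sd[1], n),
                        87.5, 140.0)
    age_off = rng.uniform(0.0, spec.age_tolerance / 2.0 - 0.05, (n, 2))
    iq_off = rng.uniform(0.0, spec.iq_tolerance / 2.0 - 0.5, (n, 2))
    age_sign = rng.choice([-1.0, 1.0], (n, 2))
    iq_sign = rng.choice([-1.0, 1.0], (n, 2))
    n_male = round(spec.male_fraction * n)
    n_right = round(spec.right_handed_fraction * n)
    gender = np.array(["male"] * n_male + ["female"] * (n - n_male))
    handed = np.array(["right"] * n_right + ["left"] * (n - n_right))
    rng.shuffle(gender)
    rng.shuffle(handed)

    for gi, group in enumerate(("asd", "comparison")):
        variables, marginals, latent = _group_model(spec, group)
        L = np.linalg.cholesky(latent)
        z = rng.standard_normal((n, len(variables))) @ L.T
        data = {v: marg.transform(z[:, j])
                for j, (v, marg) in enumerate(zip(variables, marginals))}
        df = pd.DataFrame(data)
        df.insert(0, "id", [f"{group}_{i + 1:03d}" for i in range(n)])
        df.insert(1, "group", group)
        df.insert(2, "pair_id", np.arange(1, n + 1))
        df["age"] = age_centre + age_sign[:, gi] * age_off[:, gi]
        df["gender"] = gender
        df["handedness"] = handed
        df["iq_full"] = iq_centre + iq_sign[:, gi] * iq_off[:, gi]
        df["iq_verbal"] = np.clip(df["iq_full"] + rng.normal(0, 5, n), 70, 150)
        df["iq_performance"] = np.clip(df["iq_full"] + rng.normal(0, 5, n), 70, 150)
        acc_cols = [f"acc_{e}" for e in EMOTIONS]
        df["emotion_total"] = df[acc_cols].mean(axis=1)
        if "ados_comm" not in df.columns:
            df["ados_comm"] = np.nan
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def cohort_columns() -> list[str]:
    return (["id", "group", "pair_id", "age", "gender", "handedness",
             "iq_full", "iq_verbal", "iq_performance", "aq", "ados_comm"]
            + [f"acc_{e}" for e in EMOTIONS]
            + ["emotion_total", "pitch_jnd", "timbre_jnd", "nonvocal_pitch_pct"])


def validate_cohort(cohort: pd.DataFrame,
                    spec: CohortSpec = DEFAULT_COHORT_SPEC) -> list[str]:
    """Constraint check: group sizes, scales, and within-pair matching."""
    problems = []
    for group in ("asd", "comparison"):
        if (cohort["group"] == group).sum() != spec.n_pairs:
            problems.append(f"group {group} does not have n={spec.n_pairs}")
    pct_cols = [f"acc_{e}" for e in EMOTIONS] + ["emotion_total",
                                                 "nonvocal_pitch_pct"]
    for col in pct_cols:
        v = cohort[col]
        if (v < 0).any() or (v > 100).any():
            problems.append(f"{col} outside [0, 100]")
    if (cohort["aq"] < 0).any() or (cohort["aq"] > 50).any():
        problems.append("aq outside [0, 50]")
    for col in ("pitch_jnd", "timbre_jnd"):
        if (cohort[col] <= 0).any():
            problems.append(f"{col} not strictly positive")
    wide = cohort.pivot(index="pair_id", columns="group",
                        values=["age", "iq_full", "gender", "handedness"])
    age_diff = (wide["age"]["asd"] - wide["age"]["comparison"]).abs()
    iq_diff = (wide["iq_full"]["asd"] - wide["iq_full"]["comparison"]).abs()
    if (age_diff > spec.age_tolerance).any():
        problems.append("pair age difference exceeds tolerance")
    if (iq_diff > spec.iq_tolerance).any():
        problems.append("pair IQ difference exceeds tolerance")
    if (wide["gender"]["asd"] != wide["gender"]["comparison"]).any():
        problems.append("pair gender mismatch")
    if (wide["handedness"]["asd"] != wide["handedness"]["comparison"]).any():
        problems.append("pair handedness mismatch")
    return problems


# -------------------------------------------------------------- sessions ----

def default_stimulus_attributes(seed=None) -> pd.DataFrame:
    """Synthetic per-stimulus covariates for one 120-trial session layout.

    Emotional-intensity scores (independent-rater recognition accuracy,
    0-100%) cluster near the expressions that are easy to recognise; the F0
    frequency range (Hz) is larger for high-arousal expressions.  Values are
    illustrative stand-ins with a realistic ordering, not measurements.
    """
    rng = np.random.default_rng(seed)
    intensity_centre = {e: ref.EMOTION_ACCURACY[e]["comparison"][0]
                        for e in EMOTIONS}
    freq_centre = {"happiness": 190.0, "sadness": 80.0, "fear": 210.0,
                   "anger": 170.0, "disgust": 120.0, "neutral": 60.0}
    rows = []
    i = 0
    for emotion in EMOTIONS:
        for speaker in SPEAKERS:
            for _ in range(TRIALS_PER_EMOTION_SPEAKER):
                i += 1
                rows.append({
                    "trial_id": i,
                    "true_emotion": emotion,
                    "speaker": speaker,
                    "intensity_score": float(np.clip(
                        rng.normal(intensity_centre[emotion], 8.0), 30.0, 99.0)),
                    "freq_range": float(np.clip(
                        rng.normal(freq_centre[emotion], 25.0), 20.0, 400.0)),
                })
    return pd.DataFrame(rows)


def generate_emotion_session(profile: dict[str, float], seed=None,
                             stimulus_attributes: pd.DataFrame | None = None,
                             intensity_effect: float = 0.0,
                             freq_range_effect: float = 0.0) -> pd.DataFrame:
    """Simulate one 120-trial 6-AFC session for a participant profile.

    ``profile`` maps each emotion to that participant's expected percent
    correct.  Errors are distributed uniformly over the five wrong labels.
    If stimulus attributes are supplied, per-trial correctness probabilities
    are modulated by the z-scored covariates (``*_effect`` in percentage
    points per SD), so a positive intensity effect yields monotone level
    means in the quartile analysis.
    """
    rng = np.random.default_rng(seed)
    for e in EMOTIONS:
        if not (0.0 <= profile[e] <= 100.0):
            raise ValueError(f"profile accuracy for {e} outside [0, 100]")
    if stimulus_attributes is None:
        stimulus_attributes = default_stimulus_attributes(seed=rng.integers(2 ** 31))
    trials = stimulus_attributes.copy().reset_index(drop=True)
    p = np.array([profile[e] for e in trials["true_emotion"]], dtype=float)
    for col, effect in (("intensity_score", intensity_effect),
                        ("freq_range", freq_range_effect)):
        if effect:
            v = trials[col].to_numpy(dtype=float)
            p = p + effect * (v - v.mean()) / v.std(ddof=0)
    p = np.clip(p / 100.0, 0.0, 1.0)
    correct = rng.random(len(trials)) < p
    responses = []
    for ok, true_e in zip(correct, trials["true_emotion"]):
        if ok:
            responses.append(true_e)
        else:
            wrong = [e for e in EMOTIONS if e != true_e]
            responses.append(wrong[rng.integers(len(wrong))])
    trials["response_emotion"] = responses
    order = rng.permutation(len(trials))  # words are presented in random order
    return trials.iloc[order].reset_index(drop=True)


def generate_staircase_observers(cohort: pd.DataFrame, test: str = "pitch",
                                 slope: float = 8.0,
                                 lapse_rate: float = 0.02) -> dict[str, Observer]:
    """One sigmoid observer per participant whose 75% point equals their JND."""
    col = {"pitch": "pitch_jnd", "timbre": "timbre_jnd"}[test]
    return {row.id: observer_with_p75(getattr(row, col), slope=slope,
                                      lapse_rate=lapse_rate)
            for row in cohort.itertuples()}
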