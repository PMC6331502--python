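"""Parametric simulated observers for two-interval forced-choice discrimination.

An observer maps a nonnegative stimulus difference (cents for the pitch test,
SER-% for the timbre test) to a probability of choosing the manipulated
interval.  The sigmoid observer uses a logistic psychometric function in
log-delta — Weber-like behaviour appropriate for ratio-scaled pitch
differences — with a 2AFC guess rate of 0.5 and a lapse rate:

    P(correct | delta) = 0.5 + (0.5 - lapse/2) * logistic(slope * ln(delta/threshold))

so P(correct | 0) = 0.5 and P(correct | inf) = 1 - lapse/2.  ``threshold`` is
the delta at the psychometric inflection, not the 75% point; use
:func:`threshold_at` (or :func:`observer_with_p75`) for percent-correct
ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["Observer", "p_correct", "respond", "threshold_at",
           "observer_with_p75", "parse_observer"]


@dataclass(frozen=True)
class Observer:
    kind: str  # "sigmoid" or "deterministic_threshold"
    threshold: float
    slope: float = 8.0
    lapse_rate: float = 0.0
    guess_rate: float = 0.5

    def __post_init__(self):
        if self.kind not in ("sigmoid", "deterministic_threshold"):
            raise ValueError(f"unknown observer kind {self.kind!r}")
        if self.threshold <= 0 and self.kind == "sigmoid":
            raise ValueError("sigmoid threshold must be positive")
        if not (0.0 <= self.lapse_rate <= 1.0):
            raise ValueError("lapse_rate must be in [0, 1]")
        if self.slope <= 0:
            raise ValueError("slope must be positive")


def p_correct(observer: Observer, delta: float) -> float:
    """Probability of a correct 2AFC response at stimulus difference ``delta``."""
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    if observer.kind == "deterministic_threshold":
        return 1.0 if delta >= observer.threshold else 0.0
    span = 1.0 - observer.guess_rate - observer.lapse_rate / 2.0
    if delta == 0.0:
        return observer.guess_rate
    z = observer.slope * math.log(delta / observer.threshold)
    psi = 1.0 / (1.0 + math.exp(-z))
    return observer.guess_rate + span * psi


def respond(observer: Observer, delta: float, manipulated_interval: int,
            rng: np.random.Generator) -> int:
    """Simulate one trial: return the interval (1 or 2) the observer chooses."""
    if manipulated_interval not in (1, 2):
        raise ValueError("manipulated_interval must be 1 or 2")
    if rng.random() < p_correct(observer, delta):
        return manipulated_interval
    return 3 - manipulated_interval


def threshold_at(observer: Observer, p: float) -> float:
    """Delta at which ``p_correct`` equals ``p`` (inverse psychometric function)."""
    if observer.kind == "deterministic_threshold":
        if not (0.0 < p < 1.0):
            raise ValueError("p must be strictly between 0 and 1")
        return observer.threshold
    span = 1.0 - observer.guess_rate - observer.lapse_rate / 2.0
    psi = (p - observer.guess_rate) / span
    if not (0.0 < psi < 1.0):
        raise ValueError(
            f"p={p} is not strictly achievable (floor {observer.guess_rate}, "
            f"ceiling {observer.guess_rate + span})")
    return observer.threshold * math.exp(math.log(psi / (1.0 - psi)) / observer.slope)


def observer_with_p75(jnd: float, slope: float = 8.0, lapse_rate: float = 0.02) -> Observer:
    """Sigmoid observer whose 75%-correct point is exactly ``jnd``.

    This is the natural ground-truth parameterisation for validating the
    weighted up-down staircase, whose equilibrium is the 75% point.
    """
    if jnd <= 0:
        raise ValueError("jnd must be positive")
    span = 0.5 - lapse_rate / 2.0
    psi = 0.25 / span
    inflection = jnd * math.exp(-math.log(psi / (1.0 - psi)) / slope)
    return Observer("sigmoid", threshold=inflection, slope=slope, lapse_rate=lapse_rate)


def parse_observer(text: str) -> Observer:
    """Parse a CLI observer spec like ``sigmoid:thresh=40,slope=8,lapse=0.02``."""
    kind, _, rest = text.partition(":")
    kind = kind.strip()
    if kind == "deterministic":
        kind = "deterministic_threshold"
    params = {}
    if rest:
        for item in rest.split(","):
            key, _, value = item.partition("=")
            params[key.strip()] = float(value)
    return Observer(
        kind=kind,
        threshold=params.get("thresh", params.get("threshold", 40.0)),
        slope=params.get("slope", 8.0),
        lapse_rate=params.get("lapse", params.get("lapse_rate", 0.0)),
    )
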