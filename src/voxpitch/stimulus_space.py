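"""Acoustic parameter spaces for the vocal pitch and vocal timbre discrimination tests.

The pitch test lives on a musical-cents scale around a 112 Hz male-voice
baseline (1200 cents == 112 Hz; 100 cents == 1 semitone; the grid spans
0-2400 cents, i.e. one octave either side of the baseline).  The timbre test
lives on a spectral-envelope-ratio (SER) scale: a dimensionless factor that
scales all formant frequencies proportionally in log-frequency, emulating a
change in vocal-tract length / perceived speaker size (grid 0.80-1.30).

A lightweight source-filter vowel synthesizer provides WAV fixtures so the
staircase and scoring machinery can be demonstrated end to end: a harmonic
comb at the requested F0 is shaped by a three-formant Gaussian spectral
envelope whose centre frequencies are the vowel's table values scaled by SER.
This is a surrogate for full analysis-resynthesis of recorded vowels; tests
assert F0 and formant-scaling fidelity, not naturalness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import find_peaks

__all__ = [
    "BASE_F0_HZ",
    "BASE_CENTS",
    "CENTS_MIN",
    "CENTS_MAX",
    "SER_MIN",
    "SER_MAX",
    "VOWELS",
    "FORMANT_TABLE",
    "PitchPoint",
    "TimbrePoint",
    "VowelSpec",
    "cents_to_hz",
    "hz_to_cents",
    "enumerate_stimulus_set",
    "stimulus_manifest",
    "synthesize_vowel",
    "estimate_f0",
    "estimate_formants",
    "write_wav",
]

BASE_F0_HZ = 112.0   # fixed standard stimulus, near the average adult male F0
BASE_CENTS = 1200.0  # scale position assigned to the 112 Hz baseline
CENTS_MIN, CENTS_MAX = 0.0, 2400.0
SER_MIN, SER_MAX = 0.80, 1.30

VOWELS = ("a", "e", "i", "o", "u")

# Three-formant (centre Hz, bandwidth Hz) table per vowel, classic adult-male
# values in the Peterson & Barney tradition.  Only the relative scaling by SER
# matters for the discrimination tests, not the absolute choice.
FORMANT_TABLE: dict[str, tuple[tuple[float, float], ...]] = {
    "a": ((730.0, 60.0), (1090.0, 80.0), (2440.0, 110.0)),
    "e": ((530.0, 60.0), (1840.0, 80.0), (2480.0, 110.0)),
    "i": ((270.0, 55.0), (2290.0, 80.0), (3010.0, 110.0)),
    "o": ((570.0, 60.0), (840.0, 80.0), (2410.0, 110.0)),
    "u": ((300.0, 55.0), (870.0, 80.0), (2240.0, 110.0)),
}

_FORMANT_GAINS = (1.0, 0.6, 0.35)
_ENVELOPE_FLOOR = 1e-7


def cents_to_hz(cents: float, base_hz: float = BASE_F0_HZ,
                base_cents: float = BASE_CENTS) -> float:
    """Frequency at a position on the musical-cents scale.

    1200 cents is one octave (frequency ratio 2), so
    ``hz = base_hz * 2 ** ((cents - base_cents) / 1200)``.
    """
    if not (math.isfinite(cents) and math.isfinite(base_hz)
            and math.isfinite(base_cents)):
        raise ValueError("cents_to_hz requires finite inputs")
    if base_hz <= 0:
        raise ValueError("base_hz must be positive")
    return base_hz * 2.0 ** ((cents - base_cents) / 1200.0)


def hz_to_cents(hz: float, base_hz: float = BASE_F0_HZ,
                base_cents: float = BASE_CENTS) -> float:
    """Inverse of :func:`cents_to_hz`."""
    if not (math.isfinite(hz) and math.isfinite(base_hz)):
        raise ValueError("hz_to_cents requires finite inputs")
    if hz <= 0 or base_hz <= 0:
        raise ValueError("frequencies must be positive")
    return base_cents + 1200.0 * math.log2(hz / base_hz)


@dataclass(frozen=True)
class PitchPoint:
    """A point on the F0 scale of the pitch test (cents and Hz, consistent)."""

    cents: float
    hz: float = None  # type: ignore[assignment]

    def __post_init__(self):
        if not (CENTS_MIN <= self.cents <= CENTS_MAX):
            raise ValueError(f"cents {self.cents} outside [{CENTS_MIN}, {CENTS_MAX}]")
        if self.hz is None:
            object.__setattr__(self, "hz", cents_to_hz(self.cents))
        elif abs(self.hz - cents_to_hz(self.cents)) > 1e-6 * self.hz:
            raise ValueError("hz inconsistent with cents")
        if self.hz <= 0:
            raise ValueError("hz must be positive")


@dataclass(frozen=True)
class TimbrePoint:
    """A point on the spectral-envelope-ratio scale (1.0 = unmodified)."""

    ser: float

    def __post_init__(self):
        if not (SER_MIN <= self.ser <= SER_MAX):
            raise ValueError(f"ser {self.ser} outside [{SER_MIN}, {SER_MAX}]")


@dataclass(frozen=True)
class VowelSpec:
    """Full specification of one synthetic vowel stimulus."""

    vowel: str
    f0: PitchPoint = field(default_factory=lambda: PitchPoint(BASE_CENTS))
    timbre: TimbrePoint = field(default_factory=lambda: TimbrePoint(1.0))
    duration_ms: float = 600.0
    sample_rate_hz: int = 44100
    target_rms: float = 0.05

    def __post_init__(self):
        if self.vowel not in VOWELS:
            raise ValueError(f"unknown vowel {self.vowel!r}; expected one of {VOWELS}")
        if self.duration_ms <= 0 or self.sample_rate_hz <= 0 or self.target_rms <= 0:
            raise ValueError("duration, sample rate and target RMS must be positive")


def enumerate_stimulus_set(test: str, vowels: tuple[str, ...] = VOWELS) -> list[tuple]:
    """Identifiers of the full stimulus lattice for one test.

    Pitch: 1-cent steps, 2400 grid values per vowel (the 0-cent endpoint is the
    origin of the 1-cent ladder, giving 5 x 2400 = 12,000 stimuli).  Timbre:
    0.001 SER steps over [0.80, 1.30] inclusive, 501 values per vowel.
    """
    if test == "pitch":
        return [(v, c) for v in vowels for c in range(1, int(CENTS_MAX) + 1)]
    if test == "timbre":
        grid = [round(SER_MIN + 0.001 * i, 3) for i in range(501)]
        return [(v, s) for v in vowels for s in grid]
    raise ValueError("test must be 'pitch' or 'timbre'")


def stimulus_manifest(test: str) -> pd.DataFrame:
    """CSV-ready manifest (stimulus id, vowel, scale value, Hz where defined)."""
    rows = []
    for vowel, value in enumerate_stimulus_set(test):
        if test == "pitch":
            rows.append({"stimulus_id": f"{vowel}_c{value:04d}", "vowel": vowel,
                         "cents": value, "hz": cents_to_hz(value), "ser": 1.0})
        else:
            rows.append({"stimulus_id": f"{vowel}_s{value:.3f}", "vowel": vowel,
                         "cents": BASE_CENTS, "hz": BASE_F0_HZ, "ser": value})
    return pd.DataFrame(rows)


def _spectral_envelope(freqs: np.ndarray, vowel: str, ser: float,
                       formant_table=None) -> np.ndarray:
    """Gaussian-resonance envelope, combined as a max in log amplitude.

    Each formant contributes log-amplitude ln(g_i) - (f - ser*F_i)^2 /
    (2 (ser*b_i)^2); taking the pointwise maximum keeps every resonance an
    exact parabola on its own basin, so parabolic peak interpolation over
    harmonic amplitudes recovers the centre frequencies without bias.
    """
    table = (formant_table or FORMANT_TABLE)[vowel]
    log_env = np.full_like(freqs, math.log(_ENVELOPE_FLOOR), dtype=float)
    for (centre, bw), gain in zip(table, _FORMANT_GAINS):
        candidate = math.log(gain) - ((freqs - ser * centre) ** 2
                                      / (2.0 * (ser * bw) ** 2))
        log_env = np.maximum(log_env, candidate)
    return np.exp(log_env)


def synthesize_vowel(spec: VowelSpec, formant_table=None) -> np.ndarray:
    """Render a mono waveform for ``spec`` (harmonic comb x formant envelope).

    The voiced source is an in-phase harmonic comb at ``spec.f0.hz``; each
    harmonic's amplitude is the vowel's Gaussian formant envelope (scaled by
    SER) evaluated at the harmonic frequency.  Output is RMS-normalised to
    ``spec.target_rms`` (relative error < 1e-6).
    """
    sr = spec.sample_rate_hz
    nyquist = sr / 2.0
    table = (formant_table or FORMANT_TABLE)[spec.vowel]
    top = spec.timbre.ser * max(c + 3.0 * b for c, b in table)
    if top >= nyquist:
        raise ValueError(
            f"SER {spec.timbre.ser} scales the highest formant past Nyquist "
            f"({top:.0f} Hz >= {nyquist:.0f} Hz)")

    n = round(spec.duration_ms / 1000.0 * sr)
    t = np.arange(n) / sr
    f0 = spec.f0.hz
    k = np.arange(1, int(nyquist / f0) + 1)
    harmonics = k * f0
    harmonics = harmonics[harmonics < nyquist]
    amps = _spectral_envelope(harmonics, spec.vowel, spec.timbre.ser, formant_table)
    wave = (amps[:, None] * np.sin(2.0 * np.pi * harmonics[:, None] * t[None, :])).sum(axis=0)
    rms = math.sqrt(float(np.mean(wave ** 2)))
    return wave * (spec.target_rms / rms)


def estimate_f0(waveform: np.ndarray, sample_rate_hz: int = 44100,
                fmin: float = 50.0, fmax: float = 500.0) -> float:
    """Estimate the fundamental by autocorrelation with parabolic interpolation."""
    x = np.asarray(waveform, dtype=float)
    x = x - x.mean()
    ac = np.correlate(x, x, mode="full")[x.size - 1:]
    lag_min = int(sample_rate_hz / fmax)
    lag_max = min(int(sample_rate_hz / fmin), ac.size - 2)
    lag = lag_min + int(np.argmax(ac[lag_min:lag_max + 1]))
    y0, y1, y2 = ac[lag - 1], ac[lag], ac[lag + 1]
    denom = y0 - 2.0 * y1 + y2
    shift = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    return sample_rate_hz / (lag + shift)


def estimate_formants(waveform: np.ndarray, f0: float,
                      sample_rate_hz: int = 44100, n_formants: int = 3) -> np.ndarray:
    """Formant centre frequencies from harmonic amplitudes.

    Samples the magnitude spectrum at harmonics of ``f0``, finds the most
    prominent local maxima of the log-amplitude sequence and refines each by a
    parabolic fit through the neighbouring harmonics (exact for a Gaussian
    spectral envelope in linear frequency).
    """
    x = np.asarray(waveform, dtype=float)
    x = x * np.hanning(x.size)  # suppress leakage between distant harmonics
    spectrum = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(x.size, d=1.0 / sample_rate_hz)
    nyquist = sample_rate_hz / 2.0
    harmonics = np.arange(1, int(nyquist / f0)) * f0
    idx = np.clip(np.searchsorted(freqs, harmonics), 1, freqs.size - 1)
    # snap to nearest bin
    idx = np.where(np.abs(freqs[idx] - harmonics) < np.abs(freqs[idx - 1] - harmonics),
                   idx, idx - 1)
    amp = spectrum[idx]
    # numerical floor: leakage residue far from any formant is not a peak
    logamp = np.log(np.maximum(amp, amp.max() * 1e-7))
    peaks, props = find_peaks(logamp, prominence=0.5)
    if peaks.size < n_formants:
        raise ValueError("fewer spectral peaks than requested formants")
    order = np.argsort(props["prominences"])[::-1][:n_formants]
    chosen = np.sort(peaks[order])
    estimates = []
    for p in chosen:
        y0, y1, y2 = logamp[p - 1], logamp[p], logamp[p + 1]
        denom = y0 - 2.0 * y1 + y2
        shift = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
        estimates.append((p + 1 + shift) * f0)  # harmonic index is 1-based
    return np.asarray(estimates)


def write_wav(path, waveform: np.ndarray, sample_rate_hz: int = 44100) -> None:
    """Write a mono 16-bit PCM RIFF WAV file."""
    scaled = np.clip(np.asarray(waveform, dtype=float), -1.0, 1.0)
    wavfile.write(path, sample_rate_hz, (scaled * 32767.0).astype(np.int16))
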