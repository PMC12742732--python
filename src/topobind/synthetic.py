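"""Synthetic EEG, dynamical-system fixtures, and Libet-clock trials.

Everything downstream of raw data is exercised against signals with known
ground truth: band-structured oscillations over a 1/f background with
optional 50 Hz line noise and an optional broadband "muscle" component
(rising log-log spectrum, spatially focal) for the artifact screener;
canonical scalar series (sine, two-tone, Lorenz, white noise) for the
embedding/persistence oracles; and clock-judgment trials with injectable
perceptual shifts that the binding analysis must recover.

All generators draw from one seeded :class:`numpy.random.Generator` per
call, so identical config + seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.integrate import solve_ivp

from .binding import (
    ACTION_ONLY,
    AGENCY_JUDGE_ACTION,
    AGENCY_JUDGE_TONE,
    CONDITIONS,
    DEFAULT_CLOCK_PERIOD_MS,
    TONE_ONLY,
    TrialRecord,
)
from .recording import MUSE_CHANNELS, EEGRecording
from .spectral import DEFAULT_BANDS

#: Default band weights: an eyes-closed resting profile (alpha-dominant,
#: strong slow activity, weak fast activity).
DEFAULT_BAND_WEIGHTS: dict[str, float] = {
    "delta": 1.0,
    "theta": 0.6,
    "alpha": 1.2,
    "sigma": 0.15,
    "beta": 0.3,
    "gamma": 0.1,
}

#: Microvolt scale of one unit of generated (unit-RMS) signal.
_UV_SCALE = 10.0


@dataclass
class EEGSimConfig:
    """Parameters of the EEG-like signal generator.

    ``band_weights`` are the RMS weights of band-limited oscillatory
    components (band edges from :data:`topobind.spectral.DEFAULT_BANDS`);
    ``tonal_weights`` add spectrally coherent single-frequency oscillations
    at the band centre (random phase) -- these trace clean loops after
    delay embedding, unlike the incoherent band-noise components;
    ``one_over_f_exponent`` shapes the aperiodic background power as
    ``1/f^exponent``; ``line_noise_amp`` is the RMS of a 50 Hz sinusoid
    relative to one unit of background; the muscle artifact is broadband
    noise with a *rising* log-log spectrum mixed into a spatially focal
    component.
    """

    duration_s: float = 240.0
    fs: float = 256.0
    n_channels: int = 4
    channel_names: tuple[str, ...] = MUSE_CHANNELS
    band_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_WEIGHTS))
    tonal_weights: Mapping[str, float] = field(default_factory=dict)
    one_over_f_exponent: float = 1.0
    one_over_f_amp: float = 1.0
    line_noise_hz: float = 50.0
    line_noise_amp: float = 0.1
    muscle_artifact: bool = False
    muscle_amp: float = 5.0
    muscle_mixing: tuple[float, ...] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be positive, got {self.duration_s}")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.n_channels < 1:
            raise ValueError("need at least one channel")
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length must equal n_channels")
        if any(w < 0 for w in self.band_weights.values()):
            raise ValueError("band weights must be nonnegative")
        if any(w < 0 for w in self.tonal_weights.values()):
            raise ValueError("tonal weights must be nonnegative")
        active = (any(w > 0 for w in self.band_weights.values())
                  or any(w > 0 for w in self.tonal_weights.values())
                  or self.one_over_f_amp > 0 or self.line_noise_amp > 0
                  or self.muscle_artifact)
        if not active:
            raise ValueError("config generates an all-zero signal: enable "
                             "at least one band weight or noise term")


@dataclass
class TrialSimConfig:
    """Parameters of the Libet-clock trial generator.

    ``action_shift_ms`` / ``tone_shift_ms`` are the ground-truth perceptual
    shifts added to agency-block judgments (positive = reported later);
    baseline blocks get only Gaussian judgment noise. Reported positions
    wrap onto the clock period.
    """

    n_trials_per_condition: int = 20
    action_tone_delay_ms: float = 250.0
    clock_period_ms: float = DEFAULT_CLOCK_PERIOD_MS
    action_shift_ms: float = 0.0
    tone_shift_ms: float = 0.0
    judgment_noise_sd_ms: float = 70.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_trials_per_condition < 1:
            raise ValueError("need at least one trial per condition")
        if self.clock_period_ms <= 0:
            raise ValueError("clock period must be positive")
        if self.judgment_noise_sd_ms < 0:
            raise ValueError("judgment noise SD must be nonnegative")


def _shaped_noise(rng: np.random.Generator, n: int, fs: float,
                  gain) -> np.ndarray:
    """White noise spectrally shaped by ``gain(freqs)``, unit RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    g = np.asarray(gain(freqs), dtype=float)
    g[0] = 0.0  # no DC
    shaped = np.fft.irfft(spec * g, n=n)
    rms = np.sqrt(np.mean(shaped ** 2))
    return shaped / rms if rms > 0 else shaped


def _band_component(rng, n, fs, low, high):
    return _shaped_noise(rng, n, fs,
                         lambda f: ((f >= low) & (f < high)).astype(float))


def _one_over_f(rng, n, fs, exponent):
    def gain(f):
        with np.errstate(divide="ignore"):
            g = np.where(f > 0, f, np.nan) ** (-exponent / 2.0)
        return np.nan_to_num(g, nan=0.0, posinf=0.0)
    return _shaped_noise(rng, n, fs, gain)


def _muscle_source(rng, n, fs):
    # Rising power spectrum (~ f^{+1.5} over 5 Hz..Nyquist) so the 7-45 Hz
    # log-log slope is clearly positive, times a slow lognormal burst
    # envelope: real postural EMG arrives in bursts, and the resulting
    # super-Gaussian amplitude distribution is what lets an ICA pull the
    # source out of an otherwise near-Gaussian background.
    def gain(f):
        return np.where((f >= 5.0) & (f <= 55.0),
                        np.maximum(f, 1e-12) ** 0.75, 0.0)

    carrier = _shaped_noise(rng, n, fs, gain)
    slow = _shaped_noise(rng, n, fs, lambda f: ((f > 0) & (f < 1.0)).astype(float))
    envelope = np.exp(1.0 * slow)
    source = carrier * envelope
    rms = np.sqrt(np.mean(source ** 2))
    return source / rms if rms > 0 else source


def generate_eeg(config: EEGSimConfig) -> EEGRecording:
    """Generate a multichannel EEG-like recording (microvolts).

    Each channel is an independent sum of band-limited oscillations,
    1/f background, and optional 50 Hz line noise; the optional muscle
    artifact is a single shared broadband source mixed through a focal
    spatial vector (default: concentrated on the last channel).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.fs))
    fs = config.fs
    data = np.zeros((config.n_channels, n))
    for ch in range(config.n_channels):
        x = np.zeros(n)
        for name, weight in config.band_weights.items():
            if weight > 0:
                low, high = DEFAULT_BANDS[name]
                x += weight * _band_component(rng, n, fs, low, high)
        for name, weight in config.tonal_weights.items():
            if weight > 0:
                low, high = DEFAULT_BANDS[name]
                f0 = (low + high) / 2.0
                phase = rng.uniform(0, 2 * np.pi)
                t = np.arange(n) / fs
                x += weight * np.sqrt(2) * np.sin(2 * np.pi * f0 * t + phase)
        if config.one_over_f_amp > 0:
            x += config.one_over_f_amp * _one_over_f(
                rng, n, fs, config.one_over_f_exponent)
        if config.line_noise_amp > 0:
            phase = rng.uniform(0, 2 * np.pi)
            t = np.arange(n) / fs
            x += (config.line_noise_amp * np.sqrt(2)
                  * np.sin(2 * np.pi * config.line_noise_hz * t + phase))
        data[ch] = x
    if config.muscle_artifact:
        mixing = config.muscle_mixing
        if mixing is None:
            mixing = tuple([0.05] * (config.n_channels - 1) + [1.0])
        mixing = np.asarray(mixing, dtype=float)
        if mixing.shape != (config.n_channels,):
            raise ValueError("muscle_mixing must have one weight per channel")
        source = _muscle_source(rng, n, fs)
        data += config.muscle_amp * np.outer(mixing, source)
    return EEGRecording(data * _UV_SCALE, fs=fs,
                        channel_names=config.channel_names)


def generate_session(
    group: str,
    config: EEGSimConfig,
    n_questions: int = 8,
    question_s: float = 30.0,
    ctr_duration_s: float = 240.0,
) -> EEGRecording:
    """Generate one reflection session with event markers.

    SCR/SLR sessions are ``n_questions`` back-to-back question blocks of
    ``question_s`` seconds, marked ``question_1 .. question_N``; CTR is a
    single silent block of ``ctr_duration_s`` seconds marked ``rest``.
    """
    import dataclasses

    if group in ("SCR", "SLR"):
        duration = n_questions * question_s
        cfg = dataclasses.replace(config, duration_s=duration)
        rec = generate_eeg(cfg)
        step = int(round(question_s * config.fs))
        rec.events = [(q * step, f"question_{q + 1}") for q in range(n_questions)]
    elif group == "CTR":
        cfg = dataclasses.replace(config, duration_s=ctr_duration_s)
        rec = generate_eeg(cfg)
        rec.events = [(0, "rest")]
    else:
        raise ValueError(f"unknown group {group!r} (expected SCR, SLR or CTR)")
    return rec


FIXTURES = ("sine", "two_tone", "lorenz", "white_noise")


def generate_fixture(name: str, n: int, seed: int = 0, *,
                     period: float = 32.0) -> np.ndarray:
    """Deterministic scalar test series for the embedding/persistence oracles.

    ``sine`` is a single frequency (one cycle per ``period`` samples, random
    phase); ``two_tone`` superposes that with a weaker 4x-faster tone;
    ``lorenz`` is the x-coordinate of the standard chaotic Lorenz trajectory
    (sigma=10, rho=28, beta=8/3) after a transient; ``white_noise`` is iid
    Gaussian.
    """
    if n < 16:
        raise ValueError(f"need n >= 16 samples, got {n}")
    rng = np.random.default_rng(seed)
    t = np.arange(n, dtype=float)
    if name == "sine":
        phase = rng.uniform(0, 2 * np.pi)
        return np.sin(2 * np.pi * t / period + phase)
    if name == "two_tone":
        phase = rng.uniform(0, 2 * np.pi, size=2)
        return (np.sin(2 * np.pi * t / period + phase[0])
                + 0.5 * np.sin(2 * np.pi * t / (period / 4.0) + phase[1]))
    if name == "lorenz":
        x0 = np.array([1.0, 1.0, 1.0]) + 0.1 * rng.standard_normal(3)
        dt = 0.02
        t_transient = 20.0
        t_eval = t_transient + dt * np.arange(n)

        def lorenz(_, s):
            x, y, z = s
            return [10.0 * (y - x), x * (28.0 - z) - y, x * y - 8.0 / 3.0 * z]

        sol = solve_ivp(lorenz, (0.0, t_eval[-1]), x0, t_eval=t_eval,
                        rtol=1e-9, atol=1e-9, method="RK45")
        return sol.y[0]
    if name == "white_noise":
        return rng.standard_normal(n)
    raise ValueError(f"unknown fixture {name!r} (choose from {FIXTURES})")


def generate_trials(config: TrialSimConfig) -> list[TrialRecord]:
    """Generate one subject's Libet-clock trials in randomized order.

    Baseline conditions report ``actual + noise``; agency conditions add the
    configured action/tone shift to the corresponding judgments. Reported
    positions wrap modulo the clock period.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    period = config.clock_period_ms
    ms_to_deg = 360.0 / period
    shifts = {
        ACTION_ONLY: 0.0,
        TONE_ONLY: 0.0,
        AGENCY_JUDGE_ACTION: config.action_shift_ms,
        AGENCY_JUDGE_TONE: config.tone_shift_ms,
    }
    trials: list[TrialRecord] = []
    for condition in CONDITIONS:
        for _ in range(config.n_trials_per_condition):
            actual_deg = rng.uniform(0.0, 360.0)
            noise_ms = (rng.normal(0.0, config.judgment_noise_sd_ms)
                        if config.judgment_noise_sd_ms > 0 else 0.0)
            reported_deg = (actual_deg
                            + (shifts[condition] + noise_ms) * ms_to_deg) % 360.0
            trials.append(TrialRecord(
                condition=condition,
                actual_deg=actual_deg,
                reported_deg=reported_deg,
                clock_period_ms=period,
            ))
    order = rng.permutation(len(trials))
    return [trials[i] for i in order]
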