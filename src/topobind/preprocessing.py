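"""EEG cleaning chain: band-pass + notch, muscle-component screening,
channel pooling, condition segmentation, and anti-aliased downsampling.

The chain mirrors a low-density (4-channel Muse) recording protocol:
zero-phase FIR band-pass 0.1-45 Hz with a 50 Hz notch, FastICA-based
screening of muscle components (rising 7-45 Hz log-log spectral slope,
spatially focal, spectrally smooth), averaging TP9/TP10 and AF7/AF8 into
pooled TP and AF channels, extraction of 25 s per-condition segments, and
decimation by 4 (256 -> 64 Hz) for the topological features.

A meaningful "fourth order" FIR is not realizable at a 0.1 Hz edge; the
default kernel length instead follows the standard transition-bandwidth
rule for the low edge and is configurable via ``FilterSpec.fir_length``.
Zero phase comes from centred convolution of the symmetric linear-phase
kernel.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal
from sklearn.decomposition import FastICA

from .recording import EEGRecording
from .spectral import welch_psd

logger = logging.getLogger(__name__)


class DegenerateChannelError(ValueError):
    """Raised when a channel makes the data rank-deficient for ICA."""


@dataclass
class FilterSpec:
    """Band-pass + notch design parameters."""

    highpass_hz: float = 0.1
    lowpass_hz: float = 45.0
    notch_hz: float | None = 50.0
    notch_halfwidth_hz: float = 1.0
    fir_length: int | None = None  # odd tap count; None = auto rule

    def validate(self, fs: float) -> None:
        if not 0 < self.highpass_hz < self.lowpass_hz:
            raise ValueError("need 0 < highpass < lowpass")
        if self.lowpass_hz >= fs / 2:
            raise ValueError(
                f"lowpass {self.lowpass_hz} Hz >= Nyquist {fs / 2} Hz")
        if self.notch_hz is not None and not (
                self.highpass_hz < self.notch_hz < fs / 2):
            raise ValueError("notch frequency must lie between the high-pass "
                             "edge and Nyquist (set notch_hz=None to disable)")


@dataclass
class ComponentScreenReport:
    """Screening verdict for one independent component."""

    component_index: int
    slope_7_45: float       # log10-power per log10-Hz over 7-45 Hz
    focality: float         # max |mixing weight| / sum |mixing weights|
    smoothness: float       # R^2 of the log-log spectral fit
    flagged: bool


@dataclass
class ScreenThresholds:
    """Muscle-component criteria; a component is flagged only if all hold."""

    min_slope: float = 0.0
    min_focality: float = 0.6
    min_smoothness: float = 0.65


@dataclass
class ConditionSegment:
    """One pooled-channel 25 s segment of a condition."""

    group: str
    channel: str
    question_index: int | None
    samples: np.ndarray
    fs: float

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


def _odd(n: int) -> int:
    return n if n % 2 == 1 else n + 1


def design_fir(spec: FilterSpec, fs: float) -> np.ndarray:
    """Symmetric FIR kernel combining the band-pass and the notch."""
    spec.validate(fs)
    if spec.fir_length is not None:
        ntaps = _odd(int(spec.fir_length))
    else:
        # transition-bandwidth rule anchored at the (wide) low edge
        trans = max(0.5, 2.0 * spec.highpass_hz)
        ntaps = _odd(int(round(3.3 * fs / trans)))
    kernel = sp_signal.firwin(ntaps, [spec.highpass_hz, spec.lowpass_hz],
                              pass_zero=False, fs=fs)
    if spec.notch_hz is not None:
        n_notch = _odd(int(round(3.3 * fs / spec.notch_halfwidth_hz)))
        notch = sp_signal.firwin(
            n_notch,
            [spec.notch_hz - spec.notch_halfwidth_hz,
             spec.notch_hz + spec.notch_halfwidth_hz],
            pass_zero=True, fs=fs)
        kernel = np.convolve(kernel, notch)
    return kernel


def bandpass_notch(rec: EEGRecording, spec: FilterSpec | None = None) -> EEGRecording:
    """Zero-phase FIR band-pass (+ optional notch) applied per channel.

    The symmetric kernel is applied by centred FFT convolution, which is
    exactly zero-phase and linear; edge regions of about half a kernel
    length are attenuated.
    """
    spec = spec or FilterSpec()
    kernel = design_fir(spec, rec.fs)
    logger.info("bandpass_notch: %d taps, %.3g-%.3g Hz, notch=%s",
                len(kernel), spec.highpass_hz, spec.lowpass_hz, spec.notch_hz)
    filtered = np.stack([
        sp_signal.fftconvolve(ch, kernel, mode="same") for ch in rec.data
    ])
    return rec.with_data(filtered)


def _check_rank(rec: EEGRecording) -> None:
    data = rec.data
    variances = data.var(axis=1)
    for name, v in zip(rec.channel_names, variances):
        if v <= 1e-24:
            raise DegenerateChannelError(
                f"channel {name!r} is constant; ICA needs full-rank data")
    cov = np.cov(data)
    rank = np.linalg.matrix_rank(cov, tol=1e-10 * np.trace(cov))
    if rank < rec.n_channels:
        # name the channel best explained by the others
        resid = []
        for i in range(rec.n_channels):
            others = np.delete(data, i, axis=0)
            coef, *_ = np.linalg.lstsq(others.T, data[i], rcond=None)
            resid.append(np.var(data[i] - others.T @ coef) / variances[i])
        name = rec.channel_names[int(np.argmin(resid))]
        raise DegenerateChannelError(
            f"data is rank-deficient (rank {rank} < {rec.n_channels}); "
            f"channel {name!r} is linearly dependent on the others")


def _fit_ica(rec: EEGRecording, n_components: int, seed: int):
    _check_rank(rec)
    ica = FastICA(n_components=n_components, random_state=seed,
                  whiten="unit-variance", max_iter=2000, tol=1e-5)
    sources = ica.fit_transform(rec.data.T)     # (n_samples, k)
    mixing = ica.mixing_                        # (n_channels, k)
    return sources, mixing


def _screen(sources, mixing, fs, thresholds) -> list[ComponentScreenReport]:
    reports = []
    for i in range(sources.shape[1]):
        # short windows = many averages: the log-log fit needs a low-variance
        # PSD estimate far more than it needs fine frequency resolution
        freqs, psd = welch_psd(x=sources[:, i], fs=fs, window_s=0.5)
        mask = (freqs >= 7.0) & (freqs <= 45.0) & (psd > 0)
        logf = np.log10(freqs[mask])
        logp = np.log10(psd[mask])
        # moving-average smoothing: the fit should judge the spectral trend,
        # not the estimator noise of individual Welch bins
        k = 5
        if len(logp) > k:
            sm = np.convolve(logp, np.ones(k) / k, mode="same")
            sm[:k // 2] = sm[k // 2]
            sm[-(k // 2):] = sm[-(k // 2) - 1]
            logp = sm
        slope, intercept = np.polyfit(logf, logp, 1)
        fitted = slope * logf + intercept
        ss_res = np.sum((logp - fitted) ** 2)
        ss_tot = np.sum((logp - logp.mean()) ** 2)
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        weights = np.abs(mixing[:, i])
        focality = float(weights.max() / weights.sum()) if weights.sum() > 0 else 0.0
        flagged = (slope > thresholds.min_slope
                   and focality > thresholds.min_focality
                   and r2 > thresholds.min_smoothness)
        reports.append(ComponentScreenReport(
            component_index=i, slope_7_45=float(slope),
            focality=focality, smoothness=float(r2), flagged=flagged))
    return reports


def screen_components(
    rec: EEGRecording,
    n_components: int | None = None,
    seed: int = 0,
    thresholds: ScreenThresholds | None = None,
) -> list[ComponentScreenReport]:
    """Decompose with FastICA and screen components for muscle artifact.

    A component is flagged when its 7-45 Hz log-log spectral slope is
    positive, its mixing weights are concentrated on one channel
    (focality), and its log-log spectrum is well fit by a line
    (smoothness). Thresholds are configurable.
    """
    n_components = n_components or rec.n_channels
    if n_components > rec.n_channels:
        raise ValueError("n_components cannot exceed the channel count")
    thresholds = thresholds or ScreenThresholds()
    sources, mixing = _fit_ica(rec, n_components, seed)
    reports = _screen(sources, mixing, rec.fs, thresholds)
    logger.info("screen_components: flagged %s of %d",
                [r.component_index for r in reports if r.flagged], n_components)
    return reports


def remove_muscle_components(
    rec: EEGRecording,
    n_components: int | None = None,
    seed: int = 0,
    thresholds: ScreenThresholds | None = None,
) -> tuple[EEGRecording, list[ComponentScreenReport]]:
    """Screen and reconstruct the recording without flagged components.

    With an empty flagged set the reconstruction equals the input to
    numerical tolerance (nothing is projected out).
    """
    n_components = n_components or rec.n_channels
    if n_components > rec.n_channels:
        raise ValueError("n_components cannot exceed the channel count")
    thresholds = thresholds or ScreenThresholds()
    sources, mixing = _fit_ica(rec, n_components, seed)
    reports = _screen(sources, mixing, rec.fs, thresholds)
    flagged = [r.component_index for r in reports if r.flagged]
    if flagged:
        removed = sources[:, flagged] @ mixing[:, flagged].T
        cleaned = rec.with_data(rec.data - removed.T)
    else:
        cleaned = rec.with_data(rec.data.copy())
    return cleaned, reports


def pool_channels(rec: EEGRecording) -> EEGRecording:
    """Average TP9/TP10 into TP and AF7/AF8 into AF."""
    for name in ("TP9", "TP10", "AF7", "AF8"):
        if name not in rec.channel_names:
            raise ValueError(f"cannot pool channels: {name!r} is missing")
    tp = (rec.channel("TP9") + rec.channel("TP10")) / 2.0
    af = (rec.channel("AF7") + rec.channel("AF8")) / 2.0
    return EEGRecording(np.stack([tp, af]), fs=rec.fs,
                        channel_names=("TP", "AF"), events=list(rec.events))


_QUESTION_RE = re.compile(r"^question[_ ]?(\d+)$")

SEGMENT_S = 25.0


def extract_segments(rec: EEGRecording, group: str) -> list[ConditionSegment]:
    """Cut the per-condition 25 s segments from a marked session.

    SCR/SLR: one segment per question marker and channel, the *last* 25 s
    of each question span (span = to the next marker or end of recording).
    CTR: one segment per channel, the *central* 25 s of the ``rest`` block
    (symmetric about the block midpoint; for 240 s that is 107.5-132.5 s).
    Sample intervals are half-open and 0-based.
    """
    seg_len = int(round(SEGMENT_S * rec.fs))
    segments: list[ConditionSegment] = []
    if group in ("SCR", "SLR"):
        marks = []
        for idx, label in rec.events:
            m = _QUESTION_RE.match(label)
            if m:
                marks.append((idx, int(m.group(1))))
        if not marks:
            raise ValueError(f"no question markers found for group {group}")
        marks.sort()
        for pos, (start, qidx) in enumerate(marks):
            end = marks[pos + 1][0] if pos + 1 < len(marks) else rec.n_samples
            if end - start < seg_len:
                raise ValueError(
                    f"question {qidx} spans {(end - start) / rec.fs:.2f} s, "
                    f"shorter than the {SEGMENT_S:g} s segment")
            lo, hi = end - seg_len, end
            for ch, name in enumerate(rec.channel_names):
                segments.append(ConditionSegment(
                    group=group, channel=name, question_index=qidx,
                    samples=rec.data[ch, lo:hi].copy(), fs=rec.fs))
    elif group == "CTR":
        starts = [idx for idx, label in rec.events if label == "rest"]
        if not starts:
            raise ValueError("no 'rest' marker found for group CTR")
        start = starts[0]
        later = [idx for idx, _ in rec.events if idx > start]
        end = min(later) if later else rec.n_samples
        if end - start < seg_len:
            raise ValueError(
                f"rest block of {(end - start) / rec.fs:.2f} s is shorter "
                f"than the {SEGMENT_S:g} s segment")
        lo = start + (end - start - seg_len) // 2
        hi = lo + seg_len
        for ch, name in enumerate(rec.channel_names):
            segments.append(ConditionSegment(
                group=group, channel=name, question_index=None,
                samples=rec.data[ch, lo:hi].copy(), fs=rec.fs))
    else:
        raise ValueError(f"unknown group {group!r} (expected SCR, SLR or CTR)")
    return segments


def downsample(seg: ConditionSegment, factor: int) -> ConditionSegment:
    """Anti-aliased decimation by an integer factor (FIR, zero phase)."""
    if factor < 1:
        raise ValueError(f"downsampling factor must be >= 1, got {factor}")
    if factor == 1:
        out = seg.samples.copy()
    else:
        out = sp_signal.decimate(seg.samples, factor, ftype="fir",
                                 zero_phase=True)
        out = out[: len(seg.samples) // factor]
    return ConditionSegment(group=seg.group, channel=seg.channel,
                            question_index=seg.question_index,
                            samples=out, fs=seg.fs / factor)
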