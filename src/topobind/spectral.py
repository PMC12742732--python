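"""Welch power spectra and six-band relative band power.

Relative band power is computed the way it is defined for this pipeline:
the PSD is averaged *within* each band, and each band mean is divided by
the sum of the six band means. This differs from dividing by the total
integrated power whenever the bands have unequal widths and the spectrum
is not flat; a regression test pins the band-mean variant.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sp_signal

#: Band edges in Hz, half-open intervals [low, high).
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 5.0),
    "theta": (5.0, 8.0),
    "alpha": (8.0, 13.0),
    "sigma": (13.0, 16.0),
    "beta": (16.0, 30.0),
    "gamma": (30.0, 45.0),
}


def validate_band_scheme(bands: Mapping[str, tuple[float, float]],
                         fs: float | None = None) -> None:
    """Check that bands are non-overlapping, increasing and below Nyquist."""
    prev_high = 0.0
    for name, (low, high) in bands.items():
        if not 0.0 < low < high:
            raise ValueError(f"band {name!r}: invalid edges ({low}, {high})")
        if low < prev_high:
            raise ValueError(f"band {name!r} overlaps the previous band")
        if fs is not None and high > fs / 2:
            raise ValueError(f"band {name!r} exceeds Nyquist ({fs / 2} Hz)")
        prev_high = high


def _as_series(seg) -> tuple[np.ndarray, float]:
    if hasattr(seg, "samples"):
        return np.asarray(seg.samples, dtype=float), float(seg.fs)
    raise TypeError("welch_psd needs a ConditionSegment or (x, fs=...)")


def welch_psd(seg=None, window_s: float = 4.0, overlap: float = 0.5,
              *, x: np.ndarray | None = None, fs: float | None = None):
    """One-sided Welch PSD with Hann windows.

    Parameters
    ----------
    seg : ConditionSegment, optional
        Segment holding ``samples`` and ``fs``; alternatively pass ``x``
        and ``fs`` directly.
    window_s : float
        Window length in seconds; frequency resolution is ``1 / window_s``.
    overlap : float
        Fractional window overlap in [0, 1).

    Returns
    -------
    (frequencies, psd) : pair of ndarray
    """
    if seg is not None:
        x, fs = _as_series(seg)
    if x is None or fs is None:
        raise TypeError("pass a segment or both x= and fs=")
    x = np.asarray(x, dtype=float)
    if not 0 <= overlap < 1:
        raise ValueError(f"overlap must be in [0, 1), got {overlap}")
    nperseg = int(round(window_s * fs))
    step = max(1, int(round(nperseg * (1 - overlap))))
    if len(x) < nperseg + step:
        raise ValueError(
            f"segment of {len(x)} samples too short for two {window_s} s "
            f"windows at {fs} Hz"
        )
    noverlap = nperseg - step
    freqs, psd = sp_signal.welch(x, fs=fs, window="hann", nperseg=nperseg,
                                 noverlap=noverlap, detrend="constant")
    return freqs, psd


def relative_band_power(
    freqs: np.ndarray,
    psd: np.ndarray,
    bands: Mapping[str, tuple[float, float]] | None = None,
) -> dict[str, float]:
    """Six-band relative power: band-mean PSD over the sum of band means.

    Band-edge bins are assigned half-open, ``low <= f < high``. The output
    fractions are nonnegative and sum to 1.
    """
    bands = dict(bands or DEFAULT_BANDS)
    validate_band_scheme(bands)
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    means = {}
    for name, (low, high) in bands.items():
        mask = (freqs >= low) & (freqs < high)
        if not mask.any():
            raise ValueError(
                f"band {name!r} [{low}, {high}) contains no PSD bins "
                f"(resolution {freqs[1] - freqs[0]:.4g} Hz)"
            )
        means[name] = float(psd[mask].mean())
    total = sum(means.values())
    if total == 0:
        # zero signal: no power anywhere, keep the simplex degenerate-uniform
        return {name: 1.0 / len(means) for name in means}
    return {name: m / total for name, m in means.items()}


def average_over_questions(
    values: Sequence[Mapping[str, float]],
) -> dict[str, float]:
    """Element-wise mean of per-question relative band powers."""
    if not values:
        raise ValueError("cannot average an empty list of band powers")
    names = list(values[0].keys())
    for v in values:
        if list(v.keys()) != names:
            raise ValueError("band power mappings have mismatched bands")
    return {name: float(np.mean([v[name] for v in values])) for name in names}
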