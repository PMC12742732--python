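"""Sample entropy and multiscale entropy.

Sample entropy SampEn(m, r) is the negative log of the conditional
probability that two sequences matching for m points (Chebyshev distance
<= r * SD, self-matches excluded) also match for m+1 points. Multiscale
entropy evaluates SampEn on successively coarse-grained series (window
means of length tau); by default the tolerance stays anchored to the SD
of the *original* series across scales, the common convention (a
per-scale-SD variant is available via ``use_original_sd=False``).

Degenerate situations (no matches, zero variance, too-short series)
return NaN rather than raising, so whole feature tables never crash on
one pathological segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


@dataclass
class SampEnConfig:
    m: int = 2
    r: float = 0.2                       # tolerance as a fraction of SD
    scales: tuple[int, ...] = field(default_factory=lambda: tuple(range(1, 21)))

    def validate(self) -> None:
        if self.m < 1:
            raise ValueError("pattern length m must be >= 1")
        if self.r <= 0:
            raise ValueError("tolerance fraction r must be positive")
        if any(s < 1 for s in self.scales):
            raise ValueError("scales must be >= 1")


@dataclass
class MSECurve:
    """Sample entropy per coarse-graining scale; NaN marks undefined."""

    scales: tuple[int, ...]
    values: np.ndarray

    def as_dict(self) -> dict[int, float]:
        return {s: float(v) for s, v in zip(self.scales, self.values)}


def coarse_grain(x: np.ndarray, tau: int) -> np.ndarray:
    """Non-overlapping window means of length tau (trailing rest dropped)."""
    x = np.asarray(x, dtype=float)
    if tau < 1:
        raise ValueError(f"scale factor must be >= 1, got {tau}")
    if tau > len(x):
        raise ValueError(f"scale factor {tau} exceeds series length {len(x)}")
    if tau == 1:
        return x.copy()
    n = (len(x) // tau) * tau
    return x[:n].reshape(-1, tau).mean(axis=1)


def _count_matches(templates: np.ndarray, tol: float, block: int = 512) -> int:
    """Number of unordered template pairs (i<j) within Chebyshev tol."""
    n = templates.shape[0]
    total = 0
    for start in range(0, n, block):
        chunk = templates[start:start + block]            # (b, m)
        # compare chunk rows against all later rows only
        diff = np.abs(chunk[:, None, :] - templates[None, start:, :]).max(axis=2)
        within = diff <= tol
        rows = np.arange(chunk.shape[0])[:, None]
        cols = np.arange(within.shape[1])[None, :]
        total += int(np.count_nonzero(within & (cols > rows)))
    return total


def sample_entropy(x: np.ndarray, m: int = 2, r: float = 0.2,
                   sd: float | None = None) -> float:
    """SampEn(m, r) = -ln(A / B) with B m-matches and A (m+1)-matches.

    Both counts use template start indices 0..N-m-1 so every m-template
    has an (m+1)-extension. Returns NaN when undefined (constant series,
    no matches, or series shorter than m+2).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < m + 2:
        return float("nan")
    if sd is None:
        sd = float(np.std(x))
    if not sd > 0:
        return float("nan")
    tol = r * sd
    templates_m1 = sliding_window_view(x, m + 1)          # (n-m, m+1)
    templates_m = templates_m1[:, :m]                     # same starts
    b = _count_matches(templates_m, tol)
    a = _count_matches(templates_m1, tol)
    if a == 0 or b == 0:
        return float("nan")
    return float(-np.log(a / b))


def multiscale_entropy(x: np.ndarray, config: SampEnConfig | None = None,
                       use_original_sd: bool = True) -> MSECurve:
    """SampEn of each coarse-grained series over ``config.scales``."""
    config = config or SampEnConfig()
    config.validate()
    x = np.asarray(x, dtype=float)
    sd0 = float(np.std(x)) if use_original_sd else None
    values = np.empty(len(config.scales))
    for i, tau in enumerate(config.scales):
        if tau > len(x):
            values[i] = float("nan")
            continue
        values[i] = sample_entropy(coarse_grain(x, tau), m=config.m,
                                   r=config.r, sd=sd0)
    return MSECurve(scales=tuple(config.scales), values=values)
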