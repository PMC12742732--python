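"""Takens delay embedding of scalar series into point clouds.

Row j of the embedding is ``(x_j, x_{j+tau}, ..., x_{j+(m-1)tau})``. A
periodic series traces a closed loop in the reconstructed space; chaotic
dynamics give an intricate attractor-shaped cloud. Clouds can be reduced
by farthest-point subsampling before building filtrations, which keeps
the coarse geometry while bounding the simplicial blow-up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class EmbeddingConfig:
    """Delay-embedding parameters.

    ``tau=None`` selects the delay per series as the first minimum of the
    time-delayed mutual information; ``subsample_to`` caps the cloud size
    by farthest-point sampling (None = keep every point).
    """

    m: int = 3
    tau: int | None = None
    subsample_to: int | None = 400

    def validate(self) -> None:
        if self.m < 2:
            raise ValueError("embedding dimension m must be >= 2")
        if self.tau is not None and self.tau < 1:
            raise ValueError("delay tau must be >= 1")


@dataclass
class PointCloud:
    """Delay-embedded trajectory (N x m coordinates in signal units)."""

    points: np.ndarray
    m: int
    tau: int
    source: str | None = None


def takens_embed(series: np.ndarray, config: EmbeddingConfig | None = None,
                 *, m: int | None = None, tau: int | None = None,
                 subsample_to: int | None = None,
                 source: str | None = None) -> PointCloud:
    """Embed a scalar series; optionally farthest-point subsample.

    Raises with the required length when the series is too short for
    (m, tau): at least ``(m-1)*tau + m + 2`` samples are needed.
    """
    if config is None:
        config = EmbeddingConfig(m=m or 3, tau=tau, subsample_to=subsample_to)
    config.validate()
    series = np.asarray(series, dtype=float).ravel()
    m_, tau_ = config.m, config.tau
    if tau_ is None:
        tau_ = delay_from_mutual_information(series)
    n_points = len(series) - (m_ - 1) * tau_
    if n_points < m_ + 2:
        raise ValueError(
            f"series of {len(series)} samples too short for m={m_}, "
            f"tau={tau_}: need at least {(m_ - 1) * tau_ + m_ + 2}")
    idx = np.arange(n_points)[:, None] + tau_ * np.arange(m_)[None, :]
    points = series[idx]
    if config.subsample_to is not None and n_points > config.subsample_to:
        keep = farthest_point_sample(points, config.subsample_to)
        points = points[keep]
    return PointCloud(points=points, m=m_, tau=tau_, source=source)


def delay_from_mutual_information(series: np.ndarray, max_lag: int | None = None,
                                  n_bins: int = 16) -> int:
    """First local minimum of the lagged mutual information.

    Falls back to the lag where the autocorrelation first drops below
    1/e, then to ``max_lag``, when no local minimum exists.
    """
    series = np.asarray(series, dtype=float).ravel()
    n = len(series)
    if max_lag is None:
        max_lag = max(2, min(n // 4, 100))
    mi = np.empty(max_lag + 1)
    for lag in range(1, max_lag + 1):
        a, b = series[:-lag], series[lag:]
        hist, _, _ = np.histogram2d(a, b, bins=n_bins)
        pxy = hist / hist.sum()
        px = pxy.sum(axis=1, keepdims=True)
        py = pxy.sum(axis=0, keepdims=True)
        nz = pxy > 0
        mi[lag] = float((pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])).sum())
    for lag in range(2, max_lag):
        if mi[lag] < mi[lag - 1] and mi[lag] <= mi[lag + 1]:
            return lag
    # fallback: autocorrelation 1/e crossing
    x = series - series.mean()
    denom = float(x @ x)
    if denom > 0:
        for lag in range(1, max_lag + 1):
            if float(x[:-lag] @ x[lag:]) / denom < 1.0 / np.e:
                return lag
    return max_lag


def farthest_point_sample(points: np.ndarray, k: int, start: int = 0) -> np.ndarray:
    """Indices of a greedy farthest-point subsample (deterministic).

    Starts from ``start`` and repeatedly adds the point farthest from the
    selected set. Returned indices are sorted so trajectory order is kept.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if k >= n:
        return np.arange(n)
    chosen = np.empty(k, dtype=int)
    chosen[0] = start
    dist = np.linalg.norm(points - points[start], axis=1)
    for i in range(1, k):
        nxt = int(np.argmax(dist))
        chosen[i] = nxt
        dist = np.minimum(dist, np.linalg.norm(points - points[nxt], axis=1))
    return np.sort(chosen)
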