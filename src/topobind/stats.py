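"""Nonparametric statistical battery for group comparisons.

Shapiro-Wilk normality gating, one-tailed Mann-Whitney U post-hoc tests,
the Kruskal-Wallis omnibus with the epsilon-squared effect size
``eps2 = H * (n + 1) / (n^2 - 1)`` (magnitude labels at the conventional
.01 / .06 / .14 cut-offs), Pearson feature-behavior correlations, and a
Wilcoxon signed-rank power analysis via the ARE-corrected t-test route
(n_t / 0.955) cross-checked by direct simulation.

No multiple-comparison correction is applied by default (a Holm option
exists); reports always state which mode ran.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.power import TTestPower

#: Asymptotic relative efficiency of the Wilcoxon signed-rank test vs the
#: t-test under normality.
WILCOXON_ARE = 0.955

EPSILON2_CUTOFFS = ((0.14, "large"), (0.06, "medium"), (0.01, "small"))


@dataclass
class GroupComparison:
    test: str
    statistic: float
    p_value: float
    tail: str
    groups: tuple[str, ...]
    effect_size: float | None = None
    effect_label: str | None = None


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n: int
    pair: tuple[str, str]


@dataclass
class NormalityResult:
    statistic: float
    p_value: float
    normal: bool


@dataclass
class PowerAnalysis:
    """Minimal sample size for a one-sample/paired Wilcoxon design."""

    effect_size: float
    alpha: float
    power: float
    tail: str
    n_are: int
    n_simulation: int | None = None
    n_sims: int = 0


def shapiro_gate(groups: Mapping[str, Sequence[float]],
                 alpha: float = 0.05) -> dict[str, NormalityResult]:
    """Shapiro-Wilk per group; ``normal`` means p > alpha.

    A (near-)constant sample cannot be normal and is flagged non-normal
    rather than crashing.
    """
    out = {}
    for name, values in groups.items():
        values = np.asarray(values, dtype=float)
        if len(values) < 3:
            raise ValueError(f"group {name!r}: Shapiro-Wilk needs n >= 3")
        if np.ptp(values) == 0:
            out[name] = NormalityResult(float("nan"), 0.0, False)
            continue
        w, p = sp_stats.shapiro(values)
        out[name] = NormalityResult(float(w), float(p), bool(p > alpha))
    return out


def mann_whitney_one_tailed(a: Sequence[float], b: Sequence[float],
                            tail: str = "greater",
                            names: tuple[str, str] = ("a", "b")) -> GroupComparison:
    """Mann-Whitney U comparing sample a against b with the given tail.

    Exact null distribution when the smaller sample has <= 8 observations
    and there are no ties; normal approximation with tie correction
    otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    if tail not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown tail {tail!r}")
    combined = np.concatenate([a, b])
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (min(len(a), len(b)) <= 8 and not has_ties) \
        else "asymptotic"
    res = sp_stats.mannwhitneyu(a, b, alternative=tail, method=method)
    return GroupComparison(test=f"mann-whitney-u ({method})",
                           statistic=float(res.statistic),
                           p_value=float(res.pvalue), tail=tail, groups=names)


def epsilon_squared_label(eps2: float) -> str:
    for cutoff, label in EPSILON2_CUTOFFS:
        if eps2 >= cutoff:
            return label
    return "negligible"


def kruskal_wallis_epsilon2(
    groups: Mapping[str, Sequence[float]],
) -> GroupComparison:
    """Tie-corrected Kruskal-Wallis H with epsilon-squared effect size."""
    names = tuple(groups.keys())
    samples = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs n >= 2")
    n = sum(len(s) for s in samples)
    if np.ptp(np.concatenate(samples)) == 0:
        h, p = 0.0, 1.0
    else:
        h, p = sp_stats.kruskal(*samples)
    eps2 = float(h * (n + 1) / (n ** 2 - 1))
    return GroupComparison(test="kruskal-wallis", statistic=float(h),
                           p_value=float(p), tail="two-sided", groups=names,
                           effect_size=eps2,
                           effect_label=epsilon_squared_label(max(eps2, 0.0)))


def pearson_corr(x: Sequence[float], y: Sequence[float],
                 pair: tuple[str, str] = ("x", "y")) -> CorrelationResult:
    """Pearson r with the two-sided t-based p-value.

    Zero variance in either variable yields an undefined (NaN) result
    instead of an exception.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(float("nan"), float("nan"), len(x), pair)
    res = sp_stats.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue),
                             len(x), pair)


def holm_correct(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    return multipletests(p_values, method="holm")[1]


def _wilcoxon_power_sim(n: int, d: float, alpha: float, one_sided: bool,
                        n_sims: int, rng: np.random.Generator) -> float:
    """Simulated power of the signed-rank test (normal-approximation p)."""
    x = rng.normal(d, 1.0, size=(n_sims, n))
    ranks = sp_stats.rankdata(np.abs(x), axis=1)
    w_plus = np.where(x > 0, ranks, 0.0).sum(axis=1)
    mean_w = n * (n + 1) / 4.0
    var_w = n * (n + 1) * (2 * n + 1) / 24.0
    z = (w_plus - mean_w) / np.sqrt(var_w)
    if one_sided:
        p = sp_stats.norm.sf(z)
    else:
        p = 2 * sp_stats.norm.sf(np.abs(z))
    return float(np.mean(p < alpha))


def wilcoxon_power_n(d: float, alpha: float = 0.05, power: float = 0.95,
                     tail: str = "one-sided", simulate: bool = False,
                     n_sims: int = 5000, seed: int = 0,
                     max_n: int = 10_000) -> PowerAnalysis:
    """Minimal n for a paired Wilcoxon signed-rank design at effect d.

    The analytic route solves the one-sample t-test sample size and
    divides by the asymptotic relative efficiency 0.955 (ceiling); with
    ``simulate=True`` a direct Monte-Carlo route (``n_sims`` replicates of
    N(d, 1) differences per candidate n) is reported alongside.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if not 0 < power < 1:
        raise ValueError("power must be in (0, 1)")
    if d <= 0:
        raise ValueError("effect size d must be positive")
    one_sided = tail == "one-sided"
    alternative = "larger" if one_sided else "two-sided"
    n_t = TTestPower().solve_power(effect_size=d, alpha=alpha, power=power,
                                   alternative=alternative)
    n_are = int(ceil(float(n_t) / WILCOXON_ARE))
    result = PowerAnalysis(effect_size=d, alpha=alpha, power=power, tail=tail,
                           n_are=n_are)
    if simulate:
        rng = np.random.default_rng(seed)
        n = 5
        while n <= max_n:
            if _wilcoxon_power_sim(n, d, alpha, one_sided, n_sims, rng) >= power:
                result.n_simulation = n
                result.n_sims = n_sims
                break
            n += 1
        else:
            raise ValueError(f"power {power} unreachable below n={max_n}")
    return result


def compare_ttb_directions(
    ttb_by_group: Mapping[str, Sequence[float]],
    directions: Iterable[tuple[str, str, str]] = (
        ("SCR", "SLR", "greater"),
        ("SLR", "CTR", "less"),
        ("SCR", "CTR", "greater"),
    ),
) -> list[GroupComparison]:
    """One-tailed Mann-Whitney tests in the hypothesized directions."""
    out = []
    for first, second, tail in directions:
        out.append(mann_whitney_one_tailed(
            ttb_by_group[first], ttb_by_group[second], tail=tail,
            names=(first, second)))
    return out
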