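# topobind

Topological and spectral EEG features with intentional-binding analysis.

`topobind` is a tested, synthetic-data-driven implementation of a complete
analysis for a three-group self-reflection study run on a 4-channel
Muse-style EEG headband (TP9, AF7, AF8, TP10 at 256 Hz): participants
perform self-centered reflection (SCR), selfless reflection (SLR), or sit
quietly (CTR), then complete a Libet-clock intentional-binding task. The
package answers two questions for such designs:

1. **Behavior** — how strongly does each group bind voluntary actions to
   their sensory outcomes (total time binding, TTB, in ms)?
2. **Neural features** — how do conventional spectral features and
   *topological* features of the EEG (persistent homology and Hodge
   spectral entropy of delay-embedded signals) differ between groups, and
   do they track TTB?

Because human EEG/behavioral data for this paradigm are rarely shareable,
the package ships a first-class synthetic-data module that generates
EEG-like sessions and clock-judgment trials with known ground truth, so
every stage of the pipeline is verifiable end to end.

## The quantities it computes

**Delay embedding.** A scalar series x(t) is embedded as the point cloud
with rows (x(t), x(t+τ), …, x(t+(m−1)τ)). Periodic signals trace loops;
irregular signals fill space.

**Vietoris–Rips persistence.** Growing a radius r over the cloud, a
simplex enters when all pairwise distances fall below r. For homology
orders k = 0, 1, 2 the package computes birth/death pairs (b_i, d_i),
Betti curves β_k(s) = #{i : b_i ≤ s < d_i}, the persistence entropy

    S_k^pe = −Σ p_i ln p_i,   p_i = (d_i − b_i) / Σ_j (d_j − b_j),

(finite bars only), and the Wasserstein amplitude
(Σ ((d_i−b_i)/√2)^p)^{1/p} of the diagram against the empty diagram.
H0 is computed by union-find (deaths are exactly the minimum-spanning-tree
edge lengths); H1/H2 by GF(2) boundary-matrix reduction with clearing.
Both are tested against an independent textbook dense reduction and
rank-nullity Betti numbers.

**Hodge spectral entropy.** At a fixed radius (default: where the
1-skeleton becomes connected) the order-n Hodge Laplacian
L_n = B_nᵀB_n + B_{n+1}B_{n+1}ᵀ is built from signed boundary operators;
its eigenvalues λ_i define the Gibbs entropy

    S_n^hs = α⟨λ⟩ + ln Z,   Z = Σ_i e^{−αλ_i},

which equals −Σ q_i ln q_i for q_i = e^{−αλ_i}/Z, so 0 ≤ S ≤ ln N_n.

**Conventional features.** Welch PSD with six-band relative power
(delta 0.5–5, theta 5–8, alpha 8–13, sigma 13–16, beta 16–30,
gamma 30–45 Hz), normalized by the *sum of band means*; and multiscale
sample entropy SampEn(m, r) = −ln(A^{m+1}/A^m) on coarse-grained series.

**Binding.** Clock judgments are wrapped angle errors converted to ms
(positive = reported later). Action binding = agency-block minus
action-only mean error; tone binding likewise; total = action − tone, so
mutual attraction is positive.

**Statistics.** Shapiro–Wilk gating, one-tailed Mann–Whitney U (exact
for small tie-free samples), Kruskal–Wallis with ε² = H·(n+1)/(n²−1),
Pearson correlations, and a Wilcoxon signed-rank power analysis
(ARE-corrected t route cross-checked by simulation). No
multiple-comparison correction by default (a Holm flag exists); every
report records the mode.

## Worked example

```python
import numpy as np
from topobind.synthetic import TrialSimConfig, generate_trials, generate_fixture
from topobind.binding import binding_scores
from topobind.tda import (takens_embed, vr_persistence, persistence_entropy,
                          build_hodge_laplacian, hodge_spectral_entropy)

# behavior: a subject with injected +40/-30 ms shifts, 70 ms judgment noise
cfg = TrialSimConfig(action_shift_ms=40.0, tone_shift_ms=-30.0,
                     judgment_noise_sd_ms=70.0, seed=7)
sc = binding_scores(generate_trials(cfg), "demo")
print(f"action {sc.action_binding_ms:+.1f} ms, tone {sc.tone_binding_ms:+.1f} ms,"
      f" total {sc.total_binding_ms:+.1f} ms")
# -> action +51.9 ms, tone -47.7 ms, total +99.6 ms

# topology: a sine embedded at a quarter period is a loop
x = generate_fixture("sine", n=256, seed=1, period=32.0)
cloud = takens_embed(x, m=2, tau=8, subsample_to=64)
diag = vr_persistence(cloud.points, max_dim=1)
h1 = diag.finite_pairs(1)
print(np.round(np.sort(h1[:, 1] - h1[:, 0])[::-1][:3], 3))
# -> [1.568 0.   ]  (one dominant loop, S_1^pe ~ 0)
spec = build_hodge_laplacian(cloud.points, order=1)
print(round(hodge_spectral_entropy(spec), 4), spec.n_simplices)
# -> 3.7118 120
```

The injected 70 ms total binding is recovered as 99.6 ms for this single
noisy subject (judgment noise SD is 70 ms; averaging over 200 simulated
subjects recovers 70 ± 1 ms). The sine's H1 diagram has a single
long-lived bar — the loop — so its persistence entropy is ~0, while the
Hodge entropy of its 120-edge 1-skeleton is bounded by ln 120 ≈ 4.79.

A full synthetic study (three groups, EEG sessions, features, statistics,
feature–behavior correlations) runs with:

```bash
topobind run --n-per-group 6 --seed 1 --out report/
```

and writes tidy CSV tables (binding, omnibus and directed tests with ε²,
per-feature Kruskal–Wallis, TTB–feature Pearson correlations, Betti
curves) plus a JSON manifest with the config hash, seed, and versions.

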