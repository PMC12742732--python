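# Methods

This note documents the models, conventions, defaults, and deliberate
design choices behind `topobind`, in the spirit of a package methods
appendix. It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Study model

The package models a between-subjects design with three groups —
self-centered reflection (SCR), selfless reflection (SLR), control (CTR)
— recorded on a 4-channel dry-electrode headband (TP9, AF7, AF8, TP10;
256 Hz). SCR/SLR sessions are eight 30 s guided questions; CTR is one
240 s silent block. Each subject then performs a Libet-clock
intentional-binding task: 4 conditions (action-only, tone-only, and two
action–tone variants judged on the action or the tone) × 20 trials = 80
trials, with a 250 ms action–tone delay in agency blocks.

## Synthetic data

The generator is the package's ground-truth source; its defaults are the
study conditions above.

**EEG.** Each channel is an independent sum of (a) band-limited
oscillations obtained by FFT-shaping white noise into the six canonical
bands, weighted by `band_weights` (default: an eyes-closed,
alpha-dominant profile); (b) optionally *tonal* components — single
sinusoids at band centres with random phase (`tonal_weights`) — which,
unlike incoherent band noise, trace clean loops after delay embedding;
(c) 1/f^β background synthesized by spectral shaping (β = 1 by default;
the aperiodic model is a package choice, since only band structure is
prescribed by the protocol); (d) an optional 50 Hz line sinusoid; and
(e) an optional muscle artifact: noise with a *rising* power spectrum
(~f^1.5 over 5–55 Hz) multiplied by a slow lognormal burst envelope and
mixed through a focal spatial vector (default weight 1.0 on TP10, 0.05
leakage elsewhere). The burst envelope is essential: it makes the source
super-Gaussian so that FastICA — which separates by non-Gaussianity and
is blind to purely Gaussian mixtures — can isolate it, exactly as real
postural EMG bursts are isolated in practice. One unit of generated
signal is scaled to 10 µV.

**Trials.** Actual event positions are uniform on the clock face;
reported positions add Gaussian judgment noise (default SD 70 ms — the
noise model is an assumption, stated here, since no error model is
prescribed) plus, in agency blocks, the configured action/tone shift.
Reported times wrap modulo the clock period. The clock period defaults to
2560 ms (a standard Libet-clock convention; the protocol does not state
its rotation speed) and *all* ms outputs scale with it.

**Fixtures.** `sine`, `two_tone`, `lorenz` (σ=10, ρ=28, β=8/3, dt=0.02,
20 s transient discarded), and `white_noise` provide oracle inputs for
the embedding and persistence tests.

All generators draw from a single `numpy.random.Generator` seeded per
call; identical config + seed is bit-identical.

## Preprocessing

* **Filtering.** Zero-phase FIR band-pass 0.1–45 Hz plus a 49–51 Hz
  band-stop. A meaningful "fourth-order" FIR cannot realize a 0.1 Hz
  edge, so the default tap count follows the transition-bandwidth rule
  3.3·fs/Δf with Δf = max(0.5, 2·highpass) Hz (≈1691 taps at 256 Hz),
  configurable via `FilterSpec.fir_length`. The symmetric kernel is
  applied by centred FFT convolution — exactly zero-phase and linear —
  so filtering commutes with channel pooling (tested). Edge regions of
  roughly half a kernel length are attenuated; segments are cut well
  inside session boundaries.
* **Muscle screening.** FastICA (delegated to scikit-learn, fixed seed)
  decomposes the filtered channels; each component is scored by
  (i) the slope of a line fit to log10 PSD vs log10 frequency over
  7–45 Hz, (ii) focality = max|mixing weight| / Σ|mixing weights|, and
  (iii) "smoothness", the R² of that line fit. A component is flagged
  only if slope > 0, focality > 0.6, and smoothness > 0.65. The PSD for
  the fit uses short (0.5 s) Welch windows and a 5-bin moving average of
  the log-PSD: the criterion should judge the spectral *trend*, not
  estimator noise, and with only four channels the artifact component
  always retains some background leakage, which caps the raw-fit R² well
  below what an idealized component would reach. Clean components are
  rejected by the slope sign alone. Reconstruction subtracts flagged
  components; with none flagged it is the identity.
* **Pooling and segmentation.** TP = (TP9+TP10)/2, AF = (AF7+AF8)/2.
  SCR/SLR: the last 25 s of each question span; CTR: the central 25 s of
  the rest block (107.5–132.5 s of a 240 s block). Half-open, 0-based
  sample intervals throughout.
* **Downsampling.** FIR anti-aliased decimation by 4 (256 → 64 Hz),
  applied for the topological features only; spectral features use the
  full-rate segments.
* The pipeline exposes a subject-exclusion list in its config rather
  than hard-coding where subject rejections occur.

## Feature conventions

* **Relative band power**: mean PSD within each band divided by the sum
  of the six band means (not by integrated power — the two differ on
  non-flat spectra because band widths are unequal; a regression test
  pins the band-mean variant). Band-edge bins are half-open [low, high).
  Welch defaults: 4 s Hann windows, 50% overlap.
* **Embedding**: m = 3 by default; τ by the first local minimum of
  lagged mutual information (16-bin histogram estimator) with an
  autocorrelation-1/e fallback, or fixed by config (the pipeline fixes
  τ = 2 at 64 Hz so that per-subject feature differences reflect signal
  geometry, not delay-selection jumps). Clouds are reduced by greedy
  farthest-point subsampling before filtration building.
* **Persistence**: filtration value of a simplex = its diameter; cap
  default 2 × median pairwise distance. H0 via Kruskal union-find; H1/H2
  via per-dimension GF(2) column reduction (columns as integer bitsets,
  rows in filtration order) with the clearing optimization, enumerating
  simplices only up to the cap. Bars alive at the cap are reported with
  death = ∞ and excluded from entropy and amplitude; a capped bar might
  in truth die just beyond the cap. Zero-persistence pairs are dropped.
  Betti curves use the half-open alive convention [b, d) on a default
  grid of evenly spaced radii from 0 to the cap.
* **Entropy and amplitude**: natural logarithm everywhere (it makes the
  Gibbs identity for the Hodge entropy exact). Amplitude uses the
  Euclidean ground metric, so each bar contributes lifetime/√2; the
  diagonal factor is exposed for other conventions; p = 2 default.
* **Hodge spectra**: computed at a single documented radius per cloud —
  default the connectivity radius (largest MST edge), grown by 10% steps
  in the pipeline until the first order-n simplex exists (the growth is
  recorded in the spectrum's `radius`). Damping α = 1 by default. Dense
  eigendecomposition; a size guard rejects complexes that would exceed
  it.
* **Sample entropy**: Chebyshev template distance, tolerance r = 0.2 ×
  SD, m = 2, self-matches excluded, both counts over start indices
  0..N−m−1. Undefined situations (constant series, no matches) return
  NaN rather than raising. Multiscale entropy re-uses the *original*
  series SD across scales (the common convention; a per-scale-SD flag
  exists). Default scales 1–20; the pipeline uses 1–10 on the 64 Hz
  segments.

## Binding conventions

Judgment error = ((reported − actual + 180°) mod 360° − 180°) · period /
360°, positive = reported later. Action binding = mean agency-action
error − mean action-only error; tone binding analogously; **total =
action − tone**, so the classic mutual-attraction pattern (action later,
tone earlier) gives a positive total. The convention string is embedded
in every score object and report manifest, because published tables in
this literature are not always arithmetically consistent across the
three measures and re-analyses must know which convention was used.
Invalid (missing-click) trials are excluded listwise per condition with
counts reported.

## Statistics

* Mann–Whitney U: exact null when min(n) ≤ 8 and no ties; otherwise the
  tie-corrected normal approximation. One-tailed directions follow the
  study hypotheses (SCR>SLR, SLR<CTR, SCR>CTR on TTB).
* Kruskal–Wallis with tie correction; ε² = H·(n+1)/(n²−1) with magnitude
  labels at 0.01/0.06/0.14. ε² is invariant under monotone transforms
  (tested).
* Shapiro–Wilk gates normality at p > 0.05; constant samples are flagged
  non-normal instead of crashing.
* Power analysis: the minimal n for a *paired* Wilcoxon signed-rank
  design is the one-sample t-test n divided by the asymptotic relative
  efficiency 0.955 (ceiling), cross-checked by direct simulation
  (vectorized signed-rank with normal-approximation p). The paired test
  is implemented as specified even though the surrounding design is
  between-subjects — a mismatch inherited from the protocol and noted
  here rather than silently "fixed".
* No multiple-comparison correction by default; `holm_correction=True`
  adds Holm-adjusted columns, and the manifest always records the mode.

## The end-to-end pipeline and its built-in coupling

`run_pipeline` simulates the full study: per subject, a target TTB is
drawn from the group distribution (defaults 123±75 / 51±41 / 82±54 ms
for SCR/SLR/CTR), realized as ±TTB/2 action/tone shifts in the trial
generator, and coupled to the EEG generator through an
oscillatory-regularity mix c ∈ [0.2, 0.97]: higher TTB ⇒ larger tonal
alpha weight, less (and steeper-spectrum) aperiodic background. A
coherent alpha rhythm embeds as a loop-like cloud with few 2-simplices
at the connectivity radius, hence *lower* second-order Hodge spectral
entropy — so the built-in TTB–S²hs coupling is negative by construction,
and the correlation stage has a recoverable target of known sign.

Problem sizes are deliberately modest so the whole suite runs on one
CPU in minutes: pipeline clouds are subsampled to 32 points (64 in the
persistence-free coupling harness) — full VR reduction to dimension 2
grows steeply with cloud size in this pure-Python engine — and the
coupling harness uses 6 subjects per group with shortened sessions
(2 questions / 60 s CTR). These are scale choices of the package, stated
here so that readers know the regimes the tests actually exercise.

## What the synthetic tests do and do not show

Passing tests demonstrate that every operation implements its stated
formula (oracle equivalence), that injected parameters are recovered at
the configured noise levels, and that the statistical battery is
calibrated under its null. They do not show that real EEG exhibits the
coupling the generator builds in: the generator's channels are
independent (no volume conduction or shared sources), its background is
stationary Gaussian 1/f noise (no non-stationarity, eye movements, or
electrode drift), and its alpha rhythm is either fully coherent or fully
incoherent, unlike the waxing-waning rhythms of real recordings.
Conclusions about real data require real data; the package guarantees
only that the measurement chain is faithful.

## Known limitations

* The VR engine targets small clouds (≲100 points to dimension 2); it
  guards against combinatorial blow-up with an explicit simplex cap
  rather than streaming/implicit techniques.
* Infinite bars are an artifact of the filtration cap as much as of
  topology; features exclude them.
* EDF is read via mne when installed; there is no EDF writer.
* FastICA on four channels cannot fully separate five or more sources;
  the screener is designed around dominant, focal artifacts.
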