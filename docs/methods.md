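# Methods

This note documents the models, parameter choices and numerical decisions
behind `batcolony`, and what the synthetic-data tests do and do not
establish about real recordings.

## The behavioural model

A session simulates `n_bats` (default 5) in a 5.6 × 5.2 × 2.5 m room over
`duration` seconds (default 3600 s). Rest sites (default 5) are placed in
the upper part of the room with at least 1.2 m pairwise separation. Each
bat alternates rests and flights:

- **Rests** are exponential with mean set so that the flight rate matches
  `flight_rate` (default 77 flights per hour per bat, the observed group
  average), with a 2 s minimum. During a rest the bat sits at its site plus
  a fixed jitter (≤ 0.1 m), plus i.i.d. tracking noise (σ = 5 mm).
- **Flights** are cubic splines through the take-off point, one mid-air
  control point (per-site-pair lateral bow and vertical dip, so flights
  between the same sites repeat along the same path), and the landing
  point, traversed with a symmetric 1 − cos speed profile, peak speed
  2–4 m/s, duration clipped to 1–4 s. Only the qualitative features of real
  kinematics (smooth, short, repeatable, realistic peak speed) are
  emulated; no aerodynamics.
- **Destination choice** is proportional to the bat's per-site preference
  weights times exp(η · Σ preference to bats currently at the site), η = 3.
  With the default zero preference matrix, destinations are socially
  unbiased. Per-bat site preferences default to a sparse Dirichlet(0.7)
  draw per session: bats favour a couple of self-selected sites, which is
  what concentrates flights on repeatable paths; uniform preferences spread
  flights so thinly over site pairs that no path accumulates enough
  crossings for path-level analyses.

Ground truth recorded per flight: the distance to every other bat at the
landing instant, the derived social label (< 0.6 m social, > 0.9 m
non-social, otherwise ambiguous), and the ordered site pair (the path
identity).

The accelerometer magnitude is g ± 0.02 m/s² at rest (plus sparse grooming
bouts, default 2 per hour), and g plus a 2 m/s², 8 Hz wingbeat oscillation
in flight. Echolocation clicks are Gaussian-windowed 22.5 kHz pips
(σ = 40 µs) in pairs — 20 ms within a pair, 100 ms from the second click of
a pair to the next pair's first, both with 10 % jitter — in bouts around
every take-off and landing, over white noise at the configured SNR
(default 20 dB: click peak / noise sd = 10).

## The cell model

Firing rates live on 200 ms bins:

    λ(tᵢ) = λ_spont + λ_spatial(tᵢ) + λ_social(tᵢ)
    λ_spatial = w(tᵢ) · λ_c · exp(−|x(tᵢ) − x_c|² / 2σ_c²)
    λ_social  = b(tᵢ) · λ_s · exp(−(tᵢ − t_s)² / 2σ_s²)

with defaults λ_spont = 0.4 Hz, λ_c = 8 Hz (pure spatial), λ_s = 4 Hz
(pure social), λ_s = ±λ_c = ±4 Hz (conjunctive, sign ± with probability
0.5), σ_c = 0.5 m, σ_s = 0.5 s. `w` is 1 in flight and ramps linearly to 0
within 0.5 s of the nearest take-off or landing; `b` is true when a
conspecific is within 0.6 m of the flight's landing point (evaluated at
the landing instant, the same definition the analysis side uses, so
generator and analyser agree by construction), and for conjunctive cells
additionally requires |x(tᵢ) − x_c| ≤ σ_c. Negative conjunctive modulation
is clipped at 0 Hz (a Poisson rate cannot be negative). Spikes are Poisson
per bin with uniform timestamps within the bin. The exponent signs are the
decaying Gaussians written above. Random streams are split per component
(behaviour, accelerometer, audio) from one session seed.

## Analysis-side parameters

All thresholds are exposed as function parameters; defaults:

| quantity | default | note |
|---|---|---|
| speed threshold / min flight / merge gap | 0.5 m/s, 0.5 s, 0.3 s | min duration and gap suppress jitter |
| position smoothing | quadratic LSQ 1 s; median 5 s (rest only) | Savitzky–Golay, uniform weights |
| rest clustering | single linkage, 0.2 m cut, ≥ 10 s | clustered on a 1 Hz subsample |
| occupancy grid | 21 × 21 bins, no smoothing | exploration over contour bins, ≥ 5 s |
| 2D rate maps | 0.15 m bins, Gaussian σ = 1.5 bins, < 200 ms invalid | invalid bins kept if ≥ 1 of 8 neighbours valid |
| path clustering | 7-point paths, discrete Fréchet, complete linkage, 1.1 m | complete so cluster spread stays below the cut |
| 1D fields | 0.15 m bins, 7-sample Gaussian window, ≥ 5 flights, ≥ 4 with spikes | rescaled take-off → landing |
| spike shuffles | 1000 circular shifts; min shift 10 s (2D), 1 s (1D) | rest cut out of the timeline |
| social thresholds | < 0.6 m social, > 0.9 m non-social | ambiguous flights excluded |
| sliding windows | 16 windows of 500 ms, 100 ms steps in [−1, +1] s | ties break toward the anchor |
| modulation scores | 100 subsamples of 5 vs 5; exact 252-split null at 95 % | rule: firing > 0.5, others < 0.5 |
| stepwise GLM | Poisson, log link; enter p < 0.05, remove p > 0.10 | deviance (likelihood-ratio) tests |
| stationary-bat events | ±1 s windows, non-overlapping, accel dev ≤ 0.03 m/s², ≥ 20 events | Wilcoxon per window, Bonferroni ×16 |
| selectivity | ≥ 10 events per condition, ≥ 2 conditions, 100 shuffles | responses shifted by their minimum |
| click detection | 10–40 kHz, 10 sd, 10 ms separation, global z-score | gain invariant |
| click classification | 5 ms snippets, unit-power band spectra, 3 PCs, k-means k = 4 | centroid merge below 2× median within-cluster RMS |
| ROI analyses | min–max + 1 s moving average; [−1, 2] s landing windows; 4-fold CV | scaler fit on training folds only |

## Numerical and design choices

- **Exact conditional Poisson test.** Conditional on the total count, the
  count in condition 1 is binomial under equal rates; two-sided p by
  doubling the smaller tail, capped at 1. Matches brute-force enumeration
  to 1e−12 for totals ≤ 30.
- **Exact balanced-split null in the modulation scores.** The per-subsample
  5 vs 5 label permutation has only 252 distinct assignments; the test
  enumerates all of them instead of drawing 100 at random. The relevant
  p-values sit right at the 5 % boundary (12/252 ≈ 0.0476 in typical
  configurations), where a 100-draw Monte-Carlo estimate is a coin flip;
  enumeration is deterministic and calibrated (measured type-I 0.051).
- **Sammon mapping** is initialized by classical metric scaling and
  minimised by gradient descent with step halving, which makes the stress
  trace non-increasing by construction; zero input distances are
  ε-jittered.
- **Click-cluster merging.** k-means with k = 4 fragments a single
  homogeneous click population into arbitrary quarters, which would destroy
  the inter-click-interval structure of the accepted set. After clustering,
  centroids closer than twice the median within-cluster RMS radius are
  merged (single linkage) before the most numerous group is accepted.
  Distinct broadband artifacts remain separated; a homogeneous population
  is accepted nearly whole.
- **Anatomical clustering test.** Pairwise distances within one FOV are
  dependent, so an off-the-shelf two-sample KS p-value is not calibrated.
  The statistic (KS distance of the modulated-pair distances against the
  pooled random-subset reference) is instead ranked among the same
  statistic for each random subset — exchangeable under the null, hence
  calibrated (measured type-I 0.056).
- **Place-field fitting** forward-models the map construction: a candidate
  Gaussian field plus baseline is multiplied by the raw occupancy,
  convolved with the map kernel and divided by the smoothed occupancy, with
  residuals weighted by √occupancy (the sampling variance of a rate
  estimate scales inversely with exposure). The fitted amplitude therefore
  estimates the generative field peak, undistorted by smoothing or
  occupancy weighting.
- **Proximity index** decimates positions to 10 Hz before the threshold
  fraction and its 1000-shift null; positions are autocorrelated over
  seconds, so the estimate is unchanged and the null stays tractable.
  Shifts are uniform with a 60 s minimum.
- Intervals are half-open [start, end); coordinates are metres with the
  origin at a room corner and z up.

## What the synthetic tests show — and what they don't

The generator provides exact ground truth, so the test suite can verify
calibration (every permutation/shuffle test has type-I error in
[0.03, 0.07] at α = 0.05) and recovery (planted field centres to ~0.1 m,
field widths to < 30 %, proximity structure, planted click timing). It does
not emulate real tracking dropouts beyond simple gaps, multipath RTLS
error, crawling at rest, spike-sorting contamination, calcium-indicator
dynamics (ROI fixtures are log-normal window means with planted gains), or
acoustically realistic room reverberation. Passing tests therefore
establish the correctness and calibration of the analysis code, not the
effect sizes to be expected from real recordings.

A measured limitation worth knowing: at the published simulation effect
size (a 4 Hz social increment on a 0.4 Hz baseline) with 20 social and 20
non-social flights, the conservative modulation-score rule flags about
two-thirds of planted social cells (takeoff-anchored ≈ 0.9,
landing-anchored ≈ 0.6 — the pre-landing window priority forgoes the best
window), and only about one-third of conjunctive cells, whose 4 Hz spatial
pedestal is shared by both flight classes and halves the social
effect-to-noise ratio. The per-subsample 5 vs 5 exact test has ≈ 0.6 power
at these Poisson rates, so the score distribution straddles the 0.5
decision threshold; power rises with more flights per class (≈ 0.8 at
30 + 30 for social cells). This mirrors the conservative character of the
original exclusion-based procedure rather than an implementation defect.
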