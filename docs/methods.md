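# Methods

## Signal model and simulated world

`p300cble.simulate` emulates a row-column P300 speller recording:

* **Paradigm.** 6×6 matrix (A–Z, 0–9; `.` is aliased to the `9` cell during
  normalization, spaces are stripped), 67 ms flashes with 100 ms
  inter-stimulus interval → 167 ms stimulus onset asynchrony (SOA), a
  *sequence* = all 12 row/column flashes in random order, 10 sequences per
  character, 600 Hz sampling, 64 channels. A session spells a list of
  sentences with a 1 s silent gap between them; the first sentence of the
  first session is the training split.
* **Background.** Per-channel Gaussian noise spectrally shaped to
  1/f^α (α = 1 by default), scaled to a target RMS, synthesized by FFT
  filtering (DC zeroed). Channels are independent — real EEG is spatially
  correlated; see *Limitations*.
* **P300.** Every target flash adds a positive Gaussian-windowed deflection
  with peak at `300 ms + ε` post-onset, FWHM 150 ms, amplitude 5 µV scaled
  by a fixed smooth topography (raised Gaussian bump over channel index,
  floor 0.3, peak near the centro-parietal channels). The jitter
  `ε ~ Normal(0, σ_jitter²)` is truncated at ±3 σ and the realized peak
  latency of every target event is recorded as ground truth (clipped if a
  draw would leave the recording). Responses of nearby flashes overlap and
  sum linearly — with a 167 ms SOA and 750 ms epochs this overlap is an
  essential property of the paradigm, not an edge case. Non-target flashes
  add no response by default (`nontarget_amplitude_uv` enables a small
  early deflection).
* **SNR defaults.** amplitude 5 µV / pink-noise 6 µV RMS. This "moderate
  SNR" was calibrated so that *all three* classifiers decode near ceiling
  at zero jitter, degrade as jitter grows, and all three classifier-based
  latency estimators remain latency-sensitive. At substantially lower SNR
  the sparse autoencoder's code is dominated by background noise and its
  score becomes insensitive to the analysis-window shift, which removes the
  very effect under study; at much higher SNR nothing degrades and the
  jitter-accuracy relation has no variance to exhibit.

What a green test on this world does **not** establish: robustness to
artifacts (ocular/muscle), spatially correlated noise, non-Gaussian or
multi-component ERPs, amplitude (as opposed to latency) variability, or
non-stationarity across a session.

## Preprocessing

Windowed-sinc (Hamming) FIR bandpass 0.5–70 Hz, 661 taps, applied with
'same'-mode convolution so the integer group delay cancels and events stay
aligned. A ~1.1 s FIR cannot genuinely resolve a 0.5 Hz corner, so the taps
are offset to force exact zero DC gain; this perturbs the response only
below ≈ 1 Hz. Epochs are the half-open 0–750 ms post-stimulus windows
(450 samples, 0-based indexing); downsampling replaces each run of 30
samples by its mean (15 time bins of 50 ms), and features are flattened
channel-major. Channel selection ranks channels by the periodogram power of
the raw-rate target-minus-non-target average ERP in the frequency bin
nearest 3 Hz (2.67 Hz at the 1.33 Hz resolution of a 750 ms window; one-shot
periodogram because 750 ms is too short for Welch averaging), taking the
top 32 with ties broken by channel order. All classifiers z-score features
with training-set statistics stored in the model.

## Classifiers

* **LS**: minimum-norm least squares of the ±1 labels on intercept-augmented
  standardized features (LAPACK lstsq, never an explicit inverse).
* **SWLDA**: classical stepwise regression. Forward: the candidate with the
  smallest partial-F p-value enters if p < 0.05 (ties → lowest column
  index), computed incrementally against an orthonormal basis of the
  current model. Backward: any included coefficient with t-test p > 0.10
  leaves (largest first). Stops at no-change or 60 features; final weights
  are an ordinary LS fit on the selected set, zeros elsewhere. The
  backward step never empties the model; an empty *first* forward step
  raises (`untrainable data`).
* **SAE**: cost = mean-over-trials summed squared reconstruction error
  + λ‖W‖² (encoder+decoder weights, biases excluded) + β·Σᵢ KL(ρ‖ρ̂ᵢ), with
  sigmoid encoder *and* decoder on features min-max rescaled to [0, 1]
  (training range, clipped at transform time). λ = 0.004, β = 4, 200 hidden
  units; ρ = 0.05 (a conventional value — not dictated by the problem) is
  exposed in config. Optimized by L-BFGS from a seeded ±√(6/(D+L)) uniform
  initialization; the analytic gradient is verified against central finite
  differences in the tests, and the cost at each accepted iterate is kept
  as `training_trace`. The decoder is then discarded and a two-class
  softmax (bespoke cross-entropy fit with a 1e-4 ridge, class-0 logit
  pinned at zero) on the hidden code yields the score, the target-class
  probability. Training uses float32 arithmetic (2.8× faster; the gradient
  check runs in float64), capped at 200 iterations in cohort runs —
  sufficient for the cost to plateau on the cohort-sized training sets.
  Note that on very low-dimensional toy inputs the full-scale β collapses
  the encoder (reconstruction reward shrinks with D while the sparsity
  penalty does not); toy tests therefore use milder regularization.

## CBLE

For each analyzed trial the 750 ms window is re-extracted from the
continuous bandpassed EEG at every shift τ in the grid, downsampled,
standardized with the model's statistics and rescored; the estimate is the
score-maximizing τ (ties → smallest |τ|, then negative before positive;
out-of-bounds shifts are skipped per trial). Implementation: one wide
window per trial plus a cumulative sum gives every shifted epoch's block
means without re-reading the recording, and the resulting feature stack is
classifier-independent so all models share one extraction.

**Shift grid ±100 ms, 10 ms steps.** A grid reaching the SOA (±167 ms)
re-aligns the window with the *neighboring* flash's P300 and produces
spurious score maxima; recovery correlation against injected truth dropped
from ≈ 0.85 to ≈ 0.55 for every classifier when the grid was widened to
±200 ms. The grid remains a parameter.

**vCBLE** is the unbiased sample variance (ms²) of the per-trial shifts,
computed per participant over all supervised test target trials (a
per-sentence variant is available through `event_indices`). Accuracy
prediction fits `accuracy% ~ a·vCBLE + b` by ordinary least squares on all
other participants (leave-one-participant-out), reporting RMSE in accuracy
percentage points, R² of predicted vs. true, and the pooled Pearson r.
`ideal_prediction_floor` quantifies the irreducible error of even a perfect
predictor: observed accuracy over n characters is Binomial(n, p)/n, so the
oracle RMSE is 100·√(mean p(1−p)/n); the simulation is checked against this
closed form.

## Statistics

Blocks are participant × test sentence. Friedman uses within-block average
ranks and the tie-corrected statistic (denominator from observed squared
ranks) against chi-square with k−1 df; `method="exact"` enumerates all
(k!)^N tie-free orderings for small tables. The mean-rank post-hoc declares
pair (i, j) different when |R̄ᵢ−R̄ⱼ| exceeds z·√(k(k+1)/(6N)) with z at the
Bonferroni-adjusted two-sided level; reported per-method intervals are half
that critical difference so non-overlap ⇔ significance (this normal
construction is this package's definition of the interval). Wilcoxon
signed-rank drops zero differences, uses the exact null for n ≤ 25 without
ties and the tie/continuity-corrected normal approximation otherwise, and
multiplies raw p by k(k−1)/2 (capped at 1).

## Numerical and design choices

* Sample indexing is 0-based; epoch windows are half-open.
* SWLDA candidate columns whose residual against the current basis falls
  below 1e-10 of their original energy are treated as collinear (p = 1).
* Softmax and sigmoid evaluations use overflow-safe forms; ρ̂ is clipped to
  [1e-10, 1−1e-10] inside the KL term.
* Decoding ties break to the lowest row/column index, deterministically.
* Experiment seeds: every stochastic stage (session synthesis, SAE
  initialization) derives its seed from the experiment seed via
  `SeedSequence`, so a fixed config reproduces byte-identical accuracy
  tables and vCBLE values.
* Cohort runs are scaled down for a single-CPU budget: one session of four
  6-character sentences per participant (1 train + 3 test) in the default
  `cohort_config`; the full three-sentence × three-session structure is
  available through `ExperimentConfig(n_sessions=...)` and longer sentence
  lists.

## Known limitations

* The latency model shifts the whole P300 complex rigidly; component-wise
  latency differences (P3a vs P3b) and amplitude variability are out of
  scope.
* vCBLE saturates once injected jitter pushes most true deviations beyond
  the shift grid, compressing differences between very-high-jitter
  participants.
* The spatially independent 1/f background makes channel selection easier
  than on real EEG; selection quality on real data is not established here.
* The SAE's CBLE sensitivity degrades at low SNR earlier than the linear
  classifiers' (its unsupervised code tracks dominant variance), which is a
  genuine property of autoencoder scoring, not an implementation artifact.
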